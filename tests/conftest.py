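from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import corecirc as cc
from corecirc.pipeline import RunConfig, run_crc, run_targets

BUNDLE_SEED = 11


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """One generated small synthetic bundle shared across the session."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = dataclasses.replace(cc.make_fixture("small"), seed=BUNDLE_SEED)
    return cc.generate(cfg, outdir)


@pytest.fixture(scope="session")
def crc_result(small_bundle):
    return run_crc(RunConfig.from_yaml(small_bundle.run_config))


@pytest.fixture(scope="session")
def targets_result(small_bundle):
    return run_targets(RunConfig.from_yaml(small_bundle.run_config))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_intervals(rng, n, n_chroms=2, max_pos=5000, max_len=300):
    out = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(cc.GenomicInterval(chrom, start, start + length))
    return out
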