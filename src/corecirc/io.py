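"""Readers and writers for the on-disk formats the pipeline touches.

narrowPeak (ENCODE 10-column), BED6, the TSS annotation TSV, JASPAR PFMs
(via Bio.motifs), differential-expression TSVs, and fragment BEDs with
their total-mapped-read sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .intervals import GenomicInterval, Peak, TSSRecord, ValidationError


class ParseError(ValueError):
    """An input file line could not be parsed."""


def _parse_line(path, lineno: int, line: str, n_min: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < n_min:
        raise ParseError(f"{path}:{lineno}: expected >= {n_min} columns, got {len(fields)}")
    return fields


def read_peaks(path: str | Path, format: str = "narrowPeak") -> list[Peak]:
    """Read peaks from a narrowPeak or BED6 file.

    narrowPeak column 10 is the summit offset from ``start``; ``-1`` (summit
    not called) falls back to the interval midpoint. BED6 peaks get summit =
    midpoint and signal = the score column.
    """
    if format not in ("narrowPeak", "BED6"):
        raise ValueError(f"unknown peak format {format!r}")
    peaks: list[Peak] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            try:
                if format == "narrowPeak":
                    f = _parse_line(path, lineno, line, 10)
                    chrom, start, end = f[0], int(f[1]), int(f[2])
                    name, signal, offset = f[3], float(f[6]), int(f[9])
                    summit = start + offset if offset >= 0 else (start + end) // 2
                    strand = f[5] if f[5] in ("+", "-") else "."
                else:
                    f = _parse_line(path, lineno, line, 4)
                    chrom, start, end = f[0], int(f[1]), int(f[2])
                    name = f[3] if len(f) > 3 else "."
                    signal = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
                    strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
                    summit = (start + end) // 2
                iv = GenomicInterval(chrom, start, end, strand)
                peaks.append(Peak(iv, summit, signal, name=name, source=path.stem))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_bed(path: str | Path, items, extra_cols=None) -> None:
    """Write intervals or peaks as BED6 (+ optional extra columns)."""
    with open(path, "w") as fh:
        for i, item in enumerate(items):
            if isinstance(item, Peak):
                iv, name, score = item.interval, item.name, item.signal
            else:
                iv, name, score = item, f"region_{i + 1}", 0.0
            row = [iv.chrom, str(iv.start), str(iv.end), name, f"{score:g}", iv.strand]
            if extra_cols is not None:
                row.extend(str(x) for x in extra_cols[i])
            fh.write("\t".join(row) + "\n")


def write_narrowpeak(path: str | Path, peaks: list[Peak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        p.name,
                        "0",
                        iv.strand,
                        f"{p.signal:g}",
                        "-1",
                        "-1",
                        str(p.summit - iv.start),
                    ]
                )
                + "\n"
            )


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read the TSS annotation TSV.

    Expected header columns: gene_id, gene_symbol, chrom, tss_position,
    strand, is_tf. ``tss_position`` is the 0-based base of the transcription
    start; each row becomes a length-1 interval.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "gene_symbol", "chrom", "tss_position", "strand", "is_tf"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        pos = int(row.tss_position)
        iv = GenomicInterval(str(row.chrom), pos, pos + 1, str(row.strand))
        records.append(
            TSSRecord(str(row.gene_id), str(row.gene_symbol), iv, bool(row.is_tf))
        )
    return records


def write_tss_table(path: str | Path, records: list[TSSRecord]) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "gene_symbol": r.gene_symbol,
            "chrom": r.tss.chrom,
            "tss_position": r.tss.start,
            "strand": r.tss.strand,
            "is_tf": r.is_tf,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fragments_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED6 of aligned fragments (one line per read/fragment)."""
    frags = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                f = _parse_line(path, lineno, line, 3)
                strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
                frags.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return frags


def write_fragments_bed(path: str | Path, fragments: list[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(fragments):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tfrag_{i + 1}\t0\t{iv.strand}\n")


def read_total_mapped(path: str | Path) -> int:
    """Read the total-mapped-read sidecar JSON for a fragment BED."""
    with open(path) as fh:
        return int(json.load(fh)["total_mapped"])


def write_total_mapped(path: str | Path, total_mapped: int) -> None:
    with open(path, "w") as fh:
        json.dump({"total_mapped": int(total_mapped)}, fh)
        fh.write("\n")


def read_jaspar_pfms(path: str | Path) -> dict[str, np.ndarray]:
    """Read a JASPAR-format PFM file into ``{tf_name: 4 x L count matrix}``.

    Rows are ordered A, C, G, T. The TF name is the motif's ``name`` field
    (the part after the matrix identifier on the header line).
    """
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            out[m.name if m.name else m.matrix_id] = counts
    return out


def write_jaspar_pfms(path: str | Path, pfms: dict[str, np.ndarray]) -> None:
    """Write count matrices in JASPAR bracket format."""
    with open(path, "w") as fh:
        for i, (name, counts) in enumerate(pfms.items(), 1):
            fh.write(f">M{i:04d} {name}\n")
            for b, row in zip("ACGT", np.asarray(counts)):
                vals = " ".join(f"{v:6.0f}" for v in row)
                fh.write(f"{b} [{vals} ]\n")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression TSV (gene_id, log2fc, padj[, tag])."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if "tag" not in df.columns:
        df["tag"] = ""
    return df
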