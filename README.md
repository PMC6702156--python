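# corecirc

Super-enhancer calling and core regulatory circuitry (CRC) inference from
chromatin landscapes.

## The problem

Cancer cells are frequently addicted to a small set of lineage
transcription factors (TFs) that sit at the top of their regulatory
hierarchy. These master regulators can be found without any perturbation
data, from chromatin alone: they are driven by **super-enhancers** (SEs) —
exceptionally strong clusters of H3K27ac-marked enhancers — and they bind
each other's super-enhancers, forming a densely interconnected,
auto-regulating core circuit. `corecirc` implements this inference as a
tested, reusable pipeline for anyone with per-cell-line peak calls
(H3K27ac, H3K4me1, H3K4me3, ATAC, TF ChIP), aligned-fragment BED files, a
genome FASTA, a TSS table, JASPAR motif matrices and a
differential-expression table.

## The method

1. **Active genes** — a gene is active if an H3K27ac peak lies within
   1,000 bp of one of its TSSs in at least one cell line.
2. **Super-enhancers (ROSE)** — H3K27ac peaks from all lines are pooled,
   peaks entirely within ±2,500 bp of a TSS are removed, and survivors are
   stitched at 1,638 bp. Each region is scored by its total signal
   (rpm/bp density × length, reads extended to 200 bp). With rank and
   signal each scaled to [0, 1], the cutoff sits where the slope of the
   rank–signal curve first exceeds 1; regions above it are SEs.
3. **SE→gene assignment** — overlapping TSSs, TSSs within 50 kb
   (proximal), and the single closest gene.
4. **Nucleosome-free regions (NFRs)** — merged ATAC peaks fully contained
   in an SE of an active gene.
5. **Motif scanning** — NFR sequences are scanned on both strands with
   log-odds PWMs; each score gets an *exact* p-value from the convolution
   of the per-column score distributions under the background base
   composition, and hits are kept at Benjamini–Hochberg q < 1e-5 (every
   scanned window counts as a test).
6. **The circuit** — an edge A→B exists when a q-passing occurrence of A's
   motif lies in an NFR of an SE assigned to candidate TF B (active,
   SE-assigned, motif available). Each TF's **total degree** is
   |unique regulators| + |unique targets|; ranking by total degree
   surfaces the master regulators.
7. **Binding-site branch** — TF peaks supported by 3 of 4 cell lines form
   a consensus peakset; summit-centered 10 kb / 10 bp signal matrices of
   the three histone marks are clustered (Ward-D2, k = 3) into
   enhancer-like, promoter-like and low-signal chromatin states.
   Knockdown-responsive genes (|log2FC| > 0.6, adjusted p < 1e-10) are
   categorized by distance to the nearest consensus peak — Promoter
   (< 10 kb), Enhancer (10–400 kb), Distal (> 400 kb) — and category
   effect sizes are compared with Welch's t-test.

A first-class synthetic-data generator (`corecirc.synth`) emulates all of
these inputs with a *planted* circuitry — motifs physically written into
NFR sequences inside planted SEs, a hockey-stick enhancer signal law,
three chromatin-state archetypes, seeded down to byte-identical output —
so every stage is verifiable offline against machine-readable ground
truth.

## Worked example

```sh
corecirc synth --out bundle --size small --seed 1
corecirc -v crc --config bundle/config.yaml
python examples/04_circuitry.py
```

prints (abridged):

```
candidate TFs: 8
edges called: 22, planted: 22, recovered: 22, false: 0
TF ranking by total degree (in + out unique partners):
  1. TF01  in=8 out=8 total=16 <- planted master
  2. TF02  in=2 out=2 total=4
  ...
```

All 22 planted regulatory interactions are recovered with no false edges,
and the planted master regulator (which regulates and is regulated by
every TF) ranks first by total degree — the same read-out that nominates
a lineage oncogene on real data. The other examples demonstrate SE
calling (`02`, 24 stitched regions → 9 SEs at the elbow cutoff), exact
motif p-values (`03`), and the chromatin-state / target-category branch
(`05`, 53/53 binding sites in their planted state; Welch enhancer-vs-
promoter p = 2.3e-4).

Outputs are plain TSV/BED/JSON under `bundle/results/`, with a
`manifest.json` recording every parameter and input content hash.

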