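# Methods

This note records the models, conventions, numerical choices and
limitations behind `corecirc`, in the order the pipeline runs.

## Coordinates and interval algebra

All coordinates are 0-based, half-open (BED convention); conversion
happens only at parse/serialize boundaries (narrowPeak summits are
`start + offset`, with offset −1 falling back to the interval midpoint).
Strand is carried on intervals but ignored by all distance and merge
rules — only motif scanning is strand-aware. Two conventions worth
spelling out:

* **Adjacency merges at gap 0.** `[a, b)` and `[b, c)` have zero
  intervening bases, so `merge_intervals(gap=0)` joins them. Consensus
  peak grouping, by contrast, requires ≥ 1 bp of true overlap.
* **Distances** are the number of bases between closest ends (0 when
  overlapping, ∞ across chromosomes); ties in nearest-neighbor queries
  break toward the smaller start, then input order, so results are
  deterministic.

## Signal model

Densities are rpm/bp: reads per million mapped reads per base pair. Reads
are extended 3′-ward from their 5′ end to at least 200 bp (the
conventional ChIP fragment size); unstranded reads extend rightward.
Coverage is accumulated as exact integer per-base counts (cached
cumulative-sum arrays per chromosome), then normalized by region length
and by the caller-supplied library size — whether that count is pre- or
post-deduplication is the caller's responsibility and is echoed in the
run log. Summit-centered matrices tile a 10 kb window in 10 bp bins by
default; bins running off a chromosome start are zero-filled, and the
mean of the bin densities equals the whole-window density exactly.

## Super-enhancer identification

Enhancer stitching pools H3K27ac peaks from all cell lines, removes any
peak lying *entirely* within ±2,500 bp of a TSS (no truncation of
partially overlapping peaks — the simplest containment reading; removal
counts appear in the log) and merges survivors at 1,638 bp. Regions are
scored by total signal — rpm/bp density × region length — because the
rank-ordering algorithm this follows ranks stitched regions by total,
not mean, signal; `se_score_mode: mean` switches to density. An optional
control track is subtracted before flooring at zero (off by default; the
reference analysis does not state whether input DNA was subtracted).

**Cutoff geometry.** Signals are sorted ascending and both rank position
and signal are scaled to [0, 1]. The cutoff is the signal at the left
endpoint of the first consecutive-point segment whose slope exceeds 1,
and every region with signal ≥ cutoff is a super-enhancer. Consequences
that the tests pin down: the SE set is always an upper set of the signal
ranking; a perfectly linear signal vector (slope ≡ 1, never > 1) and a
constant vector yield zero SEs (with a warning for the constant case);
and on hockey-stick data the cutoff lands at the transition into the
upper tail, typically admitting the single strongest body region along
with the tail — recovery is therefore measured as base-level Jaccard
rather than exact set identity.

SE→gene assignment takes overlapping TSSs, TSSs within a 50 kb proximal
window (the cited tooling's convention; the reference text leaves
"proximal" undefined) and always the single closest gene, collapsing
duplicates to the strongest relation. Nucleosome-free regions are merged
pooled ATAC peaks *contained* in (not merely overlapping) an SE assigned
to at least one active gene; active means an H3K27ac peak within
1,000 bp of any transcript TSS in any single cell line.

## Motif scanning and exact p-values

PFMs become log2-odds PWMs with pseudocount 0.1 distributed by the
background composition. Scores are rounded to a 1e-3-bit grid; both
window scoring and the null distribution use the same integer grid, so
the p-value of a score is exact by construction. The null distribution of
the total score under i.i.d. background bases is built by column-wise
convolution over that grid — identical to full 4^L enumeration (verified
for L ≤ 8 under uniform and skewed backgrounds) at a DP cost linear in
motif length. The grid introduces at most L·(1e-3) bits of score slack;
with the default granularity this is far below any decision boundary the
pipeline uses.

Both strands are scanned (reverse strand via the reverse-complement PWM);
windows containing N are skipped but windows scanned count as tests.
Benjamini–Hochberg control is applied per TF across *all* windows scanned
for that TF (`fdr_scope: global` pools all TFs into one family). The BH
step-up is implemented directly because the family size must be settable
independently of the emitted hit list; it is cross-checked against
statsmodels in the tests. Scanning at p ≤ q-threshold loses no q-passing
hit, since q ≥ p always and undetected windows cannot drag any kept q
below the threshold. The background defaults to the pooled mononucleotide
composition of the scanned sequences, overridable in config.

## Circuit construction and ranking

Candidate TFs are genes that are simultaneously active, SE-assigned
(overlapping, proximal, or closest) and present in the motif database;
gene-symbol↔motif-name matching is exact but case-insensitive, and
unmatched motifs are logged rather than silently dropped. An edge A→B
needs one q-passing hit of A's motif in an NFR contained in an SE
assigned to B; evidence aggregates on a single edge per ordered pair, so
degrees are invariant to hit multiplicity. Autoregulation counts once in
each of the in- and out-sets (total degree 2 for an isolated self-loop),
matching the view of auto-activation as the hallmark of a core circuit;
`exclude_self` removes self-loops before ranking. Ranking is by total
degree descending, ties by out-degree, then name.

## Chromatin states

The consensus TF peakset keeps transitively overlapping cross-line
groups with peaks from ≥ 3 of 4 lines, spanning the union of members and
centered on the summit of the strongest member (ties → leftmost) — the
reference procedure centers on "cell-line-specific summits" without
naming the line, and the strongest peak is the least arbitrary single
choice. Summit-centered matrices of H3K27ac/H3K4me1/H3K4me3 (averaged
across lines per mark) are concatenated and clustered with Ward-D2
linkage on Euclidean distances (scipy's `ward`, equivalent to R
`hclust(method="ward.D2")`), cut at k = 3. Each mark block is z-scaled
(global mean/std per mark) by default so no mark dominates the metric;
`scale_marks: false` clusters raw densities — the reference text does not
state whether scaling preceded the cut, so both paths exist. Cluster
labels are renumbered 1..k by decreasing mean H3K27ac, making reports
deterministic.

## Target categorization

Regulated genes pass |log2FC| > 0.6 (1.5-fold) *and* adjusted p < 1e-10,
both strict. (The source methods text prints the p-inequality with the
opposite sign; "<" is the only reading under which genes are "selected",
and is implemented as such.) Distance is the minimum over a gene's TSSs
to the nearest consensus peak: Promoter d < 10 kb, Enhancer
10 kb ≤ d ≤ 400 kb, Distal d > 400 kb, Unassigned when no peak shares a
chromosome. The printed bin definitions leave both boundary points
ambiguous; the promoter boundary follows the printed strict "<", and
400 kb is closed on the enhancer side so the partition is total. Category
log2FC distributions are compared with Welch's unequal-variance t-test
(Welch–Satterthwaite df); groups need n ≥ 2 and nonzero variance.

## Synthetic data

The generator is the package's testbed and defines the study conditions:

* **Geometry.** One 2 Mb chromosome (small fixture: 40 genes, 8 TFs;
  medium: 10 Mb, 300 genes, 25 TFs). Each TF gene occupies a 120 kb
  block: promoter peaks at the TSS, three 2 kb H3K27ac constituents
  (1 kb gaps, so they stitch) starting 6 kb downstream, and two 700 bp
  ATAC peaks inside the constituents. Block spacing guarantees each
  planted SE is proximal/closest to exactly one TF, so planted edges and
  pipeline edges coincide by construction. Promoter-bound and
  enhancer-bound DE target genes sit at ~2 kb and ~28 kb from a planted
  TF peak; distal targets sit > 400 kb from every TF peak.
* **Planted circuitry.** Default wiring: the master regulates all TFs
  (itself included), all TFs regulate the master, non-masters form a
  ring — the master's total degree strictly dominates. Every edge A→B is
  realized by writing A's consensus (length 18, near-deterministic
  columns 197:1:1:1, pairwise Hamming ≥ 6) into a target NFR. The length
  was chosen so recovery is deterministic, not seed-lucky: the worst-case
  exact p of a perfect match under the GC = 0.41 background is
  0.295^18 ≈ 3e-10, and with ~2×10⁴ scanned windows per TF the BH q stays
  below the 1e-5 threshold for every possible consensus composition,
  while a chance background hit would need p ≤ 5e-10 (never observed).
* **Signal law.** Reads are 50 bp, centers Normal(site, 120 bp), counts
  Poisson. SE constituents draw ~500 reads/line, typical enhancers a
  log-normal body (log-mean 3.0, log-sd 0.4 — the sd keeps consecutive
  body gaps below the slope-1 trigger so the elbow lands at the planted
  tail), promoters 80, plus 4,000 uniform background reads per track and
  a fixed library size of 10⁶.
* **Chromatin states.** Three archetypes (enhancer-like: K27ac 400 /
  K4me1 350; promoter-like: K27ac 250 / K4me3 350; low: ~8 reads) drive
  the mark fragments at TF binding sites; mean H3K27ac decreases across
  states so label renumbering is unambiguous. Peak calls are written only
  at planted loci — signal without a call at state sites mimics
  sub-threshold enhancers and keeps the SE ranking controlled by the
  planted law. A few TF peaks appear in only 2 lines to exercise the
  consensus filter.
* **DE model.** Planted targets: log2FC ~ Normal(−1.5, 0.3) with a ±0.4
  category shift (enhancer-bound stronger), clamped at −0.8 so every
  planted target clears the 1.5-fold cutoff; padj ~ 10^−U(12,18). Nulls:
  Normal(0, 0.2), padj ~ U(1e-3, 1).
* **Determinism.** Every stream derives from (seed, stream label) via a
  seed sequence, so identical seeds give byte-identical trees and adding
  a track never perturbs the others; the emitted `config.yaml` uses
  relative paths so bundles are relocatable.

What the generator does **not** emulate: nucleosome positioning,
fragment-length mixtures, mappability and GC bias, copy-number effects,
correlated replicate noise, or realistic motif degeneracy. Passing tests
therefore demonstrate correctness of the inference rules and their
implementation — not robustness to the noise structure of real
sequencing data, where peak calling and the q-threshold do real work.

## Problem sizes and runtime

Default test and acceptance runs use the small fixture (2 Mb, 8 TFs; one
end-to-end run ≈ 5 s) and one medium run (10 Mb, 25 TFs, echoing the
25-candidate scale; ≈ 8 s); the full suite completes in about a minute on
one CPU. Coverage arrays are per-chromosome int64 cumulative sums, so
memory scales with chromosome length (~8 bytes/bp per cached track), fine
for these genomes and for scanning NFR-sized sequence sets; scanning a
whole mammalian genome per-base is out of scope.

## Known limitations

* The SE cutoff admits the strongest typical enhancer at the elbow's left
  endpoint by construction; consumers who need exact planted-set identity
  should use the ground-truth intervals, not the flag.
* Interval queries are linear scans per chromosome group — appropriate at
  these scales; no interval tree is built.
* One node per gene symbol: paralogous TFs sharing a matrix are not
  deduplicated (shared matrices are visible in the log).
* The DE table is taken as given (single table, any upstream model);
  no expression quantification or DE fitting is performed.
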