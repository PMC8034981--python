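# Methods

This note documents the models and procedures trimux implements, the
parameter choices that matter, and what the synthetic fixtures do and do
not establish.

## Coordinates and intervals

All genomic coordinates are 0-based half-open (BED / fragment-file
convention); an interval of length L covers `start .. start+L-1`.
Abutting intervals do not overlap, and merging combines only genuinely
overlapping intervals into their outer coordinates (min start, max end of
each connected component) — mirroring GenomicRanges `reduce` with
`min.gapwidth = 0` semantics. Chromosome names match by exact string
equality; a rename map at the BED reader is the only aliasing mechanism.
Overlap queries run against a per-chromosome sorted index (binary search
on starts plus a prefix maximum of ends) whose contract is bit-identical
results to a linear scan; tests enforce this equivalence.

## ADT tag counting

Read 1 carries a 16 nt cell barcode then a 12 nt UMI; read 2 carries the
antibody tag barcode at its 5′ end (a configurable fixed offset supports
chemistry variants). Two barcode-correction modes exist because droplet
ADT libraries and plate-based ATAC libraries used different rules:

- `quality_gated` (default, ADT): a non-whitelist barcode is corrected to
  the unique whitelist member at Hamming distance 1 whose mismatching
  base has Phred quality < 20. No unique qualifying candidate → reject.
  When several low-quality positions each admit a candidate there is no
  defined tie-break, so the read is rejected and tallied.
- `lowest_quality_position` (ATAC): any single mismatch is allowed; among
  multiple candidates the one mismatching at the lowest-quality position
  wins; unresolved ties reject.

Hamming-1 neighbors are enumerated on the fly (≤ 48 lookups per barcode)
against a hash set, so memory stays proportional to the whitelist — the
property that makes multi-million-barcode whitelists feasible. Tag
matching allows one mismatch; the tag list's minimum pairwise distance is
computed at load and a distance < 3 triggers a warning because one
allowed mismatch then no longer guarantees uniqueness. UMIs containing N
are dropped (they cannot be deduplicated reliably) and counted in the run
report. Counts are distinct UMIs per (cell, antibody) — no
distance-based UMI collapsing, matching the exact-unique convention.
Qualities are Phred+33.

## Fragment processing

Single-end reads with alignment score ≥ 30 become fragments spanning the
aligned interval; duplicates are groups sharing (chrom, start, end,
barcode, strand) and the group size is stored as the duplicate count.
Strand is part of the duplicate key for single-end data because a + and a
− read at identical coordinates are distinct transposition events;
paired-end fragments are unstranded. No Tn5 shift is applied when
constructing or storing fragments — stored files stay equal to upstream
output, and shifts happen only inside pileup operations. Overlap counting
gives each fragment one count in every feature it overlaps.

## ATAC quality control

Denominator conventions: mitochondrial fraction is over total fragments
(duplicates included); FRIP, FRITSS and DHS fraction are over unique
fragments. The DHS denominator is unique fragments by analogy with
FRIP/FRITSS (the convention is not otherwise pinned down). Mitochondrial
chromosomes default to {chrM, MT}. TSS windows are anchor ± 2 kb, built
by the interval `expand` helper from single-bp stranded anchors.

Filtering uses strict inequalities — a barcode with exactly 1,000 unique
fragments fails the standard preset. Presets:

| preset    | min unique | FRIP  | FRITSS | DHS  |
|-----------|-----------:|------:|-------:|-----:|
| standard  | 1000       | 0.2   | 0.2    | 0.5  |
| icicle    | 500        | 0.65  | 0.2    | 0.5  |
| tea_atac  | 2500       | 0.2   | 0.2    | 0.5  |

## Tn5 pileups

Each fragment end is one transposition event. The TSD (target-site
duplication) center is the 5′ end + 4 bp, or the last covered base
(`end − 1`, since `end` is exclusive) − 5 bp. The +4/−5 shifts follow the
standard ATAC convention; the alternative +5/−4 convention is available
through parameters. The Tn5 footprint is the 29 bp of accessible DNA
around one insertion (9 bp TSD + 10 bp flanks), modeled as a contiguous
window centered on the TSD center. TSS profiles support two aggregation
modes — `footprint` (default; sums footprint coverage) and
`fragment_coverage` (per-base fragment overlap) — because both
aggregations are in common use and answer slightly different questions.
Offsets are strand-flipped for − anchors so that mirroring every anchor's
strand reverses a profile exactly; footprint regions are clipped at the
window edge and contribute only in-window bases.

## ADT feature filtering and normalization

The isotype control (e.g. mouse IgG1κ) binds no target, so its counts
estimate ambient background. The Mann–Whitney rule tests each feature
one-sided ("greater") against the control across the same cells and
removes features with p > 10⁻⁹. Small tie-free samples use the exact U
null; larger or tied samples use the tie-corrected normal approximation
(the 10⁻⁹ decision threshold is robust to that approximation). Zero rank
variance (e.g. feature identical to a constant control) yields p = 1 by
convention. The fold rule flags a cell when feature/control ≤ 16 and
removes features flagged in > 0.5% of cells; cells with control count 0
use a denominator pseudocount of 1, which can only increase flagging — a
conservative choice the results do not hinge on. The control feature is
always excluded from the retained set.

Normalization: `log10(count / (total/1000) + 1)` per cell, dropping cells
with zero ADT total; this is scale-invariant to per-cell depth and maps
zero counts to exactly 0. A per-feature z-scaling helper prepares the
normalized matrix for embedding.

## TF-IDF LSI

Input is a binarized cell × feature matrix. Features detected in more
than `min_cell_frac` of cells are kept (default 0.03; the plate-based
preset uses 0.005). TF is the row-normalized value, IDF is
n_cells / feature count, and the weight is `log1p(TF · IDF · 10⁴)` — the
scale constant is not pinned down by any convention and is configurable;
10⁴ places typical TF·IDF values where the log transform discriminates.
Truncated SVD uses the deterministic ARPACK backend (no randomized
solver), so embeddings are reproducible without seeding. The first
component correlates almost perfectly with log per-cell depth on matrices
with a depth gradient (|r| > 0.9 in the acceptance checks), which is the
rationale for the default `keep = (2, 30)`; the plate-based preset keeps
2–20. Projection of new cells reuses the stored feature set, IDF and
components; all-zero cells are rejected because their TF is undefined.

## Weighted nearest neighbors

Every modality contributes one embedding with identical cell order
(caller-supplied dimension slicing, e.g. RNA PCs 1–30, ATAC LSI 2–30, all
scaled ADT features). For each ordered pair (α, β), cell i's modality-α
vector is predicted as the mean of the α-vectors of its k nearest
neighbors in β-space (k = 20 by default, self excluded, Euclidean
distances, exact all-pairs backend — approximate backends would need
seeding and are not used here). The affinity kernel is

    θ = exp( − max(d − d_near, 0) / (σ − d_near) )

with d_near the distance to the nearest non-self within-modality neighbor
and σ the distance to the k-th; σ ≤ d_near falls back to a tiny positive
width. The affinity ratio S, softmax weights w (with max subtraction — S
can reach the order of 1/ε = 10⁴, and exp(10⁴) overflows), and weighted
similarity θ_weighted follow the three equations in the README, with
ε = 10⁻⁴. All reductions over modalities (softmax denominator, weighted
similarity) sum in canonical sorted order, making results exactly
invariant to modality ordering rather than merely up to float
reassociation. θ_weighted is not symmetric: the weights belong to cell i.
The final graph scores either every other cell (`all_pairs`) or the union
of each modality's 3·graph_k nearest neighbors; the two agree whenever
the pool covers all cells, which tests verify.

## Peak linkage

Cells are aggregated into overlapping groups (default 100 groups of 20 at
desk scale): seeded anchors plus nearest embedding neighbors, profiles
summed. Pairs are tested when the peak lies within 250 kb of the feature
anchor (the conventional window). Pearson r across groups gets a
two-sided p from the t transform with n_groups − 2 df; BH FDR is applied
over all tested pairs of one kind; links need |r| ≥ 0.05 and FDR ≤ 0.01.
Group overlap induces dependence between aggregate columns, so the FDR is
approximate — the acceptance check measures the realized error rate
(pooled over 20 replicates) against twice the nominal level. Peak-to-
protein links substitute the ADT aggregate matrix for RNA; the tested
pair set is unchanged.

## Synthetic fixtures

All generators are deterministic in (seed, parameters) down to file
bytes. The fragment fixtures use an artificial genome (3 × 10 Mb plus a
16 kb mitochondrial contig), disjoint 500 bp peaks and ±2 kb TSS windows
on a coarse grid (DHS = their union, so the planted DHS fraction is the
sum of the peak and TSS rates), two barcode classes (cell-like:
2,000 fragments at FRIP ≈ 0.55; noise-like: 200 at 0.1) and an
80 bp / 180 bp length mixture. ADT fixtures plant mutations with quality
10 and give all other bases quality 37, making the quality-gated
correction path deterministic; whitelists and tag lists are sampled with
pairwise Hamming distance ≥ 3 so every planted single-base error is
uniquely correctable. Trimodal embeddings displace each group's centroid
by 5 noise-SD units in its informative modality only.

What the fixtures do **not** emulate: real sequence composition, GC or
mappability structure, chromatin biology (peak co-accessibility,
nucleosome phasing), ambient contamination, doublets, or batch effects.
Passing tests therefore establish algorithmic correctness against the
stated rules and oracles — not end-to-end performance on real libraries.

## Problem sizes

The test and acceptance workloads are desk-scale by design: 10⁴ reads
against a 10³-barcode whitelist for counting-oracle equivalence, 10³
fragments × 10² intervals for QC equivalence, 60 cells for equation-level
WNN checks, 300 cells × 20 replicates for weight recovery, 500 cells ×
200 replicates for filter operating characteristics, and 520 peak-feature
pairs × 100 aggregates × 20 replicates for linkage error control. These
sizes exercise every code path and keep the whole suite in seconds while
the algorithms themselves stream or scale to realistic data.

## Known limitations

- The WNN affinity kernel follows the cited two-modality method's family;
  the original modified implementation's exact bandwidth construction is
  not restated anywhere public, so agreement is asserted against this
  package's own specification of the kernel.
- Mann–Whitney p-values near machine precision rely on the normal tail;
  the removal decision at 10⁻⁹ is insensitive to this.
- Linkage FDR control is nominal under group-overlap dependence.
- UMAP, clustering, peak calling, label transfer and doublet detection
  are intentionally out of scope; the package produces their inputs.
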