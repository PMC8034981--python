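# trimux

Toolkit for trimodal single-cell genomics: simultaneous measurement of
transcriptome (RNA), chromatin accessibility (ATAC), and surface-protein
epitopes (antibody-derived tags, ADTs) from the same cells. It covers the
computational steps between raw reads / fragment files and an integrated
multimodal cell graph:

- **ADT tag counting** — UMI counting from paired reads with
  whitelist-based cell-barcode correction (single mismatch at a basecall
  with Phred quality < 20) and tag-barcode matching (one mismatch allowed;
  TotalSeq-A tags are mutually Hamming ≥ 3 apart). UMIs unique within a
  (cell, antibody) pair are counted.
- **ATAC fragment processing and QC** — fragment-file I/O, single-end read
  collapsing, sparse fragment × feature count matrices, per-barcode QC
  (FRIP, FRITSS, DHS fraction, mitochondrial fraction) with strict
  threshold presets, fragment-length spectra, Tn5 footprint pileups at TSS
  (29 bp = 9 bp target-site duplication + 10 bp flanks per insertion), and
  TSD-center pileups at motif windows (+4 / −5 bp end shifts).
- **ADT feature QC and normalization** — isotype-control filtering
  (one-sided Mann–Whitney at p > 10⁻⁹, and a per-cell 16-fold enrichment
  rule) and depth normalization `log10(count / (total/1000) + 1)`.
- **TF-IDF LSI** — binarized term frequency–inverse document frequency
  weighting, log transform, truncated SVD; the depth-correlated first
  component is dropped by default (components 2–30 kept).
- **Weighted nearest neighbors (WNN)** — N-modality integration. With
  per-cell affinity kernel θ and cross-modality kNN predictions x̂:

  ```
  S_α(i) = θ_α(x_i, x̂_i,knn_α) / ( max_{β≠α} θ_α(x_i, x̂_i,knn_β) + ε ),  ε = 1e-4
  w_α(i) = exp S_α(i) / Σ_β exp S_β(i)
  θ_weighted(i, j) = Σ_α w_α(i) θ_α(x_i, x_j)
  ```

  yielding per-cell modality weights and an integrated kNN graph.
- **Peak linkage** — peak-to-RNA and peak-to-protein Pearson correlations
  over aggregated cell groups within a genomic window, with BH FDR
  (defaults corCutOff = 0.05, FDRCutOff = 0.01).
- **Synthetic fixtures** — seeded generators for ADT read pairs, fragment
  files with planted FRIP/length structure, binary accessibility matrices
  with depth gradients, and trimodal embeddings with modality-specific
  clusters, each with ground truth. Everything runs on a small artificial
  genome; no downloads.

## Worked example

Which modality carries the signal for each cell population? Simulate three
populations, each separable in exactly one modality, and integrate:

```python
import numpy as np
from trimux.synthetic import gen_trimodal_embeddings
from trimux.wnn import WeightedNearestNeighbors

emb, truth = gen_trimodal_embeddings(n_cells=300, seed=0)
wnn = WeightedNearestNeighbors(k=20).fit(emb)
labels = np.array(truth.tables["labels"])
for g in range(3):
    mw = wnn.W_[labels == g].mean(axis=0)
    print(f"group {g}: " + "  ".join(
        f"{m}={w:.3f}" for m, w in zip(wnn.modalities_, mw)))
```

```
group 0: rna=0.539  atac=0.237  adt=0.223
group 1: rna=0.233  atac=0.531  adt=0.236
group 2: rna=0.241  atac=0.230  adt=0.528
```

Each group's informative modality receives the largest mean weight
(weights sum to 1 per cell); the uninformative modalities fall back to the
noise floor near 1/3. `wnn.graph_indices_` / `wnn.graph_scores_` hold the
integrated neighbor graph for downstream UMAP or clustering.

The same pipelines are available from the shell:

```bash
trimux simulate fragments --seed 1 --out sim/
trimux atac-qc --fragments sim/fragments.tsv.gz --peaks sim/peaks.bed \
    --tss sim/tss.bed --dhs sim/dhs.bed --preset standard --out qc/
```

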