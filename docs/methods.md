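# Methods

This note documents the modelling choices, parameter semantics, numerical
conventions and known limitations of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Input model and preprocessing

The universal record is a spot × gene matrix of raw nonnegative counts
with 2-D coordinates per spot (`ExpressionDataset`; h5ad with coordinates
in `obsm["spatial"]`, or a CSV/MTX directory). Preprocessing is:

1. **HVG selection** — Seurat-style normalized dispersion: per-gene
   `var/mean` of library-size-normalized counts, z-scored within bins of
   genes of similar mean, ranked descending with ties broken by ascending
   gene index. The conventional 20 mean-bins presuppose genome-wide
   panels; with targeted panels a 3-gene bin makes the within-bin z-score
   quantized noise, so the bin count adapts to keep roughly 20 genes per
   bin. Panels with at most `n_hvg` genes (default 4000) are kept whole —
   the low-plex rule for osmFISH/STARmap-class platforms.
2. **Normalization** — each spot scaled to the median total count of the
   dataset (library sizes computed on the full panel, before HVG
   subsetting), then `log(1+x)`, then per-gene z-scoring with population
   denominator `N`. Genes constant up to float rounding map to all-zero
   columns rather than amplifying noise. Note the consequence of the
   median target: multiplying the whole matrix by `c` rescales the
   normalized matrix by `c` (the *compositions* are invariant, the scale
   is not), while per-spot library-size differences are removed exactly.
3. **Multislice** — each slice runs the full recipe *independently*
   (normalize, subset to the shared genes — the intersection of per-slice
   top-5000 HVGs — log, z-score), and the standardized slices are
   concatenated. Per-slice standardization removes per-gene multiplicative
   slice offsets, the dominant technical batch signature, before the
   slices ever meet; the architecture itself has no explicit
   batch-correction term, so this step is what makes integration work.
   The uncorrected alternative (z-scoring once on the concatenated
   matrix, `per_slice_scale=False`) is retained as the baseline against
   which batch mixing is measured.

## Graphs

Spatial graphs are K-nearest-neighbor (default `K = 6`) under Euclidean
distance, self excluded, symmetrized by union, with distance ties broken
by ascending spot index (deterministic across platforms; exact distance
matrices are used up to 8192 spots, a KD-tree beyond). The default
`K = 6` suits array spot layouts; `K = 4` is a reasonable alternative on
square grids, so `K` is a first-class flag rather than a constant.
Convolution uses
`Ã = D^{-1/2}(A+I)D^{-1/2}` where `D` is the degree matrix **of `A+I`** —
computing degrees on `A` alone would leave isolated nodes undefined, and
with self-loop degrees the spectrum of `Ã` lies in `[-1, 1]` with largest
eigenvalue exactly 1 (unit-tested). Multislice adjacency is block
diagonal; normalization commutes with the block structure.

## Model and objectives

Encoder/decoder are single-layer GCNs (`d = 64`); the topology decoder is
`sigmoid(Z Zᵀ)` (the only shape-consistent reading of an inner-product
decoder that is compared row-wise against the `N×N` adjacency). The
feature decoder's output activation is the **identity**: the input is
z-scored and signed, which a ReLU image could never reconstruct; a ReLU
variant remains available (`decoder_activation="relu"`). The corrupted
view permutes feature rows with a fresh seeded permutation every epoch and
passes through the same topology.

Both contrastive terms consume the 2-layer MLP projection head's output
(`d→d→d`, ReLU between layers); the reconstruction terms consume `Z`/`H`
directly. A config switch (`global_on_projection=False`) lets the global
term consume raw embeddings instead. The temperature `τ = 0.5` is a
conventional graph-contrastive default, exposed in `RunConfig`.

The local loss averages the positive exponentials *inside* the logarithm
(divided by the positive count `N̂_i = 2|N_i| + 1`), exactly as the
printed formula; with an edgeless adjacency it reduces algebraically to
the classical two-view InfoNCE, and the test suite holds it to a
brute-force enumerator on hundreds of random instances.

The readout divides by row sums of the **raw binary adjacency** (no
self-loops). KNN construction guarantees degree ≥ 1; if a degenerate graph
with isolated nodes is supplied (the spatial-ablation baseline), the
training loop falls back to `A + I` row sums so the readout degenerates to
a per-node identity aggregation instead of failing.

## Numerical conventions

* Cosine of a zero-norm vector is 0 (neutral), never NaN; zero rows pass
  through L2 normalization unchanged. A warning is logged when this fires.
* Exponentials in the local loss use per-anchor max subtraction, with
  separate shifts for numerator (max over positive candidates) and
  denominator (max over all candidates, the anchor's self-similarity
  excluded). In the normal regime the numerator reuses the denominator's
  exponentials with a per-row rescale; when the shift gap could overflow
  (pathologically small `τ`), masked re-exponentiation keeps every term
  finite.
* Training is float64 throughout, full-batch, Adam
  (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), no weight decay, no schedule, a fixed
  500 epochs. Two runs with the same seed are bitwise identical.
* Reconstruction is computed on the original view only; the corrupted
  view exists solely for contrast (reconstructing shuffled features would
  be meaningless).
* The autodiff core treats the KNN adjacencies as sparse constants
  (`O(nnz·d)` graph convolutions); gradient correctness is checked against
  central finite differences at relative 1e-4 on a frozen instance chosen
  away from dead-ReLU degeneracies, where the loss is genuinely smooth.

## Clustering and refinement

PCA reduces `H` to 20 components (deterministic sign: largest-magnitude
loading positive; the component count is capped by the centered rank of
`H`, which small-embedding runs can undershoot). With a known domain
count, a tied-covariance Gaussian mixture (the mclust "EEE" analogue) is
fitted by EM from eleven starts — ten seeded k-means restarts plus one
Ward-tree partition, the hierarchical start mclust itself uses — keeping
the highest-likelihood fit; k-means starts alone were observed to land in
a poorer optimum on one synthetic seed that the Ward start avoids (and the
likelihood criterion itself prefers the Ward fit there). Without a known
count, Leiden (RB-configuration, resolution 0.5) runs on a 15-NN graph of
the embedding, labels sorted by community size.

Refinement is a single majority-vote pass: each spot's neighborhood is
every spot within radius `r = 50` **in the dataset's native coordinate
units**, itself included; ties keep the current label. A radius below the
minimum spot spacing silently disables refinement — check your units. For
concatenated multislice data refinement runs within each slice (slices
occupy overlapping coordinate frames).

## Evaluation metrics

ARI and NMI delegate to scikit-learn; NMI normalizes by the arithmetic
mean of entropies. The unsupervised metrics follow the standard
literature definitions with all free parameters pinned: iLISI (inverse
Simpson over batch proportions among `k = 30` embedding neighbors, ties
broken by index; 1 = unmixed, B = perfectly mixed), PAS (fraction of spots
disagreeing with the modal label of their 10 nearest spatial neighbors),
CHAOS (mean within-cluster 1-NN distance on z-scored coordinates;
singleton clusters are skipped with a warning). These parameter values are
this package's choices, not extracted constants.

## Synthetic data: what it emulates and what it does not

The generator plants contiguous domains (7 horizontal stripes by default,
echoing layered cortex; Voronoi blobs as an alternative) on a jittered
square grid — spacing 20 units, jitter ±2 — and draws negative-binomial
counts: baseline mean 1.0 per gene, shape 2.0 (variance `μ + μ²/2`,
matching typical ST overdispersion), with 10 disjoint marker genes per
domain elevated by `exp(log_fold_change)` (default `e¹ ≈ 2.7`) inside
their domain. Per-slice batch effects multiply every gene's mean by
`exp(Normal(0, batch_sigma))`. Labels are assigned before any noise, so
ground truth is exact.

This emulates: spatial contiguity, domain-specific programs, count
overdispersion, and purely technical between-slice scaling. It does *not*
emulate: platform mean–variance trends, spatial gradients within domains,
segmentation errors, histology, or compositional (cell-type mixture)
effects. Passing the synthetic benchmark therefore demonstrates correct
mechanics and sensible inductive behavior, not performance on real tissue.

## Problem sizes used in the checks

The end-to-end checks run at 625 spots × 200 genes (single slice, 5 seeds,
full 500-epoch training, with an identity-adjacency ablation control) and
2 × 625 spots for integration; the tool-determinism check uses a 225-spot
slice at 120 epochs, since determinism is scale-free. With ~3.6-row
stripes and `K = 6`, errors concentrate at stripe boundaries where graph
smoothing genuinely mixes adjacent domains; the ablation control (identity
adjacency) collapses toward chance, showing the spatial graph carries the
signal.

## Known limitations

* The reconstruction objective sums `N` adjacency entries per spot but
  only `M` feature entries, so the topology term's effective weight grows
  linearly with graph size at fixed `(α₁, α₂)`. The formula is kept as
  stated; in the two-slice integration check (1250 spots) this measurably
  degrades the domain structure of the reconstructed expression relative
  to single-slice runs, and batch mixing (iLISI) is the integration
  property that holds robustly. A per-entry-mean normalization would be
  scale-free but would change the stated objective.
* Dense `N×N` similarity matrices in the contrastive losses bound
  practical problem sizes to a few thousand spots per training run on one
  CPU core; the graph convolutions themselves are sparse.
* The inner-product topology decoder composed with a ReLU encoder cannot
  emit edge probabilities below 0.5 (nonnegative inner products), so the
  adjacency reconstruction term acts mainly by orthogonalizing non-neighbor
  embeddings — a property of the printed architecture, kept as printed.
* The multislice path assumes shared gene namespaces across slices and
  removes batch effects only implicitly (shared encoder + contrastive
  objectives); there is no explicit alignment.
* Leiden's community count at a fixed resolution depends on the embedding
  scale; with a known domain count prefer the GMM path.
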