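# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions a user may need when comparing
results against another implementation.

## Data model

The unit of analysis is an *m* cells × *n* analytes matrix of strictly
positive levels in arbitrary fluorescence units, with one ordinal day label
per cell (default day set {0, 1, 3, 5}). Day labels only ever enter through
their order — no stage uses elapsed time quantitatively. Column order
defines the analyte index everywhere; nothing reorders columns silently.

Background-subtracted fluorescence can in principle be ≤ 0. The default is
hard rejection at validation, because silently repaired values usually
indicate an upstream problem; an explicit floor ε > 0 may be configured to
clamp values before the log transform. All analysis operates on natural-log
levels. Optional per-analyte z-scoring (population sd) is provided as a
robustness path; it is not applied by default.

## Surprisal decomposition

The log matrix is decomposed by SVD *without centering*: the leading
component is the steady state and components 2..J+1 are deviation modules
1..J (default J = 2). Scores carry the singular value (λ_j = u_j s_j, so
influence scores are comparable across cells), loadings are unit vectors.
A `center=True` flag exists for comparison with conventional PCA.

Sign conventions are deterministic: every component is oriented so its
largest-|loading| analyte has a positive loading, and module 1 is flipped
if needed so its mean score rises from the first to the last day. Module
numbering follows singular-value order, which presumes the time module
carries more variance than the path module — true of the planted defaults
and of the motivating data. For path assignment the pipeline re-orients the
module-2 score so it correlates non-positively with the lineage marker
MITF (`orient_scores_by_marker`); with that convention MITF-high cells have
negative module-2 scores and the upper path is the majority-negative side.

Module count J = 2 is a default, not an inference: a scree table is always
emitted, and no automatic selection is attempted.

Parameter recovery is judged after the best 2×2 orthogonal (Procrustes)
alignment of estimated onto planted scores, because an SVD pair of
components with close singular values is identified only up to rotation
within their subspace.

## Trajectory graph

A sequential k-NN graph: each cell is joined to its `k_intra` nearest
same-day cells and `k_inter` nearest cells in each adjacent day (Euclidean
distance on log levels), and the union of directed neighbour lists is kept
as a simple undirected graph with weights 1/(d + 1e-8). Published
graph-based time-course visualizations of this kind add density-dependent
edge pruning; that refinement is intentionally not reproduced, and layouts
(seeded spring embedding) are for qualitative reading only. Single nodes
are placed at the origin.

## Clustering

Cells are split by day and clustered with Ward-linkage agglomerative
clustering on the log levels of a 10-marker subset (Ki67, MART1, HIF1a,
LDH, p-AMPKα, p-ERK, PFK, p-ACAC, Slug, p-LKB) — Ward because it is the
default of the hierarchical clustering package the original analysis used,
which names the package but not the linkage. Per-day k comes either from a
fixed map or from the elbow of the within-cluster sum-of-squares curve
along nested cuts, operationalized as the k with the largest discrete
second difference WSS(k−1) − 2·WSS(k) + WSS(k+1); ties go to the smallest
k. "Elbow method" is otherwise ambiguous, so the full WSS curve is always
saved for manual override. Total cluster counts (e.g. 14) are treated as
data-dependent output, never as a target.

## Criticality indices

Within a cluster, on the same 10-marker subset by default:

* SNAI = 1 / det(R), R the analyte–analyte Pearson correlation matrix.
  det(R) ∈ (0, 1] for any valid correlation matrix, so SNAI ≥ 1. The
  log-determinant is reported alongside, and a cluster is flagged
  *degenerate* when det < 1e-12 — in particular whenever the cluster has
  no more cells than analytes, where the sample determinant is exactly or
  numerically zero regardless of population structure. Degenerate clusters
  are excluded from tipping-point argmax comparisons for **both** indices;
  no ridge regularization is ever applied silently. The 10-marker default
  exists precisely to keep realistic cluster sizes above the analyte
  count.
* Ic = mean |Pearson r| over analyte pairs divided by mean |Pearson r|
  over cell pairs. Absolute values follow the index's original definition.
  A signed variant is exposed. Ic defaults to the same analyte set as SNAI
  so that agreement between the indices is a comparison on common
  variables.

Pearson is used for both indices (Spearman variants are exposed) since the
determinant-based index is defined on product-moment correlations. Path
labels per cluster come from the majority sign of the (MITF-oriented)
module-2 scores; exact ties stay unassigned with a warning. The tipping
candidate is the per-path argmax over non-degenerate clusters; ties raise
an error rather than silently picking.

A practical caveat measured on synthetic data: with clusters of ~25 cells
the sample determinant is strongly size-biased, so SNAI comparisons are
most meaningful between clusters of similar size (as per-day clustering
naturally produces), and Ic's mean-|r| numerator only resolves factors
whose footprint covers several pairs of the index's analyte set.

## Correlation networks

Per cluster, Spearman ρ for every unordered analyte pair (average ranks on
ties), two-sided p-values from the t approximation with n − 2 degrees of
freedom (an exact-style seeded permutation option exists for very small
clusters), and an edge kept iff p ≤ α / (p(p−1)/2) — a per-network
Bonferroni family, α = 0.05 by default. Constant analytes stay in the
family but their pairs are never significant (conservative). Node degree
counts significant incident edges. The hub score is the principal
eigenvector of the |ρ|-weighted significant adjacency, computed by power
iteration from the degree vector with a positive diagonal shift (the shift
leaves eigenvectors unchanged but makes the dominant eigenvalue unique in
magnitude, so the iteration also converges on bipartite graphs such as
stars); disconnected networks are scored globally by the dominant
eigenvector. Signed ρ is kept on edges for display; centralities use |ρ|.
Degree and hub scores are min–max rescaled to [0, 1] per network for
side-by-side comparison; an all-equal metric rescales to zeros with a
warning.

## Synthetic data generator

The generator emulates an antibody-barcode-chip snapshot series over four
treatment days for a 20-analyte panel spanning six functional categories.
Per-cell log levels are

```
ln X(c) = g0 + λ1(c)·g1 + λ2(c)·g2 [+ f(c)·h] + ε ,   ε ~ N(0, noise_sd²) i.i.d.
```

with every structural element returned as ground truth.

* **Steady state** g0: per-analyte baselines spread over 5–8 log units.
* **Time module** g1: proliferation and oncogenic-signaling markers load
  negatively, resistance markers positively. λ1 follows a strictly
  increasing per-day schedule, default (−1, −0.4, 0.4, 1), crossing zero
  between the intermediate days; per-cell jitter sd is 10% of the schedule
  range.
* **Path module** g2: melanocytic markers (MITF, MART1, Ki67, PFK, Slug)
  load negatively, mesenchymal/resistance markers positively. Each cell
  carries a permanent path label (Bernoulli, p_high = 0.5; no switching,
  matching the reported absence of stochastic interconversion), and
  λ2 = ∓0.7 (high path negative) plus 10% jitter. The module amplitudes
  are deliberately comparable, with the time module moderately dominant
  (score-variance ratio ≈ 1.3): this matches the displayed influence-score
  scales of the motivating study and keeps the SVD component order equal
  to the module numbering. Both g1 and g2 are orthogonalized against the
  steady-state direction and each other — constraints are deviations from
  the steady state.
* **Tipping clusters**: at day 3 (the intermediate window where the
  transition happens), 60% of each path's cells additionally share a
  latent factor f·h with f ~ N(0, 0.8²). The loading h is uniform over the
  subnetwork that path's near-critical state engages: for the upper path
  the melanocytic/metabolic hub set (MITF, PFK, PKM2, LDH, p-LKB, Slug)
  plus MART1 and Ki67; for the lower path the TNFR/N-cadherin/p-NFκB hub
  set plus a stress axis (HIF1α, p-ERK, p-AMPKα, p-ACAC). The factor
  amplitude is comparable to the module amplitudes, consistent with the
  sharp transitory variance burst reported at the intermediate day. This
  planting raises analyte–analyte correlation and lowers cell–cell
  correlation in the flagged cells — the statistical signature both
  indices are built to detect — and gives each factor support inside the
  10-marker index set.
* **Noise**: log-normal measurement noise (Gaussian in log space),
  sd 0.1 by default. No noise model is published for this assay class;
  log-normality is the standard assumption for fluorescence immunoassays
  and is stated here as an assumption.

Identical configuration and seed give bit-identical output.

What the generator does **not** emulate: day-to-day changes in noise
level, analyte-specific detection floors and saturation, doublet/empty
chamber artifacts, cell-cycle covariation beyond the planted modules, path
switching, and any drug-perturbation response. Passing tests therefore
demonstrate that the pipeline recovers planted low-rank and
critical-transition structure at realistic scale and noise — not that any
particular biological dataset contains such structure.

### Size-matched signature checks

Mean |r| over pairs is biased upward in smaller groups (the null scale is
≈ 0.8/√n). Tests that compare tipping against non-tipping cells therefore
subsample the larger group to the smaller group's size before comparing,
and average over ≥ 20 seeds.

## Pipeline

Stages run in analysis order (simulate/read → log → decomposition → graph →
per-day clustering → criticality → tipping networks). One global seed fans
out to per-stage seeds via a CRC32 hash of the stage name, so any stage can
be reproduced in isolation. The summary (JSON, sorted keys) contains the
seed, a configuration hash, per-day k, and per path the tipping cluster
with its indices and top-3 hub analytes; two runs with the same
configuration and seed are byte-identical. Stage failures abort with the
stage name; artifacts written before the failure are retained.

## Problem sizes used in validation

The validation studies run at 50 cells/day (simulation studies of tipping
detection, 50 seeds), 100–150 cells/day (recovery and differential-hub
checks, 20 seeds), and the full per-day counts (156/185/162/171) for
paper-scale checks. These sizes make the whole suite and the acceptance
script complete in a few seconds while leaving all measured rates well
clear of their thresholds.

## Known limitations

* SNAI's raw determinant is size-biased; comparisons across clusters of
  very different sizes are not meaningful, and clusters with ≤ p cells are
  structurally degenerate. A bias-corrected variant is deliberately out of
  scope (the published index is the plain reciprocal determinant).
* Ic's numerator needs the shared factor to cover several pairs of the
  chosen analyte set; a factor concentrated on analytes outside that set
  is visible to SNAI (through the determinant) long before it moves Ic.
* The exact edge rules of the published time-course graph visualization
  are not reproduced; graph output is qualitative.
* Which analyte set the original analysis used for the indices, and
  whether any background floor preceded its log transform, are not stated
  in the source; the defaults here (10-marker indices, hard rejection) are
  documented choices, both overridable.
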