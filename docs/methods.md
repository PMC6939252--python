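# Methods

This note records the models, conventions and numerical choices behind
`arcmorph`, in the spirit of a package vignette: what is computed, under
which assumptions, and where genuinely open design choices were settled.

## Superimposition

Generalized Procrustes analysis operates on the classical full-Procrustes
convention: every configuration is centred, scaled to unit centroid size,
and rotated to the running consensus; the consensus is the arithmetic mean
of the aligned shapes rescaled to unit size. Only proper rotations
(determinant +1) are allowed — mirroring left and right skeletal elements
onto one another is a data-preparation decision (the I/O layer offers
`reflect_configuration`, with right-side elements reflected to left by
default), never something the optimizer should do silently.

Convergence is declared when the mean per-landmark consensus displacement
falls below `tol` (default 1e-10, `max_iter` 100); non-convergence is
flagged on the result rather than raised, since a nearly-converged
superimposition is still interpretable.

**Semilandmark sliding.** Semilandmarks slide along the unit chord joining
their neighbours, by the signed projection of (consensus − current point)
onto that chord — the one-dimensional least-squares optimum, i.e. the
Procrustes-distance criterion. Sliding is interleaved with consensus
updates (three sliding passes per outer iteration, each followed by
re-centring, re-scaling and re-rotation). Two facts shape the schedule:

1. Sliding leaves the semilandmarks' positions *along* the curve
   unconstrained — a soft mode. Interleaved sliding therefore approaches
   its fixed-point manifold only geometrically (observed contraction rate
   ≈ 0.998 per iteration), and no practical iteration cap reaches a 1e-10
   tolerance while sliding stays active. Sliding is frozen once it has
   effectively converged — when the consensus change stops improving
   between outer iterations (ratio > 0.9) or drops below `slide_tol`
   (1e-7) — after which plain GPA iterations finish the convergence.
2. Because the soft mode makes the solution set a continuum, which point
   of it is reached depends on the iteration path. The path is therefore
   kept exactly rotation-equivariant when sliders are present (consensus
   initialized from the first configuration), so superimposing rigidly
   transformed copies of a dataset lands on the *same* solution to machine
   precision. Without sliders the fixed point is unique and the consensus
   starts from the raw mean, which lets an already-superimposed dataset
   reconverge in a single iteration.

The final solution is rotated to a canonical pose anchored on landmark
geometry (first distinct landmark pair along +x; in 3-D the first
off-baseline landmark pins the x–y plane). Principal-axis poses were
rejected: for near-symmetric shapes (tooth outlines, symmetrized crania)
their sign conventions sit on a knife edge and flip under perturbation.

A known convergence limitation: for two shapes near the maximum possible
Procrustes distance (√2 for unit shapes) the alternating rotation updates
contract arbitrarily slowly. This regime is far outside morphometric use —
conspecific skeletal elements have Procrustes distances well below 1 — and
the closed-form two-shape solution (normalized midpoint of the OPA pair)
remains the fixed point throughout.

**Symmetrization.** Configurations with object symmetry are replaced by
their symmetric component: reflect one axis, swap paired left/right
labels, rotate the mirrored copy onto the original, average. The operator
is idempotent and its output is a fixed point of reflect-and-relabel. It
is applied to crania only (per-element configuration).

Downstream analyses use Procrustes coordinates directly, without a formal
tangent-space projection — the usual small-variation approximation, which
also means group Procrustes variances are computed as Euclidean variances
in the common aligned frame.

## Ordination and dimensionality reduction

PCA is on the covariance matrix (coordinates share units; correlation
scaling would distort shape space). Form space appends one unscaled
natural-log centroid-size column to the flattened Procrustes coordinates;
with purely isometric variation this column carries PC1 entirely, which is
the intended reading. Components with variance below 1e-12 of the total
are dropped; loading signs follow a largest-element-positive convention so
runs are reproducible.

Retained components for testing and classification: the smallest count
reaching a cumulative-variance threshold (default 0.90), capped at
(smallest group size − 1) so pooled within-group covariances remain
invertible, never fewer than 1. The count actually used is recorded in
every report; it is selected once per comparison dataset, not per balanced
replicate (reproducibility and cross-replicate comparability; per-replicate
re-selection is available behind a flag and off by default).

## The test battery

* **Size** — two-sided Wilcoxon rank-sum on log centroid size. The
  reported W is the Mann–Whitney U of the first group. Exact enumeration
  p when n₁+n₂ ≤ 12 without ties; otherwise the normal approximation with
  tie and continuity corrections.
* **Size variance** — Fligner–Killeen (normal scores of ranks of absolute
  deviations from group medians), χ² with (groups − 1) df.
* **Shape / form** — one-way MANOVA on retained PCs: Wilks'
  Λ = det(W)/det(W+B), Rao's F approximation. Λ ≥ 1 (numerically) is
  reported as F = 0, p = 1.
* **Allometry** — multivariate linear model of PC scores on group,
  log size and their interaction; the interaction block (equality of
  allometric slopes) is tested by Wilks' Λ with hypothesis df (g − 1) and
  error df (n − 2g). Fitted via residual SSCP differences of the nested
  models; cross-checked against an independent MANOVA implementation in
  the tests.
* **Shape variance** — per-group Procrustes variance with the (n−1)
  denominator; the statistic d_var is the absolute difference, its null
  distribution obtained by permuting group labels. Permutation p-values
  count the observed statistic in numerator and denominator,
  p = (1 + #{perm ≥ obs}) / (n_perm + 1), so p is never 0. Default
  n_perm = 10 000; a warning is issued below 100.

Multiple comparisons are corrected per element table across all blocks of
all configured pairs (Benjamini–Hochberg step-up by default; Holm and
Bonferroni available); the method used is recorded in the report, and both
raw and adjusted p-values are emitted.

## Classification and phenograms

LDA uses the pooled within-group covariance with equal priors; a held-out
specimen is assigned to the nearest group mean in Mahalanobis distance.
Balanced cross-validation subsamples every group without replacement to
the global minimum group size, runs leave-one-out CV, and repeats 100
times; the summary is the replicate mean with the empirical 5th/95th
percentiles as the 90% interval. Size is cross-validated the same way as a
one-dimensional LDA on log centroid size.

Mahalanobis distances between group means (reported as D, not D²) feed a
Saitou–Nei neighbour-joining tree. NJ on non-additive distances can
produce negative branch lengths; these are clamped to zero with the
deficit transferred to the sister branch, preserving the joined pair's
path length. Discriminant-axis visualization back-projects the
(S⁻¹ Δμ) axis from retained-PC space through the PCA loadings and displaces
the grand mean shape ±3 pooled discriminant-score SDs by default.

## Haplotype differentiation

F_ST is the G_ST form on haplotype frequencies: (H_T − H_S)/H_T with H_S
the sample-size-weighted mean within-group gene diversity and H_T the
pooled diversity; it returns 0 for a monomorphic pooled sample. The
unbiased n/(n−1) correction is available (and the default for point
estimation); the permutation test uses the plug-in form so the statistic
is a pure frequency contrast, and permutes specimen labels (not counts),
matching individual-based sampling. The estimator name is recorded in
every result.

## Synthetic data

The generator mirrors exactly the structure the analysis assumes: per
specimen, shape = template + group mean-shape offset + allometric slope ×
(log size − group log-mean) + isotropic i.i.d. Gaussian landmark noise;
the shape is then scaled to a log-normally drawn centroid size (so log CS
is Gaussian, as analysed) and given a random rigid motion, which GPA must
undo. Scalar offsets draw a random centred direction of that magnitude;
ground truth (realized offsets, slopes, sizes) is returned for recovery
testing. Templates: an elliptical outline with two fixed endpoints and
equally spaced sliding semilandmarks (tooth-outline design), a 15-landmark
2-D mandible, and a 30-landmark 3-D cranium with 12 bilateral pairs and 6
midline points.

Defaults represent a clean, well-digitized assemblage: landmark noise SD
0.02 in unit-centroid-size template units, log-size SD 0.1, specimen
centroid sizes around e⁴ ≈ 55 mm. What passing tests on such data show is
that the *pipeline* is correct and calibrated; they do not exercise
digitization error structure, missing landmarks, fragmentary specimens or
correlated measurement noise, all of which real assemblages have. Missing
landmarks are deliberately unsupported (specimens are excluded with a
warning) — no estimation step is implemented.

## Validation problem sizes

The acceptance checks run at sizes chosen to keep the full validation
sweep fast while leaving Monte-Carlo error well inside the asserted
margins: 200 random-rigid-motion trials for superimposition invariance,
1000 simulations per null for test calibration (permutation tests at 199
permutations, where rejection at α = 0.05 is exactly achievable), 100
balanced-CV replicates, offset-recovery at n = 50 and 100 per group, and
20 null datasets for the end-to-end corrected-significance sweep. The
standalone acceptance script uses 400 simulations per null and 10 null
datasets.

## Known limitations

* Procrustes-distance sliding only; bending-energy sliding is out of scope.
* No tangent-space projection; variance comparisons assume small shape
  variation.
* No missing-landmark estimation.
* NJ trees carry no bootstrap support.
* The MANCOVA allometry test can be anticonservative when the retained PC
  count approaches the smallest group size; the PC cap mitigates but does
  not remove this.
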