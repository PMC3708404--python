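# Methods

## Problem setting

A stack of M co-registered, same-shape intensity volumes (dense 3rd-order
tensors, e.g. CT liver volumes after shape normalization) is to be
represented compactly so that (i) individual volumes can be reconstructed
from few numbers, (ii) plausible novel volumes can be synthesized, and
(iii) two groups (e.g. normal vs abnormal organs) can be classified from
the representation. Sample counts in this setting are tiny (tens) while
the ambient dimension is millions of voxels, so classical PCA on flattened
volumes is hopelessly under-determined; multilinear models that share
structure across modes are the standard answer.

## GND-PCA (shared Tucker subspace baseline)

Each centered sample `A_i - mean` is approximated in a shared multilinear
subspace: one orthonormal factor matrix `U^(n)` of shape `I_n x J_n` per
mode, and a per-sample core `B_i = (A_i - mean) x_0 U^(0)^T ... x_{N-1}
U^(N-1)^T`. The factors maximize the captured energy `S' = sum_i
||B_i||^2`, equivalent to least-squares reconstruction. With all factors
but mode n fixed, the optimal `U^(n)` is the top-`J_n` eigenvector block of
the accumulated mode-n scatter of the partially projected samples, so the
fit alternates exact per-mode eigen-updates (higher-order orthogonal
iteration). Consequences used by the tests: `S'` is non-decreasing across
sweeps; the projection is orthogonal, so per sample `||centered||^2 =
||core||^2 + ||residual||^2`; and for matrix ensembles with a full
trailing-mode factor the leading-mode factor spans the top left-singular
subspace of the horizontally stacked data.

Numerical choices: HOSVD-style initialization (leading eigenvectors of the
raw mode-n scatters) — deterministic and close to the fixed point;
symmetric eigendecomposition of the `I_n x I_n` scatter rather than SVD of
the wide unfolding (equivalent, memory-bounded); convergence when the
relative change of `S'` drops below `tol = 1e-9` or after `max_sweeps =
50`; eigenvector signs pinned so the largest-magnitude entry is positive
(reproducibility across LAPACK backends); within a degenerate eigenvalue
the factor columns are unique only up to rotation, and descending
eigenvalue order plus the sign rule is the documented tie-break.

## Linear tensor coding (greedy rank-one deflation)

The coding replaces the shared core/factor structure by an ordered list of
unit-norm rank-one basis tensors `B_j = u_j^(0) o ... o u_j^(N-1)` common
to the ensemble, with one scalar coefficient per sample and basis:

    A_i = mean + sum_j c_{i,j} B_j + residual_i.

Extraction is greedy: the best shared rank-one direction of the current
residuals is the rank-(1,...,1) GND-PCA fit (leading eigenvector per
mode); the coefficient is the full mode-product contraction of the
residual with those unit vectors, which equals the inner product with the
basis tensor; each residual is then deflated by its fitted component, and
the loop repeats until `sum_i ||residual_i||` falls below a threshold `r`
(absolute, or relative to the initial centered norm) or a basis budget is
reached. Deflation along a unit direction gives the per-step Pythagoras
identity `||r||^2 = c^2 + ||r - cB||^2`, so the summed residual trace is
non-increasing; with a single basis the model *is* rank-(1,...,1) GND-PCA.

The bases are not orthogonal to each other in general — greedy rank-one
deflation is not an orthogonal decomposition — so coefficients of any
sample (training or held-out) are computed by the same sequential
deflation, never by independent per-basis projections. Earlier bases are
never refit; global optimality is not claimed. A relative residual below
`1e-12` is treated as exact zero and stops extraction (accumulated
round-off of exact deflations sits above raw machine epsilon). Each
basis's sign is chosen so its coefficient column has non-negative mean;
reconstructions are invariant to the flip.

Default basis budget is 1200 (appropriate to full-resolution volumes);
all synthetic experiments in this repository use 3–40 bases at shapes
16x16x8 to 24x24x24, which keeps every test and the acceptance script in
the tens of seconds while exercising the same code paths.

## Statistical texture model

Modeling each coefficient column as Gaussian across the ensemble gives a
per-basis mean `m_k` and sample standard deviation `lambda_k` (n−1
denominator; unspecified upstream, chosen as the unbiased-variance
convention). A novel volume along basis k is `mean + c~ B_k` with the
adjusted coefficient constrained to `|c~ - m_k| <= 2 lambda_k`; sweeps
default to ±1.5 lambda. The band is centered at `m_k` by default — after
mean-centering the training coefficients `m_k` is near zero, so this
coincides in expectation with the zero-centered literal band, which
remains available via `center="zero"`. Out-of-band values are clamped with
a warning (or rejected under `strict`). Visual output uses the central
frontal slice by default; the slice choice is qualitative only.

## Basis selection and classification

Each basis receives the Pearson correlation between its coefficient
column and the ±1 label vector (point-biserial correlation, since labels
are binary). Bases are ranked by |r| descending — an anti-correlated basis
is exactly as discriminative as a correlated one — with ties broken by
lower index; a constant column ranks last with r = 0. Classification uses
leave-one-out cross-validation with a linear SVM (C = 1) or KNN (k = 3);
features are z-scored on the training part of every fold because the
coefficient scales decay by construction and distance/margin classifiers
are scale-sensitive. Hyperparameters are exposed but unremarkable at these
sample sizes.

The end-to-end driver supports two fold-hygiene modes. The default refits
the coding and the selection inside every fold, so the held-out sample
never influences its own features. The "pooled" mode fits the coding and
the selection once on all samples and cross-validates only the classifier;
it is cheaper and matches how such pipelines are commonly run on small
clinical ensembles, at the cost of optimistic selection bias. Both are
first-class and reported explicitly.

## Synthetic ensembles

The generator emulates a registered two-group volume database: a smooth
mean texture (Gaussian-filtered noise over a constant background, default
level 100 ± 20 — arbitrary intensity units), planted unit-norm rank-one
bases whose per-mode factor vectors are drawn orthonormal (QR of a seeded
Gaussian matrix), shared-variation coefficients `N(0, (base_sigma *
decay^j)^2)` with a geometric spectrum, class-linked coefficients `label *
effect/2 + N(0, class_sigma^2)`, and i.i.d. Gaussian voxel noise. Defaults:
16x16x8 voxels, M = 20 balanced samples, five shared bases (sigma 10,
decay 0.7), one class basis (effect 2, sigma 0.25), noise 0.1 — a
desk-scale stand-in for a 10-vs-10 organ database.

Per-mode orthogonality of the planted factors makes the basis tensors
mutually orthogonal, so exact greedy recovery is well-posed; recovery
tests rely on this, and greedy deflation need not recover non-orthogonal
planted structure. What the generator does **not** emulate: anatomy,
registration error, spatially correlated noise, intensity
non-stationarity, non-Gaussian coefficient distributions. Passing tests
therefore demonstrate algorithmic correctness and the selection
mechanism's behavior under the model's own assumptions, not clinical
performance.

Two fixed benchmark conditions are frozen in `ltcvol.synthetic`:

- `discriminant_benchmark_spec`: 24^3 voxels, M = 20, twenty nuisance
  bases (sigma 10, decay 0.85), two class bases (effect 2.5, within-class
  sigma 0.3), noise 0.3; the coding extracts 40 bases and the top 5 by
  |r| are selected. The discriminative directions carry a tiny fraction of
  the total variation, so classifiers fed all 40 coefficients are diluted
  by nuisance features while the selected subset separates the groups —
  the regime the selection mechanism exists for.
- `null_benchmark_spec`: pure noise, no planted structure; accuracy must
  sit at chance.

## Known limitations

- Greedy coding offers no global-optimality or uniqueness guarantees; on
  data whose structure is far from per-mode-orthogonal, recovered bases
  mix planted directions.
- The rank-one inner solver converges slowly on noise-dominated residuals
  (tiny eigen-gaps); the deflation loop accepts the iterate at the sweep
  cap, which is harmless for coding purposes but means late bases are not
  exact stationary points.
- Encoding held-out samples reuses training bases; no out-of-sample basis
  adaptation is attempted.
- Dense storage only; volumes at clinical resolution (~5M voxels) fit
  comfortably, but the per-basis full-volume outer products make very
  large basis budgets I/O- and memory-heavy.
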