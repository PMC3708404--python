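"""Linear tensor coding: greedy extraction of rank-one basis tensors.

Each sample in an ensemble of same-shaped tensors is represented as a
linear combination of shared unit-norm rank-one bases around the ensemble
mean:

    A_i = mean + sum_j c_{i,j} * B_j + residual_i,
    B_j = u_j^(0) o u_j^(1) o ... o u_j^(N-1)   (outer product, unit factors).

Bases are extracted one at a time by a greedy deflation loop: fit the best
shared rank-one direction of the current residuals (a rank-(1,...,1)
GND-PCA), record one coefficient per sample (the inner product of its
residual with the new basis, equivalently the full mode-product contraction
for unit factors), subtract the fitted component from every residual, and
repeat until the summed residual norm drops below a threshold or a basis
budget is exhausted.

The deflation is greedy: earlier bases are never refit, and the bases are
not orthogonal to each other in general, so coefficients of a new sample
must be computed by the same *sequential* deflation (see :func:`encode`),
not by independent inner products against each basis.  With a single basis
the model coincides with rank-(1,...,1) GND-PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gndpca import fit_gndpca, reconstruct as gndpca_reconstruct, project_core
from .tensor_core import RankOneBasis, as_tensor, inner_product, tensor_norm

__all__ = ["LTCModel", "fit_ltc", "encode", "decode", "reconstruction_quality"]


@dataclass
class LTCModel:
    """Fitted linear tensor coding model.

    Attributes
    ----------
    mean
        Ensemble mean texture (zero tensor when fitted with
        ``subtract_mean=False``).
    bases
        Ordered unit-norm rank-one bases, in extraction order.
    coefficients
        ``(M, J)`` training coefficients; entry ``(i, j)`` is the inner
        product of sample i's step-j residual with basis j.
    residual_trace
        Summed residual norms ``sum_i ||residual_i||``; entry 0 is the
        centered data itself, entry j the total after j bases.  Strictly
        non-increasing.
    threshold
        The stopping value ``r`` the fit was run with (absolute sum of
        residual norms, or a fraction of the initial sum when
        ``relative`` is set).
    """

    mean: np.ndarray
    bases: list[RankOneBasis] = field(default_factory=list)
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    residual_trace: list[float] = field(default_factory=list)
    threshold: float = 0.0
    relative: bool = False
    subtract_mean: bool = True

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mean.shape

    @property
    def n_bases(self) -> int:
        return len(self.bases)

    @property
    def n_samples(self) -> int:
        return self.coefficients.shape[0]


def fit_ltc(
    samples: Sequence[np.ndarray],
    max_bases: int = 1200,
    threshold_r: float = 0.0,
    relative: bool = False,
    subtract_mean: bool = True,
    gndpca_opts: dict | None = None,
) -> LTCModel:
    """Greedy rank-one decomposition of a tensor ensemble.

    Parameters
    ----------
    samples
        M same-shaped tensors.
    max_bases
        Maximum number of bases to extract.  The default mirrors the basis
        budget used for full-resolution medical volumes; small synthetic
        problems need far fewer.
    threshold_r
        Stop once ``sum_i ||residual_i|| <= threshold_r``.  An absolute
        threshold is scale-dependent; with ``relative=True`` the stop rule
        is ``sum_i ||residual_i|| / sum_i ||centered_i|| <= threshold_r``
        instead.
    gndpca_opts
        Options (``tol``, ``max_sweeps``) forwarded to the inner
        rank-(1,...,1) GND-PCA solver.

    Notes
    -----
    Sign convention: each basis is flipped so that the sample-mean of its
    coefficient column is non-negative, which keeps coefficient scatter
    plots reproducible (the reconstruction is invariant to the flip).  If
    the total residual falls below machine epsilon mid-loop, extraction
    stops early and the basis list is truncated.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    if max_bases < 1:
        raise ValueError("max_bases must be >= 1")
    if threshold_r < 0:
        raise ValueError("threshold_r must be >= 0")
    opts = {"tol": 1e-9, "max_sweeps": 50}
    opts.update(gndpca_opts or {})

    data = np.stack([as_tensor(s) for s in samples])
    m = data.shape[0]
    mean = data.mean(axis=0) if subtract_mean else np.zeros(data.shape[1:])
    residuals = data - mean

    def total_norm() -> float:
        return float(sum(tensor_norm(residuals[i]) for i in range(m)))

    initial_total = total_norm()
    stop_at = threshold_r * initial_total if relative else threshold_r
    # numerical floor: relative residual below ~1e-12 is treated as exact zero
    eps_floor = 1e-12 * max(initial_total, 1.0)

    bases: list[RankOneBasis] = []
    coeff_cols: list[np.ndarray] = []
    trace = [initial_total]

    for _ in range(max_bases):
        if trace[-1] <= max(stop_at, eps_floor):
            break
        engine = fit_gndpca(
            list(residuals),
            core_ranks=(1,) * (residuals.ndim - 1),
            max_sweeps=opts["max_sweeps"],
            tol=opts["tol"],
            subtract_mean=False,
        )
        factors = [u[:, 0] / np.linalg.norm(u[:, 0]) for u in engine.factors]
        basis = RankOneBasis(factors)
        coeffs = np.array([basis.contract(residuals[i]) for i in range(m)])
        if coeffs.mean() < 0:
            factors[0] = -factors[0]
            basis = RankOneBasis(factors)
            coeffs = -coeffs
        bt = basis.tensor()
        residuals = residuals - coeffs.reshape((-1,) + (1,) * bt.ndim) * bt
        bases.append(basis)
        coeff_cols.append(coeffs)
        trace.append(total_norm())

    coefficients = np.column_stack(coeff_cols) if coeff_cols else np.zeros((m, 0))
    return LTCModel(
        mean=mean,
        bases=bases,
        coefficients=coefficients,
        residual_trace=trace,
        threshold=threshold_r,
        relative=relative,
        subtract_mean=subtract_mean,
    )


def encode(model: LTCModel, sample: np.ndarray, n_bases: int | None = None) -> np.ndarray:
    """Coefficients of a sample by sequential greedy deflation.

    Subtracts the mean, then for each basis in extraction order computes
    ``c_j = <residual, B_j>`` and deflates ``residual -= c_j * B_j``.  On a
    training sample this reproduces the stored coefficient row.  Because
    the bases need not be mutually orthogonal, this sequential scheme (not
    per-basis independent projection) is the defining encoding.
    """
    a = as_tensor(sample)
    if a.shape != model.shape:
        raise ValueError(f"sample shape {a.shape} does not match model {model.shape}")
    if n_bases is None:
        n_bases = model.n_bases
    if not 0 <= n_bases <= model.n_bases:
        raise ValueError(f"n_bases must be in [0, {model.n_bases}], got {n_bases}")
    residual = a - model.mean
    coeffs = np.empty(n_bases)
    for j in range(n_bases):
        basis = model.bases[j]
        c = basis.contract(residual)
        coeffs[j] = c
        residual = residual - c * basis.tensor()
    return coeffs


def decode(model: LTCModel, coeffs: Sequence[float]) -> np.ndarray:
    """Reconstruct a volume: mean plus the coefficient-weighted bases."""
    c = np.asarray(coeffs, dtype=np.float64).ravel()
    if c.size > model.n_bases:
        raise ValueError(f"got {c.size} coefficients for {model.n_bases} bases")
    out = model.mean.copy()
    for j in range(c.size):
        if c[j] != 0.0:
            out += c[j] * model.bases[j].tensor()
    return out


def normalized_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity of two volumes: <x, y> / (||x|| * ||y||)."""
    nx, ny = tensor_norm(x), tensor_norm(y)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return inner_product(x, y) / (nx * ny)


def reconstruction_quality(
    model: LTCModel,
    samples: Sequence[np.ndarray],
    n_bases_grid: Sequence[int],
) -> np.ndarray:
    """Mean normalized correlation between samples and their reconstructions.

    For each basis count ``n`` in the grid, every sample is encoded with its
    first ``n`` bases, decoded, and compared to the original by normalized
    correlation; the per-sample values are averaged.  ``n = 0`` measures how
    well the mean texture alone explains the data.  Returns one value per
    grid entry, each in [-1, 1].
    """
    grid = [int(n) for n in n_bases_grid]
    if len(grid) == 0:
        raise ValueError("n_bases_grid must be nonempty")
    for n in grid:
        if not 0 <= n <= model.n_bases:
            raise ValueError(f"basis count {n} out of range [0, {model.n_bases}]")
    out = np.empty(len(grid))
    for g, n in enumerate(grid):
        vals = []
        for s in samples:
            recon = decode(model, encode(model, s, n_bases=n))
            vals.append(normalized_correlation(as_tensor(s), recon))
        out[g] = float(np.mean(vals))
    return out


def gndpca_equivalent_reconstruction(samples: Sequence[np.ndarray], **gndpca_kwargs) -> list[np.ndarray]:
    """Rank-(1,...,1) GND-PCA reconstructions, for comparison with one-basis coding."""
    ndim = as_tensor(samples[0]).ndim
    model = fit_gndpca(samples, core_ranks=(1,) * ndim, **gndpca_kwargs)
    return [gndpca_reconstruct(model, project_core(model, s)) for s in samples]
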