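"""Generalized N-dimensional PCA (GND-PCA) by alternating subspace fitting.

An ensemble of M same-shaped tensors is approximated in a shared Tucker
subspace: one orthonormal factor matrix ``U^(n)`` (shape ``I_n x J_n``) per
mode, plus one small core tensor per sample,

    A_i  ~  mean + B_i x_0 U^(0) x_1 U^(1) ... x_{N-1} U^(N-1),
    B_i  =  (A_i - mean) x_0 U^(0)^T ... x_{N-1} U^(N-1)^T.

The factors maximize the total captured energy S' = sum_i ||B_i||^2, which
is equivalent to minimizing the summed squared reconstruction error.  There
is no closed form for all factors jointly, but with all factors except mode
``n`` held fixed the optimum for ``U^(n)`` is the top-``J_n`` eigenvectors
of the accumulated mode-n scatter of the partially projected samples; the
fit alternates these exact per-mode updates (higher-order orthogonal
iteration), so S' is non-decreasing across sweeps.

With ``core_ranks=(1, ..., 1)`` this is the best shared rank-one direction
of the ensemble, which is the inner engine of linear tensor coding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tensor_core import as_tensor, mode_multiply, unfold

__all__ = ["GNDPCAModel", "fit_gndpca", "project_core", "reconstruct"]


def fix_signs(v: np.ndarray) -> np.ndarray:
    """Flip eigenvector columns so the largest-magnitude entry is positive.

    Symmetric eigensolvers return eigenvectors up to sign; pinning the sign
    makes fitted factors reproducible across backends.  Ties in magnitude
    resolve to the first occurrence.
    """
    v = np.asarray(v)
    idx = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    return v * signs


def _top_eigvecs(scatter: np.ndarray, k: int) -> np.ndarray:
    """Leading k eigenvectors of a symmetric PSD matrix, sign-fixed.

    Eigenvalues are sorted descending; within a degenerate eigenvalue the
    columns are unique only up to rotation, and the descending order plus
    the sign convention is the documented tie-break.
    """
    w, v = np.linalg.eigh(scatter)
    order = np.argsort(w)[::-1][:k]
    return fix_signs(v[:, order])


@dataclass
class GNDPCAModel:
    """Fitted GND-PCA model: per-mode orthonormal factors plus the mean."""

    factors: list[np.ndarray]
    core_ranks: tuple[int, ...]
    mean: np.ndarray
    converged: bool = False
    iterations: int = 0
    objective_trace: list[float] = field(default_factory=list)
    subtract_mean: bool = True

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(u.shape[0] for u in self.factors)

    @property
    def order(self) -> int:
        return len(self.factors)


def _project(centered: np.ndarray, factors: Sequence[np.ndarray], skip: int | None = None) -> np.ndarray:
    """Apply U^(k)^T on every mode (except ``skip``) of one centered sample."""
    out = centered
    for k, u in enumerate(factors):
        if k == skip:
            continue
        out = mode_multiply(out, u.T, k)
    return out


def fit_gndpca(
    samples: Sequence[np.ndarray],
    core_ranks: Sequence[int],
    max_sweeps: int = 50,
    tol: float = 1e-9,
    subtract_mean: bool = True,
) -> GNDPCAModel:
    """Fit shared per-mode subspaces to an ensemble of same-shaped tensors.

    Parameters
    ----------
    samples
        M tensors of identical shape ``(I_0, ..., I_{N-1})``.
    core_ranks
        Target core shape ``(J_0, ..., J_{N-1})`` with ``1 <= J_n <= I_n``.
    max_sweeps
        Cap on alternating sweeps over the modes.
    tol
        Convergence threshold on the relative change of the captured-energy
        objective S' between sweeps.
    subtract_mean
        Center the ensemble on its mean before fitting (the model equations
        assume zero-mean data).  Disable only for algebra-level tests or
        when the input is already centered, as in the deflation loop of
        linear tensor coding.

    Notes
    -----
    Initialization is HOSVD-style: each ``U^(n)`` starts from the leading
    eigenvectors of the raw mode-n scatter of the centered data.  This is
    deterministic and typically within a few sweeps of the fixed point.
    The scatter matrices are ``I_n x I_n`` so a symmetric eigendecomposition
    is used rather than an SVD of the wide stacked unfolding.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    data = np.stack([as_tensor(s) for s in samples])
    shape = data.shape[1:]
    ndim = len(shape)
    ranks = tuple(int(j) for j in core_ranks)
    if len(ranks) != ndim:
        raise ValueError(f"core_ranks {ranks} do not match tensor order {ndim}")
    for j, i in zip(ranks, shape):
        if not 1 <= j <= i:
            raise ValueError(f"core rank {j} out of range for mode size {i}")

    if subtract_mean:
        mean = data.mean(axis=0)
    else:
        mean = np.zeros(shape)
    centered = data - mean

    # HOSVD-style init: leading eigenvectors of each raw mode-n scatter.
    factors: list[np.ndarray] = []
    for n in range(ndim):
        scatter = np.zeros((shape[n], shape[n]))
        for i in range(centered.shape[0]):
            c = unfold(centered[i], n)
            scatter += c @ c.T
        factors.append(_top_eigvecs(scatter, ranks[n]))

    def objective() -> float:
        return float(
            sum(np.sum(_project(centered[i], factors) ** 2) for i in range(centered.shape[0]))
        )

    trace = [objective()]
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        for n in range(ndim):
            scatter = np.zeros((shape[n], shape[n]))
            for i in range(centered.shape[0]):
                c = unfold(_project(centered[i], factors, skip=n), n)
                scatter += c @ c.T
            factors[n] = _top_eigvecs(scatter, ranks[n])
        obj = objective()
        trace.append(obj)
        prev = trace[-2]
        if abs(obj - prev) <= tol * max(abs(prev), 1.0):
            converged = True
            break
    if not converged and max_sweeps > 0:
        warnings.warn(
            f"GND-PCA did not converge in {max_sweeps} sweeps "
            f"(last relative change {abs(trace[-1] - trace[-2]) / max(abs(trace[-2]), 1.0):.2e})",
            RuntimeWarning,
        )

    return GNDPCAModel(
        factors=factors,
        core_ranks=ranks,
        mean=mean,
        converged=converged,
        iterations=sweeps,
        objective_trace=trace,
        subtract_mean=subtract_mean,
    )


def project_core(model: GNDPCAModel, sample: np.ndarray) -> np.ndarray:
    """Core tensor of one sample: center, then contract every mode with U^T."""
    a = as_tensor(sample)
    if a.shape != model.shape:
        raise ValueError(f"sample shape {a.shape} does not match model {model.shape}")
    return _project(a - model.mean, model.factors)


def reconstruct(model: GNDPCAModel, core: np.ndarray) -> np.ndarray:
    """Map a core tensor back to the full volume: mean + core x_n U^(n)."""
    c = as_tensor(core)
    if c.shape != model.core_ranks:
        raise ValueError(f"core shape {c.shape} does not match ranks {model.core_ranks}")
    out = c
    for n, u in enumerate(model.factors):
        out = mode_multiply(out, u, n)
    return out + model.mean
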