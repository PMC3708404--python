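"""Statistical texture model over linear-tensor-coding coefficients.

The fitted coding expresses each volume as mean + sum_k c_{i,k} B_k.
Treating each coefficient column as Gaussian across the training ensemble
gives a per-basis mean m_k and standard deviation lambda_k; sweeping a
single coefficient within a few lambda of its mean while holding the rest
at zero synthesizes plausible novel volumes that vary only along that
basis, the volumetric analogue of eigen-texture morphing in appearance
models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ltc import LTCModel

__all__ = ["CoefficientStats", "coefficient_stats", "synthesize", "synthesis_sweep", "mid_slice"]


@dataclass
class CoefficientStats:
    """Per-basis Gaussian statistics of the training coefficients."""

    means: np.ndarray   # m_k, one per basis
    stds: np.ndarray    # lambda_k >= 0, sample (n-1) convention

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64).ravel()
        self.stds = np.asarray(self.stds, dtype=np.float64).ravel()
        if self.means.shape != self.stds.shape:
            raise ValueError("means and stds must have the same length")
        if np.any(self.stds < 0):
            raise ValueError("standard deviations must be non-negative")

    @property
    def n_bases(self) -> int:
        return self.means.size


def coefficient_stats(model: LTCModel) -> CoefficientStats:
    """Estimate m_k and lambda_k from the training coefficient matrix.

    Uses the sample (n-1 denominator) standard deviation.  Requires at
    least two training samples, otherwise the spread is undefined.
    """
    c = model.coefficients
    if c.shape[0] < 2:
        raise ValueError(
            "coefficient statistics need >= 2 training samples; "
            "refit the coding on a larger ensemble"
        )
    return CoefficientStats(means=c.mean(axis=0), stds=c.std(axis=0, ddof=1))


def synthesize(
    model: LTCModel,
    stats: CoefficientStats,
    basis_index: int,
    c_tilde: float,
    center: str = "mean",
    strict: bool = False,
) -> np.ndarray:
    """Novel volume along one basis: mean + c_tilde * B_k.

    The adjusted coefficient is constrained to lie within two standard
    deviations of the sweep center: ``|c_tilde - m_k| <= 2 lambda_k`` with
    ``center="mean"`` (the default; after mean-centering the training
    coefficients m_k is typically near zero anyway), or the literal
    ``|c_tilde| <= 2 lambda_k`` with ``center="zero"``.  Values outside the
    band are clamped with a warning, or rejected when ``strict``.
    """
    if stats.n_bases != model.n_bases:
        raise ValueError("stats do not match the model's basis count")
    if not 0 <= basis_index < model.n_bases:
        raise ValueError(f"basis_index {basis_index} out of range [0, {model.n_bases})")
    if center not in ("mean", "zero"):
        raise ValueError("center must be 'mean' or 'zero'")
    c0 = stats.means[basis_index] if center == "mean" else 0.0
    lam = stats.stds[basis_index]
    lo, hi = c0 - 2.0 * lam, c0 + 2.0 * lam
    c = float(c_tilde)
    if not lo <= c <= hi:
        msg = (
            f"adjusted coefficient {c:.4g} outside the +/-2 lambda band "
            f"[{lo:.4g}, {hi:.4g}] for basis {basis_index}"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + "; clamping", UserWarning)
        c = min(max(c, lo), hi)
    return model.mean + c * model.bases[basis_index].tensor()


def synthesis_sweep(
    model: LTCModel,
    stats: CoefficientStats,
    basis_index: int,
    multiples: Sequence[float] = (-1.5, -0.75, 0.0, 0.75, 1.5),
    center: str = "mean",
) -> list[np.ndarray]:
    """Volumes at c_tilde = center + multiple * lambda_k for each multiple.

    The default multiples span -1.5 lambda to +1.5 lambda, the range that
    makes per-basis intensity changes visible without leaving the
    plausible coefficient band.
    """
    c0 = stats.means[basis_index] if center == "mean" else 0.0
    lam = stats.stds[basis_index]
    return [
        synthesize(model, stats, basis_index, c0 + float(t) * lam, center=center)
        for t in multiples
    ]


def mid_slice(volume: np.ndarray, axis: int = 2) -> np.ndarray:
    """Central 2-D section of a 3-D volume (frontal slice by default)."""
    v = np.asarray(volume)
    if v.ndim != 3:
        raise ValueError("mid_slice expects a 3-D volume")
    idx = v.shape[axis] // 2
    return np.take(v, idx, axis=axis)
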