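"""Dense N-way tensor algebra primitives.

Every model in this package is built from a handful of multilinear
operations on dense real-valued arrays: the Frobenius-style tensor norm,
the elementwise inner product, mode-n unfolding (matricization) and its
inverse, the mode-n product with a matrix, and the outer product of one
vector per mode (a rank-one tensor).

Conventions
-----------
* Tensors are plain ``numpy.ndarray`` objects of ``float64``.
* Modes are **0-based** (``mode=0`` acts on the first axis), matching the
  host array library; the first axis corresponds to what the multilinear
  literature calls mode 1.
* The mode-n unfolding of a tensor of shape ``(I_0, ..., I_{N-1})`` is the
  ``(I_n, prod of the others)`` matrix obtained by moving axis ``n`` to the
  front and reshaping in C order.  Any fixed fiber ordering works as long
  as :func:`fold` is its exact inverse; this one is cheap (a view plus a
  reshape) and is used consistently everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RankOneBasis",
    "tensor_norm",
    "inner_product",
    "unfold",
    "fold",
    "mode_multiply",
    "rank_one_tensor",
]

#: tolerance used when validating unit-norm factor vectors
UNIT_NORM_ATOL = 1e-8


def as_tensor(t: np.ndarray | Sequence, check_finite: bool = True) -> np.ndarray:
    """Coerce input to a float64 ndarray, optionally rejecting NaN/Inf."""
    a = np.asarray(t, dtype=np.float64)
    if check_finite and not np.all(np.isfinite(a)):
        raise ValueError("tensor contains non-finite entries (NaN or Inf)")
    return a


def tensor_norm(t: np.ndarray) -> float:
    """Frobenius norm of a tensor: sqrt of the sum of squared entries.

    Equals ``sqrt(inner_product(t, t))``.
    """
    a = as_tensor(t)
    return float(np.linalg.norm(a.ravel()))


def inner_product(x: np.ndarray, y: np.ndarray) -> float:
    """Sum of elementwise products of two same-shaped tensors."""
    a = as_tensor(x)
    b = as_tensor(y)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.dot(a.ravel(), b.ravel()))


def _check_mode(ndim: int, mode: int) -> None:
    if not 0 <= mode < ndim:
        raise ValueError(f"mode {mode} out of range for order-{ndim} tensor")


def unfold(t: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding: matrix whose columns are the mode-``mode`` fibers.

    Shape ``(I_mode, prod(I_k for k != mode))``.
    """
    a = as_tensor(t, check_finite=False)
    _check_mode(a.ndim, mode)
    return np.moveaxis(a, mode, 0).reshape(a.shape[mode], -1)


def fold(m: np.ndarray, mode: int, shape: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`unfold`: refold a mode-n matricization to ``shape``."""
    shape = tuple(int(s) for s in shape)
    _check_mode(len(shape), mode)
    moved = (shape[mode],) + shape[:mode] + shape[mode + 1 :]
    a = np.asarray(m, dtype=np.float64).reshape(moved)
    return np.moveaxis(a, 0, mode)


def mode_multiply(t: np.ndarray, m: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n product: multiply matrix ``m`` onto the mode-``mode`` fibers.

    ``m`` must have ``I_mode`` columns; the result replaces mode size
    ``I_mode`` by ``m.shape[0]``.  A ``(1, I_mode)`` row vector collapses
    the mode to size 1 (tensor contraction against a vector); a 1-D vector
    is treated as such a row.
    """
    a = as_tensor(t, check_finite=False)
    _check_mode(a.ndim, mode)
    mm = np.asarray(m, dtype=np.float64)
    if mm.ndim == 1:
        mm = mm[None, :]
    if mm.ndim != 2 or mm.shape[1] != a.shape[mode]:
        raise ValueError(
            f"matrix of shape {mm.shape} cannot multiply mode {mode} "
            f"of tensor with shape {a.shape}"
        )
    out = np.tensordot(mm, a, axes=([1], [mode]))
    return np.moveaxis(out, 0, mode)


def rank_one_tensor(factors: "RankOneBasis | Sequence[np.ndarray]") -> np.ndarray:
    """Outer product of one vector per mode.

    The entry at multi-index ``(i_0, ..., i_{N-1})`` is the product of the
    corresponding factor entries.  If every factor has unit norm the result
    has unit Frobenius norm.
    """
    if isinstance(factors, RankOneBasis):
        vecs = factors.factors
    else:
        vecs = [np.asarray(v, dtype=np.float64) for v in factors]
    if len(vecs) == 0:
        raise ValueError("rank-one tensor needs at least one factor vector")
    for v in vecs:
        if v.ndim != 1 or v.size == 0:
            raise ValueError("each factor must be a nonempty 1-D vector")
    out = vecs[0]
    for v in vecs[1:]:
        out = np.multiply.outer(out, v)
    return out


@dataclass
class RankOneBasis:
    """A rank-one basis tensor stored as one unit-norm vector per mode.

    The induced basis tensor is the outer product of the factors and has
    unit Frobenius norm, so all magnitude lives in the model coefficients.
    """

    factors: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.factors = [np.asarray(v, dtype=np.float64) for v in self.factors]
        if len(self.factors) < 2:
            raise ValueError("a rank-one basis needs at least two modes")
        for n, v in enumerate(self.factors):
            if v.ndim != 1 or v.size == 0:
                raise ValueError(f"factor {n} must be a nonempty 1-D vector")
            nrm = np.linalg.norm(v)
            if abs(nrm - 1.0) > UNIT_NORM_ATOL:
                raise ValueError(
                    f"factor {n} must have unit norm (got {nrm:.3e}); "
                    "normalize before constructing the basis"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(v.size for v in self.factors)

    @property
    def order(self) -> int:
        return len(self.factors)

    def tensor(self) -> np.ndarray:
        """Materialize the (unit-norm) basis tensor."""
        return rank_one_tensor(self.factors)

    def contract(self, t: np.ndarray) -> float:
        """Inner product of ``t`` with this basis, via mode products.

        Contracting every mode of ``t`` against the factor vectors yields a
        scalar equal to ``inner_product(t, self.tensor())`` without ever
        forming the dense basis tensor.
        """
        a = as_tensor(t, check_finite=False)
        if a.shape != self.shape:
            raise ValueError(f"shape mismatch: {a.shape} vs basis {self.shape}")
        for v in reversed(self.factors):  # contract trailing modes first
            a = np.tensordot(a, v, axes=([a.ndim - 1], [0]))
        return float(a)
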