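"""Tensor algebra primitives against brute-force loop oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltcvol import (
    RankOneBasis,
    fold,
    inner_product,
    mode_multiply,
    rank_one_tensor,
    tensor_norm,
    unfold,
)
from ltcvol.tensor_core import UNIT_NORM_ATOL

from .conftest import random_unit


# ---------------------------------------------------------------- oracles


def norm_oracle(t):
    return float(np.sqrt(sum(v * v for v in t.ravel().tolist())))


def inner_oracle(x, y):
    return float(sum(a * b for a, b in zip(x.ravel().tolist(), y.ravel().tolist())))


def mode_multiply_oracle(t, m, mode):
    """Explicit loop: out[..., r, ...] = sum_s m[r, s] * t[..., s, ...]."""
    out_shape = list(t.shape)
    out_shape[mode] = m.shape[0]
    out = np.zeros(out_shape)
    for idx in itertools.product(*(range(s) for s in out_shape)):
        acc = 0.0
        for s in range(t.shape[mode]):
            src = list(idx)
            src[mode] = s
            acc += m[idx[mode], s] * t[tuple(src)]
        out[idx] = acc
    return out


def rank_one_oracle(factors):
    shape = tuple(v.size for v in factors)
    out = np.zeros(shape)
    for idx in itertools.product(*(range(s) for s in shape)):
        p = 1.0
        for n, i in enumerate(idx):
            p *= factors[n][i]
        out[idx] = p
    return out


def random_shape(rng):
    return tuple(rng.integers(2, 8, size=rng.integers(2, 5)).tolist())


# ----------------------------------------------------------------- tests


def test_norm_trivial_cases():
    assert tensor_norm(np.zeros((2, 2, 2))) == 0.0
    assert tensor_norm(np.array([[3.0, 0.0], [0.0, 4.0]])) == pytest.approx(5.0)


def test_norm_matches_flattened_euclidean(rng):
    for _ in range(20):
        t = rng.standard_normal(random_shape(rng))
        assert tensor_norm(t) == pytest.approx(norm_oracle(t), abs=1e-12)
        assert tensor_norm(t) ** 2 == pytest.approx(inner_product(t, t), rel=1e-12)


def test_norm_rejects_non_finite():
    t = np.ones((2, 2))
    t[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        tensor_norm(t)


def test_inner_product_trivial_cases(rng):
    u = rng.standard_normal((3, 4))
    u /= np.linalg.norm(u)
    assert inner_product(u, u) == pytest.approx(1.0)
    a = np.zeros((2, 3))
    b = np.zeros((2, 3))
    a[0, 0] = 5.0
    b[1, 2] = 7.0  # disjoint supports
    assert inner_product(a, b) == 0.0


def test_inner_product_matches_flatten_oracle(rng):
    for _ in range(20):
        shape = random_shape(rng)
        x, y = rng.standard_normal(shape), rng.standard_normal(shape)
        assert inner_product(x, y) == pytest.approx(inner_oracle(x, y), abs=1e-10)
        assert inner_product(x, y) == pytest.approx(inner_product(y, x))


def test_inner_product_shape_mismatch():
    with pytest.raises(ValueError, match="shape mismatch"):
        inner_product(np.zeros((2, 3)), np.zeros((3, 2)))


def test_unfold_matrix_identity(rng):
    m = rng.standard_normal((2, 2))
    np.testing.assert_array_equal(unfold(m, 0), m)


def test_unfold_shapes():
    t = np.zeros((2, 3, 4))
    assert unfold(t, 1).shape == (3, 8)
    assert unfold(t, 0).shape == (2, 12)
    assert unfold(t, 2).shape == (4, 6)


def test_unfold_columns_are_fibers(rng):
    # every column of the mode-n unfolding must appear among the mode-n fibers
    t = rng.standard_normal((3, 4, 5))
    for mode in range(3):
        cols = {tuple(c) for c in unfold(t, mode).T}
        fibers = set()
        other = [ax for ax in range(3) if ax != mode]
        for idx in itertools.product(*(range(t.shape[ax]) for ax in other)):
            sl = [slice(None)] * 3
            for ax, i in zip(other, idx):
                sl[ax] = i
            fibers.add(tuple(t[tuple(sl)]))
        assert cols == fibers


@pytest.mark.parametrize("mode", [0, 1, 2])
def test_fold_unfold_roundtrip(rng, mode):
    t = rng.standard_normal((3, 4, 5))
    np.testing.assert_array_equal(fold(unfold(t, mode), mode, t.shape), t)


def test_unfold_mode_out_of_range():
    with pytest.raises(ValueError, match="out of range"):
        unfold(np.zeros((2, 2)), 2)


def test_mode_multiply_identity(rng):
    t = rng.standard_normal((3, 4, 5))
    for mode in range(3):
        np.testing.assert_allclose(mode_multiply(t, np.eye(t.shape[mode]), mode), t)


def test_mode_multiply_contracts_rank_one(rng):
    a, b, c = (random_unit(rng, n) for n in (4, 3, 5))
    t = rank_one_tensor([a, b, c])
    collapsed = mode_multiply(t, a[None, :], 0)
    assert collapsed.shape == (1, 3, 5)
    np.testing.assert_allclose(collapsed[0], rank_one_tensor([b, c]), atol=1e-12)


def test_mode_multiply_matches_loop_oracle(rng):
    for _ in range(5):
        t = rng.standard_normal((3, 4, 5))
        mode = int(rng.integers(0, 3))
        m = rng.standard_normal((int(rng.integers(1, 6)), t.shape[mode]))
        np.testing.assert_allclose(
            mode_multiply(t, m, mode), mode_multiply_oracle(t, m, mode), atol=1e-10
        )


def test_mode_multiply_dimension_mismatch():
    with pytest.raises(ValueError, match="cannot multiply"):
        mode_multiply(np.zeros((3, 4)), np.zeros((2, 5)), 0)


def test_mode_multiply_preserves_norm_under_orthogonal(rng):
    t = rng.standard_normal((4, 5, 3))
    q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
    assert tensor_norm(mode_multiply(t, q, 0)) == pytest.approx(tensor_norm(t))


def test_mode_multiply_commutes_across_modes(rng):
    t = rng.standard_normal((3, 4, 5))
    u = rng.standard_normal((2, 3))
    v = rng.standard_normal((6, 4))
    np.testing.assert_allclose(
        mode_multiply(mode_multiply(t, u, 0), v, 1),
        mode_multiply(mode_multiply(t, v, 1), u, 0),
        atol=1e-12,
    )


def test_rank_one_indicator():
    e = np.array([1.0, 0.0])
    t = rank_one_tensor([e, e, e])
    expected = np.zeros((2, 2, 2))
    expected[0, 0, 0] = 1.0
    np.testing.assert_array_equal(t, expected)


def test_rank_one_unit_factors_unit_norm(rng):
    factors = [random_unit(rng, n) for n in (3, 4, 5)]
    assert tensor_norm(rank_one_tensor(factors)) == pytest.approx(1.0)


def test_rank_one_matches_elementwise_oracle(rng):
    factors = [random_unit(rng, n) for n in (3, 4, 2)]
    np.testing.assert_allclose(
        rank_one_tensor(factors), rank_one_oracle(factors), atol=1e-12
    )


def test_rank_one_inner_product_separability(rng):
    # <a1 o a2 o a3, b1 o b2 o b3> == prod_n <an, bn>
    fa = [rng.standard_normal(n) for n in (3, 4, 5)]
    fb = [rng.standard_normal(n) for n in (3, 4, 5)]
    lhs = inner_product(rank_one_tensor(fa), rank_one_tensor(fb))
    rhs = np.prod([np.dot(a, b) for a, b in zip(fa, fb)])
    assert lhs == pytest.approx(rhs, rel=1e-10)


def test_rank_one_basis_validation(rng):
    with pytest.raises(ValueError, match="unit norm"):
        RankOneBasis([np.array([1.0, 1.0]), np.array([1.0, 0.0])])
    with pytest.raises(ValueError, match="at least two modes"):
        RankOneBasis([np.array([1.0])])
    b = RankOneBasis([random_unit(rng, n) for n in (4, 5, 6)])
    assert b.shape == (4, 5, 6)
    assert abs(np.linalg.norm(b.tensor()) - 1.0) < UNIT_NORM_ATOL


def test_rank_one_basis_contract_equals_inner_product(rng):
    b = RankOneBasis([random_unit(rng, n) for n in (4, 3, 5)])
    t = rng.standard_normal((4, 3, 5))
    assert b.contract(t) == pytest.approx(inner_product(t, b.tensor()), rel=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    shape=st.tuples(*(st.integers(2, 5) for _ in range(3))),
    mode=st.integers(0, 2),
    seed=st.integers(0, 2**16),
)
def test_fold_unfold_bijection_property(shape, mode, seed):
    t = np.random.default_rng(seed).standard_normal(shape)
    np.testing.assert_array_equal(fold(unfold(t, mode), mode, shape), t)
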