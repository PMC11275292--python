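"""Angiography extraction on projection stacks: eigen filtering and
speckle variance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rupp import (
    ProjectionStack,
    projection_correlation_matrix,
    rupp_ed,
    rupp_projection_stack,
    rupp_sv,
    select_r_auto,
)


# --------------------------------------------------------------------------
# correlation matrix


def test_identical_frames_give_rank_one_gram():
    f = np.arange(12, dtype=float).reshape(3, 4)
    stack = ProjectionStack(np.stack([f, f]))
    corr = projection_correlation_matrix(stack)
    s = np.sum(f * f) / 2
    assert np.allclose(corr, [[s, s], [s, s]])
    assert np.linalg.matrix_rank(corr) == 1


def test_orthogonal_frames_give_diagonal_gram():
    f1 = np.zeros((2, 2)); f1[0, 0] = 2.0
    f2 = np.zeros((2, 2)); f2[1, 1] = 3.0
    corr = projection_correlation_matrix(ProjectionStack(np.stack([f1, f2])))
    assert np.allclose(corr, np.diag([2.0, 4.5]))


def test_correlation_matches_triple_loop_oracle(rng):
    frames = rng.normal(size=(3, 4, 4))
    corr = projection_correlation_matrix(ProjectionStack(frames))
    cas = frames.reshape(3, -1)
    oracle = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            s = 0.0
            for p in range(16):
                s += cas[i, p] * cas[j, p]
            oracle[i, j] = s / 3
    assert np.allclose(corr, oracle, rtol=1e-13, atol=0)
    assert np.allclose(corr, corr.T)


def test_correlation_is_positive_semidefinite(rng):
    frames = rng.normal(size=(4, 8, 8))
    corr = projection_correlation_matrix(ProjectionStack(frames))
    evals = np.linalg.eigvalsh(corr)
    assert np.all(evals >= -1e-10 * evals.max())
    assert np.isclose(evals.sum(), np.trace(corr))


# --------------------------------------------------------------------------
# automatic rank selection


def test_r_auto_counts_above_mean():
    assert select_r_auto(np.array([4.0, 1.0, 1.0, 1.0, 1.0])) == 1


def test_r_auto_zero_when_all_equal():
    assert select_r_auto(np.array([3.0, 3.0, 3.0, 3.0])) == 0


def test_r_auto_rejects_empty_and_unsorted():
    with pytest.raises(ValueError):
        select_r_auto(np.array([]))
    with pytest.raises(ValueError):
        select_r_auto(np.array([1.0, 2.0]))


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=1, max_size=12)
)
def test_r_auto_matches_recount_and_stays_below_n(vals):
    ev = np.sort(np.asarray(vals, dtype=float))[::-1]
    r = select_r_auto(ev)
    recount = sum(1 for v in ev if v > ev.mean())
    assert r == recount
    # at least one eigenvalue is always <= the mean, so r never reaches N
    assert 0 <= r < len(ev) or (r == 0 and len(ev) == 1)


# --------------------------------------------------------------------------
# eigen-decomposition filter


def test_static_stack_fully_cancelled(static_vol):
    """Identical frames form a rank-1 stack: automatic rank picks 1 and the
    projector removes essentially all energy."""
    stack = rupp_projection_stack(static_vol)
    amap, res = rupp_ed(stack, r="auto")
    assert res.r == 1
    ratio = np.sum(res.residual_stack**2) / np.sum(stack.frames**2)
    assert ratio < 1e-20
    assert np.all(amap.values >= 0)


def test_r_zero_is_identity_filter(rng):
    frames = rng.normal(size=(3, 6, 6))
    stack = ProjectionStack(frames)
    amap, res = rupp_ed(stack, r=0)
    assert np.array_equal(res.residual_stack, frames)
    assert np.allclose(amap.values, np.abs(frames).mean(axis=0))


def test_r_out_of_range_rejected(rng):
    stack = ProjectionStack(rng.normal(size=(3, 4, 4)))
    with pytest.raises(ValueError):
        rupp_ed(stack, r=3)
    with pytest.raises(ValueError):
        rupp_ed(stack, r=-1)


def test_residual_matches_least_squares_projection(rng):
    """The filtered stack equals the input minus its least-squares
    projection onto the top-r eigenvector span."""
    frames = rng.normal(size=(4, 16, 16))
    stack = ProjectionStack(frames)
    _, res = rupp_ed(stack, r=2)
    cas = frames.reshape(4, -1)
    V = res.eigenvectors[:, :2]
    coef, *_ = np.linalg.lstsq(V, cas, rcond=None)
    oracle = cas - V @ coef
    assert np.abs(res.residual_stack.reshape(4, -1) - oracle).max() < 1e-10


def test_subspace_removal_is_idempotent(rng):
    frames = rng.normal(size=(4, 8, 8))
    stack = ProjectionStack(frames)
    _, res = rupp_ed(stack, r=2)
    V = res.eigenvectors[:, : res.r]
    once = res.residual_stack.reshape(4, -1)
    twice = once - V @ (V.conj().T @ once)
    assert np.allclose(twice, once, atol=1e-10)


def test_eigen_diagnostics_invariants(vol4):
    stack = rupp_projection_stack(vol4)
    _, res = rupp_ed(stack, r="auto")
    assert np.allclose(res.correlation, res.correlation.conj().T)
    assert np.all(np.diff(res.eigenvalues) <= 1e-9 * res.eigenvalues[0])
    assert np.all(res.eigenvalues >= -1e-9 * res.eigenvalues[0])
    assert np.isclose(res.eigenvalues.sum(), np.trace(res.correlation))
    assert 0 <= res.r < stack.N


def test_ed_enhances_vessels_over_static_tissue(vol4, truth):
    amap, _ = rupp_ed(rupp_projection_stack(vol4), r="auto")
    inside = np.median(amap.values[truth.vessel_mask])
    outside = np.median(amap.values[~truth.vessel_mask])
    assert inside > outside


# --------------------------------------------------------------------------
# speckle variance


def test_sv_zero_for_identical_frames():
    f = np.arange(6, dtype=float).reshape(2, 3)
    amap = rupp_sv(ProjectionStack(np.stack([f, f, f])))
    assert np.all(amap.values == 0.0)


def test_sv_hand_example():
    """Two frames with pixel values {0, 2}: population variance is 1."""
    frames = np.stack([np.zeros((2, 2)), np.full((2, 2), 2.0)])
    amap = rupp_sv(ProjectionStack(frames))
    assert np.all(amap.values == 1.0)


def test_sv_matches_loop_variance_oracle(rng):
    frames = rng.normal(size=(4, 16, 16))
    amap = rupp_sv(ProjectionStack(frames))
    oracle = np.zeros((16, 16))
    for x in range(16):
        for y in range(16):
            m = 0.0
            for n in range(4):
                m += frames[n, x, y]
            m /= 4
            v = 0.0
            for n in range(4):
                v += (frames[n, x, y] - m) ** 2
            oracle[x, y] = v / 4
    assert np.array_equal(amap.values, oracle)


@settings(derandomize=True, max_examples=30)
@given(st.floats(min_value=-100, max_value=100),
       st.floats(min_value=0.25, max_value=8.0))
def test_sv_offset_invariant_and_quadratic(shift, scale):
    rng = np.random.default_rng(9)
    frames = rng.normal(size=(4, 5, 5))
    base = rupp_sv(ProjectionStack(frames)).values
    shifted = rupp_sv(ProjectionStack(frames + shift)).values
    scaled = rupp_sv(ProjectionStack(frames * scale)).values
    assert np.allclose(shifted, base, rtol=1e-9, atol=1e-12)
    assert np.allclose(scaled, base * scale**2, rtol=1e-12)


def test_sv_recovers_vessels(vol4, truth):
    from sklearn.metrics import roc_auc_score

    sv = rupp_sv(rupp_projection_stack(vol4)).values
    auc = roc_auc_score(truth.vessel_mask.ravel(), sv.ravel())
    assert auc >= 0.90
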