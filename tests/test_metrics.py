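"""Quantification layer: ROI statistics, SUVmax, contrast recovery,
stratification and the signed-rank test (vs exhaustive enumeration)."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rdpet import (
    ContrastRecoveryError,
    DegenerateDifferencesError,
    classify_lesion,
    contrast_recovery,
    dilate_mask,
    roi_stats,
    suvmax5,
    wilcoxon_signed_rank,
)


def _img(values):
    return np.asarray(values, dtype=float).reshape(-1, 1, 1)


def _mask(n):
    return np.ones((n, 1, 1), dtype=bool)


# ---------------------------------------------------------------------------
# roi_stats / suvmax5


def test_roi_stats_hand_cases():
    st_ = roi_stats(_img([1.5] * 8), _mask(8))
    assert (st_.suv_mean, st_.suv_std, st_.n_voxels) == (1.5, 0.0, 8)
    st2 = roi_stats(_img([1, 2, 3]), _mask(3))
    assert st2.suv_mean == pytest.approx(2.0)
    assert st2.suv_std == pytest.approx(np.sqrt(2.0 / 3.0))  # population SD
    st1 = roi_stats(_img([4.2]), _mask(1))
    assert (st1.suv_mean, st1.suv_std) == (4.2, 0.0)
    with pytest.raises(ValueError):
        roi_stats(_img([1.0]), np.zeros((1, 1, 1), dtype=bool))


def test_suvmax5_hand_cases():
    assert suvmax5(_img([1, 2, 3, 4, 5]), _mask(5)) == pytest.approx(3.0)
    assert suvmax5(_img(range(1, 11)), _mask(10)) == pytest.approx(8.0)
    assert suvmax5(_img([2.5] * 9), _mask(9)) == pytest.approx(2.5)
    with pytest.warns(UserWarning):
        assert suvmax5(_img([1, 3]), _mask(2)) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        suvmax5(_img([1.0]), np.zeros((1, 1, 1), dtype=bool))


@settings(deadline=None, derandomize=True, max_examples=50)
@given(arrays(np.float64, 12, elements=st.floats(0, 100)))
def test_suvmax5_at_least_mean(vals):
    img = _img(vals)
    assert suvmax5(img, _mask(12)) >= roi_stats(img, _mask(12)).suv_mean - 1e-12


# ---------------------------------------------------------------------------
# contrast recovery


def test_contrast_recovery_identity_and_paper_values():
    assert contrast_recovery(7.3, 1.0, 7.3, 1.0) == pytest.approx(1.0)
    # lymph-node example: 9.6 vs reference 7.3 over unit background
    assert contrast_recovery(9.6, 1.0, 7.3, 1.0) == pytest.approx(8.6 / 6.3, rel=1e-9)
    with pytest.raises(ContrastRecoveryError):
        contrast_recovery(5.0, 1.0, 2.0, 2.0)


def test_contrast_recovery_scale_invariance():
    c = 3.7
    assert contrast_recovery(9.6 * c, 1.0 * c, 7.3 * c, 1.0 * c) == pytest.approx(
        contrast_recovery(9.6, 1.0, 7.3, 1.0)
    )


# ---------------------------------------------------------------------------
# stratification


@pytest.mark.parametrize(
    "volume, suvmax, expected",
    [
        (0.5, 4.0, "small_low"),
        (12.0, 6.0, "large_high"),   # volume rule alone
        (2.0, 15.0, "large_high"),   # uptake rule alone
        (1.0, 5.0, "small_low"),     # inclusive boundaries
        (1.01, 5.0, "medium_medium"),
        (0.5, 5.01, "medium_medium"),
        (10.0, 10.0, "medium_medium"),
        (3.0, 7.0, "medium_medium"),
    ],
)
def test_classify_lesion(volume, suvmax, expected):
    assert classify_lesion(volume, suvmax) == expected


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.floats(0.01, 50), st.floats(0, 50))
def test_classify_partitions_plane(volume, suvmax):
    groups = {"small_low", "medium_medium", "large_high"}
    assert classify_lesion(volume, suvmax) in groups


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _exact_two_sided_p(diffs):
    """Exhaustive enumeration of all sign assignments of |d| ranks."""
    import scipy.stats

    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    n = len(d)
    w_obs = ranks[d > 0].sum()
    ws = [
        np.asarray(signs).dot(ranks)
        for signs in itertools.product([0, 1], repeat=n)
    ]
    ws = np.asarray(ws)
    cdf = np.mean(ws <= w_obs)
    sf = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(cdf, sf))


def test_wilcoxon_all_positive_n5():
    """n=5, all positive differences: exact two-sided p = 2/32 = 0.0625."""
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    b = np.zeros(5)
    stat, p = wilcoxon_signed_rank(a, b)
    assert p == pytest.approx(0.0625)


@pytest.mark.parametrize("seed", range(6))
def test_wilcoxon_matches_enumeration(seed):
    """Agreement with exhaustive sign enumeration for n <= 8."""
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 9)
    a = rng.normal(1.0, 1.0, n)
    b = rng.normal(0.0, 1.0, n)
    _, p = wilcoxon_signed_rank(a, b)
    assert p == pytest.approx(_exact_two_sided_p(a - b), rel=1e-9)


def test_wilcoxon_symmetry_and_degenerate():
    a = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
    b = np.array([0.5, 2.5, 1.0, 1.0, 1.0])
    _, p_ab = wilcoxon_signed_rank(a, b)
    _, p_ba = wilcoxon_signed_rank(b, a)
    assert p_ab == pytest.approx(p_ba)
    with pytest.raises(DegenerateDifferencesError):
        wilcoxon_signed_rank(a, a)
    with pytest.raises(ValueError):
        wilcoxon_signed_rank(a, b[:3])


def test_wilcoxon_drops_zero_differences():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 7.7])
    b = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 7.7])
    _, p = wilcoxon_signed_rank(a, b)
    assert p == pytest.approx(0.0625)  # zero pair excluded, n=5 remains


# ---------------------------------------------------------------------------
# mask dilation


def test_dilate_mask_grows_by_one_voxel():
    m = np.zeros((5, 5, 5), dtype=bool)
    m[2, 2, 2] = True
    d = dilate_mask(m)
    assert d.sum() == 27
    assert d[1:4, 1:4, 1:4].all()
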