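"""Optimizer correctness: likelihood/penalty values, EM identities,
BSREM behavior and the clinical post-filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rdpet import (
    RDPParams,
    ReconSchedule,
    ReconStage,
    bsrem_reconstruct,
    mlem_update,
    objective_value,
    osem_reconstruct,
    poisson_loglik,
    post_filter,
    rdp_gradient,
    rdp_value,
)
from rdpet.system_model import ScannerGeometry, SinogramData, SystemModel


def _scalar_system():
    """A 1-voxel, 1-ray system where P is multiplication by voxel size."""
    g = ScannerGeometry(
        grid_shape=(1, 1, 1), voxel_size_mm=(1.0, 1.0, 1.0),
        n_angles=1, n_radial=1, radial_spacing_mm=1.0,
        n_tof_bins=1, psf_fwhm_mm=0.0, count_scale=1.0,
    )
    return g, SystemModel(g)


def _scalar_sinogram(g, y, b):
    shape = g.sino_shape_tof
    return SinogramData(
        y=np.full(shape, y, dtype=np.int64), b=np.full(shape, float(b)),
        atten=np.ones(g.sino_shape_nontof), norm=np.ones(g.sino_shape_nontof),
        geometry=g,
    )


# ---------------------------------------------------------------------------
# likelihood


def test_poisson_loglik_hand_case():
    """x=0, b=1, y=1 on a scalar system: 1*log(1) - 1 = -1."""
    g, sm = _scalar_system()
    sino = _scalar_sinogram(g, 1, 1.0)
    assert poisson_loglik(np.zeros(g.grid_shape), sino, sm) == pytest.approx(-1.0)


def test_single_bin_likelihood_maximized_at_y():
    """Scanning ybar on a grid, the single-bin likelihood peaks at ybar = y."""
    y = 7.0
    ybar = np.linspace(0.5, 20, 200)
    ll = y * np.log(ybar) - ybar
    assert ybar[np.argmax(ll)] == pytest.approx(y, abs=0.1)


def test_loglik_decreases_with_background_when_y_zero():
    g, sm = _scalar_system()
    x = np.zeros(g.grid_shape)
    vals = [poisson_loglik(x, _scalar_sinogram(g, 0, b), sm) for b in (1.0, 2.0, 3.0)]
    assert vals[0] > vals[1] > vals[2]


def test_objective_value_composition(small_sinogram, small_system, rng):
    x = rng.random(small_system.geometry.grid_shape)
    p0 = RDPParams(beta=0.0)
    assert objective_value(x, small_sinogram, small_system, p0) == pytest.approx(
        poisson_loglik(x, small_sinogram, small_system)
    )
    const = np.ones(small_system.geometry.grid_shape)
    p2 = RDPParams(beta=2.5)
    assert objective_value(const, small_sinogram, small_system, p2) == pytest.approx(
        poisson_loglik(const, small_sinogram, small_system)
    )


# ---------------------------------------------------------------------------
# relative difference penalty


def test_rdp_hand_case_two_voxels():
    """Neighbors [2, 0], gamma=2: R = 2 * 4/(2+4) = 4/3."""
    x = np.array([2.0, 0.0]).reshape(2, 1, 1)
    assert rdp_value(x, RDPParams(beta=1.0)) == pytest.approx(4.0 / 3.0)


def test_rdp_constant_image_zero_value_and_gradient():
    x = np.full((6, 5, 4), 3.7)
    p = RDPParams(beta=1.0)
    assert rdp_value(x, p) == 0.0
    np.testing.assert_allclose(rdp_gradient(x, p), 0.0, atol=1e-14)
    assert rdp_value(np.zeros((4, 4, 4)), p) == 0.0  # 0/0 pairs contribute 0


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    arrays(np.float64, (4, 4, 3), elements=st.floats(0.0, 50.0)),
    st.floats(0.1, 10.0),
)
def test_rdp_degree_one_homogeneity(x, c):
    p = RDPParams(beta=1.0)
    assert rdp_value(c * x, p) == pytest.approx(c * rdp_value(x, p), rel=1e-9, abs=1e-9)


def test_rdp_gradient_matches_finite_differences(rng):
    """Central finite differences of rdp_value to 1e-5 relative."""
    x = rng.random((5, 5, 3)) + 0.1
    p = RDPParams(beta=1.0, gamma=2.0)
    grad = rdp_gradient(x, p)
    h = 1e-6
    fd = np.zeros_like(x)
    for idx in np.ndindex(x.shape):
        xp, xm = x.copy(), x.copy()
        xp[idx] += h
        xm[idx] -= h
        fd[idx] = (rdp_value(xp, p) - rdp_value(xm, p)) / (2 * h)
    assert np.abs(grad - fd).max() <= 1e-5 * np.abs(fd).max()


def test_rdp_gradient_euler_identity(rng):
    """Degree-1 homogeneity implies <x, grad R(x)> = R(x); the total
    gradient sum is <= 0 (adding a constant can only lower the penalty)."""
    x = rng.random((6, 6, 4))
    p = RDPParams(beta=1.0)
    g = rdp_gradient(x, p)
    assert np.vdot(x, g) == pytest.approx(rdp_value(x, p), rel=1e-9)
    assert g.sum() <= 1e-12


def test_rdp_local_weights_scale_pairs():
    x = np.array([2.0, 0.0]).reshape(2, 1, 1)
    w = np.array([1.0, 0.0]).reshape(2, 1, 1)
    assert rdp_value(x, RDPParams(beta=1.0, local_weights=w)) == 0.0


# ---------------------------------------------------------------------------
# EM updates and identities


def test_mlem_update_scalar_hand_case():
    """P=[1], s=1, b=0, x=2, y=4 -> x' = 4 (after unit geometry scaling)."""
    g, sm = _scalar_system()
    sino = _scalar_sinogram(g, 4, 0.0)
    x = np.full(g.grid_shape, 2.0)
    assert mlem_update(x, sino, sm)[0, 0, 0] == pytest.approx(4.0)


def test_mlem_fixed_point(small_phantom, small_geometry):
    """If y = Px + b exactly, one MLEM update leaves x unchanged."""
    sm = SystemModel(small_geometry)
    x = small_phantom.activity
    ybar = sm.forward(x, tof=True)
    b = np.full_like(ybar, 0.1)
    sino = SinogramData(
        y=(ybar + b), b=b, atten=np.ones(small_geometry.sino_shape_nontof),
        norm=np.ones(small_geometry.sino_shape_nontof), geometry=small_geometry,
    )
    x1 = mlem_update(x, sino, sm)
    fov = sm.sensitivity(tof=True) > 0
    np.testing.assert_allclose(x1[fov], x[fov], rtol=1e-9, atol=1e-12)


def test_mlem_zero_counts_gives_zero(small_sinogram, small_system):
    sino = small_sinogram
    zero = SinogramData(
        y=np.zeros_like(sino.y), b=sino.b + 0.5, atten=sino.atten,
        norm=sino.norm, geometry=sino.geometry,
    )
    x1 = mlem_update(np.ones(sino.geometry.grid_shape), zero, small_system)
    assert np.all(x1 == 0)


def test_osem_one_subset_equals_mlem(small_sinogram, small_system):
    """OSEM with a single subset is exactly repeated MLEM (to 1e-12)."""
    res = osem_reconstruct(small_sinogram, small_system, 4, 1, tof=True)
    x = np.ones(small_system.geometry.grid_shape)
    x *= small_system.sensitivity(tof=True) > 0
    for _ in range(4):
        x = mlem_update(x, small_sinogram, small_system, tof=True)
    assert np.abs(res.image - x).max() <= 1e-12 * max(x.max(), 1.0)


def test_bsrem_beta0_one_subset_equals_mlem(small_sinogram, small_system):
    """BSREM(beta=0, 1 subset, alpha=1, eps=0, U=inf) == MLEM to 1e-10."""
    sch = ReconSchedule(
        n_subsets=1, stages=(ReconStage("bsrem", True, 4),),
        alpha0=1.0, decay=0.0, upper_bound=1e15, epsilon=0.0,
    )
    res = bsrem_reconstruct(small_sinogram, small_system, RDPParams(beta=0.0), sch)
    x = np.ones(small_system.geometry.grid_shape)
    x *= small_system.sensitivity(tof=True) > 0
    for _ in range(4):
        x = mlem_update(x, small_sinogram, small_system, tof=True)
    assert np.abs(res.image - x).max() <= 1e-10 * max(x.max(), 1.0)


def test_mlem_loglik_monotone(small_sinogram, small_system):
    res = osem_reconstruct(
        small_sinogram, small_system, 25, 1, tof=True, track_objective="iteration"
    )
    assert np.all(np.diff(res.objective_trace) >= -1e-7 * np.abs(res.objective_trace[0]))


def test_bsrem_nonnegative_and_bounded(small_sinogram, small_system):
    sch = ReconSchedule(n_subsets=4, stages=(ReconStage("bsrem", True, 3),),
                        upper_bound=5.0)
    res = bsrem_reconstruct(small_sinogram, small_system, RDPParams(beta=0.01), sch)
    assert res.image.min() >= 0.0
    assert res.image.max() <= 5.0


def test_bsrem_huge_beta_flattens_background(small_sinogram, small_system, small_phantom):
    """In the penalty-dominated limit the background is far smoother."""
    sch = ReconSchedule(n_subsets=4, stages=(ReconStage("bsrem", True, 6),))
    free = bsrem_reconstruct(small_sinogram, small_system, RDPParams(beta=0.0), sch)
    heavy = bsrem_reconstruct(small_sinogram, small_system, RDPParams(beta=50.0), sch)
    mask = small_phantom.masks["background"]
    assert heavy.image[mask].std() < 0.1 * free.image[mask].std()


def test_bsrem_higher_beta_lower_penalty(small_sinogram, small_system):
    """Regularization path: the optimum's penalty value decreases in beta."""
    sch = ReconSchedule(n_subsets=4, stages=(ReconStage("bsrem", True, 6),))
    lo = bsrem_reconstruct(small_sinogram, small_system, RDPParams(beta=0.005), sch)
    hi = bsrem_reconstruct(small_sinogram, small_system, RDPParams(beta=0.1), sch)
    p = RDPParams(beta=1.0)
    assert rdp_value(hi.image, p) <= rdp_value(lo.image, p)


def test_bsrem_objective_trace_granularity(small_sinogram, small_system):
    sch = ReconSchedule(n_subsets=4, stages=(ReconStage("bsrem", True, 2),))
    res = bsrem_reconstruct(
        small_sinogram, small_system, RDPParams(beta=0.01), sch,
        track_objective="subiteration",
    )
    assert len(res.objective_trace) == 2 * 4  # iterations x subsets
    assert np.all(np.isfinite(res.objective_trace))


# ---------------------------------------------------------------------------
# post-filter


def test_post_filter_constant_invariant():
    img = np.full((20, 20, 5), 2.5)
    out = post_filter(img, (2.34, 2.34, 2.78))
    np.testing.assert_allclose(out, 2.5, rtol=1e-12)


def test_post_filter_inplane_fwhm():
    """In-plane impulse spreads to FWHM 5.0 mm within one voxel pitch."""
    vox = (2.34, 2.34, 2.78)
    img = np.zeros((41, 41, 3))
    img[20, 20, 1] = 1.0
    out = post_filter(img, vox)
    profile = out[:, 20, 1]
    half = profile.max() / 2.0
    above = np.nonzero(profile >= half)[0]
    # linear interpolation at the half-maximum crossings
    lo, hi = above[0], above[-1]
    fl = lo - 1 + (half - profile[lo - 1]) / (profile[lo] - profile[lo - 1])
    fr = hi + (profile[hi] - half) / (profile[hi] - profile[hi + 1])
    fwhm = (fr - fl) * vox[0]
    assert abs(fwhm - 5.0) <= vox[0]


def test_post_filter_axial_141():
    """Axial impulse of 6 spreads as 1:4:1 in adjacent slices."""
    img = np.zeros((15, 15, 5))
    img[7, 7, 2] = 6.0
    out = post_filter(img, (2.34, 2.34, 2.78), in_plane_fwhm_mm=1e-9)
    np.testing.assert_allclose(out[7, 7, 1:4], [1.0, 4.0, 1.0], rtol=1e-6)
    assert out[7, 7, 0] == pytest.approx(0.0, abs=1e-12)


def test_post_filter_requires_three_slices():
    with pytest.raises(ValueError):
        post_filter(np.zeros((5, 5, 2)), (2.0, 2.0, 2.0))
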