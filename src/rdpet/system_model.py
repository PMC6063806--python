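"""TOF forward/adjoint projection with attenuation, normalization and PSF.

The projection operator P maps an activity image x (SUV, g/ml) to expected
coincidence counts per sinogram bin:

    [Px] = count_scale * norm * atten * A (G x)

where G is an in-plane Gaussian point-spread model, A the (optionally TOF)
line-integral matrix, `atten` the per-line attenuation survival factors
exp(-integral mu dl) and `norm` user-supplied per-bin normalization factors
(identity by default; decay/dead-time calibrations can be injected here).

Geometry is 2D parallel-beam per axial slice (stacked slices): every
algorithmic ingredient of penalized-likelihood TOF reconstruction is
preserved at desk scale, while the projector reduces to one sparse matrix
per slice stack.  Line integrals use Joseph's method (bilinear interpolation
along the ray's dominant axis); the adjoint is the exact matrix transpose.
TOF mode distributes each voxel's contribution across TOF bins with a
Gaussian kernel centered at the emission position along the line of
response; kernel weights are truncated at +-3 sigma and renormalized to sum
to one, so summing TOF bins reproduces the non-TOF projection exactly.

Sinogram axis order: (angle, radial, [tof,] slice).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp

__all__ = [
    "ScannerGeometry",
    "SinogramData",
    "SystemModel",
    "forward_project",
    "back_project",
    "attenuation_factors",
    "default_geometry",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ScannerGeometry:
    """Projection geometry, TOF binning, PSF and count-scale parameters.

    ``count_scale`` is the expected number of detected counts per unit of
    SUV-weighted line integral (SUV*mm) before attenuation; it sets the
    count level of a 2-minute-acquisition-like frame.  ``tof_fwhm_mm`` is
    the spatial TOF localization kernel FWHM (~60 mm for a 400 ps timing
    resolution).  ``psf_fwhm_mm`` is an isotropic in-plane image-space
    resolution model (~5.4 mm for 68Ga on a TOF PET/MR system).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 16)
    voxel_size_mm: tuple[float, float, float] = (2.34, 2.34, 2.78)
    n_angles: int = 96
    n_radial: int = 112
    radial_spacing_mm: float = 2.34
    n_tof_bins: int = 7
    tof_fwhm_mm: float = 60.0
    psf_fwhm_mm: float = 5.4
    count_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_radial < 1:
            raise ValueError("n_angles and n_radial must be >= 1")
        if self.n_tof_bins < 1 or self.n_tof_bins % 2 == 0:
            raise ValueError("n_tof_bins must be an odd integer >= 1")
        if self.n_tof_bins > 1 and self.tof_fwhm_mm <= 0:
            raise ValueError("tof_fwhm_mm must be > 0 in TOF mode")
        if self.count_scale <= 0:
            raise ValueError("count_scale must be > 0")

    @property
    def tof_bin_width_mm(self) -> float:
        return self.tof_fwhm_mm / 2.0

    @property
    def sino_shape_tof(self) -> tuple[int, int, int, int]:
        return (self.n_angles, self.n_radial, self.n_tof_bins, self.grid_shape[2])

    @property
    def sino_shape_nontof(self) -> tuple[int, int, int]:
        return (self.n_angles, self.n_radial, self.grid_shape[2])


def default_geometry(count_scale: float | None = None) -> ScannerGeometry:
    """Default desk-scale geometry; ``count_scale`` defaults to the
    calibrated 2-minute-frame count level (see :mod:`rdpet.calibrate`)."""
    from .calibrate import DEFAULT_COUNT_SCALE

    return ScannerGeometry(
        count_scale=DEFAULT_COUNT_SCALE if count_scale is None else count_scale
    )


@dataclass
class SinogramData:
    """Measured counts, additive background and per-line correction factors.

    ``y``: Poisson counts, shape (angle, radial, tof, slice).
    ``b``: expected randoms+scatter per bin, same shape.
    ``atten``: attenuation survival factors in (0, 1], (angle, radial, slice).
    ``norm``: per-line normalization factors, (angle, radial, slice).
    """

    y: np.ndarray
    b: np.ndarray
    atten: np.ndarray
    norm: np.ndarray
    geometry: ScannerGeometry
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        g = self.geometry
        if self.y.shape != g.sino_shape_tof or self.b.shape != g.sino_shape_tof:
            raise ValueError("y/b shape inconsistent with geometry")
        if self.atten.shape != g.sino_shape_nontof:
            raise ValueError("atten shape inconsistent with geometry")
        if np.any(self.y < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.b < 0):
            raise ValueError("background must be nonnegative")
        if np.any(self.atten <= 0) or np.any(self.atten > 1):
            raise ValueError("attenuation factors must lie in (0, 1]")

    @property
    def y_nontof(self) -> np.ndarray:
        return self.y.sum(axis=2)

    @property
    def b_nontof(self) -> np.ndarray:
        return self.b.sum(axis=2)


# ---------------------------------------------------------------------------
# sparse line-integral matrices


def _joseph_entries(geometry: ScannerGeometry):
    """COO entries (row, col, weight, u) of the per-slice 2D Joseph projector.

    Rows index (angle, radial) in C order; columns index in-plane voxels
    flattened as ix * ny + iy.  Weights are path lengths in mm; ``u`` is the
    signed along-ray coordinate (mm, 0 at the closest point to the grid
    center), used to place TOF kernel weights.
    """
    nx, ny, _ = geometry.grid_shape
    dx, dy, _ = geometry.voxel_size_mm
    xs = (np.arange(nx) - (nx - 1) / 2.0) * dx
    ys = (np.arange(ny) - (ny - 1) / 2.0) * dy
    s_vals = (np.arange(geometry.n_radial) - (geometry.n_radial - 1) / 2.0) * (
        geometry.radial_spacing_mm
    )
    rows, cols, wts, us = [], [], [], []
    for a in range(geometry.n_angles):
        theta = np.pi * a / geometry.n_angles
        c, s = np.cos(theta), np.sin(theta)
        # ray: p(t) = s_r * (c, s) + t * (-s, c)
        if abs(s) >= abs(c):  # dominant step along x (|d_x| = |s|)
            step_coords, perp_coords = xs, ys
            d_dom, d_perp, n_dom, n_perp = -s, c, c, s
            d_step, d_pitch = dx, dy
            dom_is_x = True
        else:
            step_coords, perp_coords = ys, xs
            d_dom, d_perp, n_dom, n_perp = c, -s, s, c
            d_step, d_pitch = dy, dx
            dom_is_x = False
        n_perp_len = len(perp_coords)
        # t at which the ray crosses each dominant-axis voxel plane
        t = (step_coords[None, :] - s_vals[:, None] * n_dom) / d_dom  # (R, Nd)
        p_perp = s_vals[:, None] * n_perp + t * d_perp  # (R, Nd)
        f = p_perp / d_pitch + (n_perp_len - 1) / 2.0
        i0 = np.floor(f).astype(np.int64)
        frac = f - i0
        dl = d_step / abs(d_dom)
        r_idx = np.broadcast_to(
            np.arange(geometry.n_radial)[:, None], f.shape
        )
        dom_idx = np.broadcast_to(np.arange(len(step_coords))[None, :], f.shape)
        for ii, ww in ((i0, 1.0 - frac), (i0 + 1, frac)):
            valid = (ii >= 0) & (ii < n_perp_len) & (ww > 0)
            if not valid.any():
                continue
            if dom_is_x:
                col = dom_idx[valid] * ny + ii[valid]
            else:
                col = ii[valid] * ny + dom_idx[valid]
            rows.append(a * geometry.n_radial + r_idx[valid])
            cols.append(col)
            wts.append(ww[valid] * dl)
            us.append(t[valid])
    return (
        np.concatenate(rows),
        np.concatenate(cols),
        np.concatenate(wts),
        np.concatenate(us),
    )


@lru_cache(maxsize=8)
def _matrices(geometry: ScannerGeometry) -> dict:
    """Build and cache the non-TOF and TOF sparse projection matrices."""
    nx, ny, _ = geometry.grid_shape
    rows, cols, wts, us = _joseph_entries(geometry)
    n_rays = geometry.n_angles * geometry.n_radial
    a_nontof = sp.csr_matrix(
        (wts, (rows, cols)), shape=(n_rays, nx * ny), dtype=np.float64
    )
    out = {"nontof": a_nontof}
    T = geometry.n_tof_bins
    if T > 1:
        sigma = geometry.tof_fwhm_mm * _FWHM_TO_SIGMA
        centers = (np.arange(T) - (T - 1) / 2.0) * geometry.tof_bin_width_mm
        g = np.exp(-((us[:, None] - centers[None, :]) ** 2) / (2.0 * sigma**2))
        g[np.abs(us[:, None] - centers[None, :]) > 3.0 * sigma] = 0.0
        tot = g.sum(axis=1)
        # emission positions beyond the outermost bin's 3-sigma reach fall
        # into the nearest bin, preserving total mass
        far = tot == 0.0
        if far.any():
            nearest = np.argmin(
                np.abs(us[far, None] - centers[None, :]), axis=1
            )
            g[np.nonzero(far)[0], nearest] = 1.0
            tot[far] = 1.0
        g /= tot[:, None]
        t_rows, t_cols, t_wts = [], [], []
        for k in range(T):
            nz = g[:, k] > 0
            t_rows.append(rows[nz] * T + k)
            t_cols.append(cols[nz])
            t_wts.append(wts[nz] * g[nz, k])
        a_tof = sp.csr_matrix(
            (np.concatenate(t_wts), (np.concatenate(t_rows), np.concatenate(t_cols))),
            shape=(n_rays * T, nx * ny),
            dtype=np.float64,
        )
        out["tof"] = a_tof
    else:
        out["tof"] = a_nontof
    return out


def split_row_indices(geometry: ScannerGeometry, angles: np.ndarray, tof: bool):
    """Sinogram row indices (flattened angle/radial[/tof]) for given angles."""
    T = geometry.n_tof_bins if tof else 1
    per_angle = geometry.n_radial * T
    return (angles[:, None] * per_angle + np.arange(per_angle)[None, :]).ravel()


# ---------------------------------------------------------------------------
# operator


class SystemModel:
    """The full forward/adjoint operator P for one acquisition.

    Bundles geometry with attenuation and normalization factors, exposes
    subset projections for ordered-subset algorithms, and caches subset
    matrices and sensitivity images.
    """

    def __init__(
        self,
        geometry: ScannerGeometry,
        atten: np.ndarray | None = None,
        norm: np.ndarray | None = None,
    ):
        self.geometry = geometry
        shape = geometry.sino_shape_nontof
        self.atten = np.ones(shape) if atten is None else np.asarray(atten, float)
        self.norm = np.ones(shape) if norm is None else np.asarray(norm, float)
        if self.atten.shape != shape or self.norm.shape != shape:
            raise ValueError("atten/norm shape inconsistent with geometry")
        self._mats = _matrices(geometry)
        self._subset_cache: dict = {}
        self._sens_cache: dict = {}

    # -- factors -----------------------------------------------------------

    def _factors(self, tof: bool) -> np.ndarray:
        f = self.geometry.count_scale * self.norm * self.atten  # (A, R, Z)
        if tof:
            return f[:, :, None, :]
        return f

    def _psf_sigma_vox(self) -> tuple[float, float, float]:
        g = self.geometry
        s = g.psf_fwhm_mm * _FWHM_TO_SIGMA
        return (s / g.voxel_size_mm[0], s / g.voxel_size_mm[1], 0.0)

    def _blur(self, image: np.ndarray) -> np.ndarray:
        if self.geometry.psf_fwhm_mm <= 0:
            return image
        # zero-padded symmetric Gaussian => the blur is self-adjoint
        return ndi.gaussian_filter(image, sigma=self._psf_sigma_vox(), mode="constant")

    # -- full projections --------------------------------------------------

    def forward(self, image: np.ndarray, tof: bool = True) -> np.ndarray:
        """P x: expected counts per sinogram bin for activity image x."""
        g = self.geometry
        if image.shape != g.grid_shape:
            raise ValueError("image shape does not match geometry grid")
        if np.any(image < 0):
            raise ValueError("negative image values rejected")
        return self._apply(image, tof, rows=None)

    def back(self, sino: np.ndarray, tof: bool = True) -> np.ndarray:
        """P^T y: exact adjoint of :meth:`forward`."""
        g = self.geometry
        expect = g.sino_shape_tof if tof else g.sino_shape_nontof
        if sino.shape != expect:
            raise ValueError("sinogram shape does not match geometry")
        return self._apply_adjoint(sino, tof, rows=None)

    # -- subset projections ------------------------------------------------

    def _subset_matrix(self, angles: tuple, tof: bool):
        key = (angles, tof)
        if key not in self._subset_cache:
            rows = split_row_indices(self.geometry, np.asarray(angles), tof)
            mat = self._mats["tof" if tof else "nontof"][rows]
            self._subset_cache[key] = (mat, mat.T.tocsr())
        return self._subset_cache[key]

    def _apply(self, image, tof, rows, angles=None):
        g = self.geometry
        nx, ny, nz = g.grid_shape
        flat = self._blur(np.asarray(image, float)).reshape(nx * ny, nz)
        if angles is None:
            mat = self._mats["tof" if tof else "nontof"]
            proj = mat @ flat
            if tof:
                proj = proj.reshape(g.n_angles, g.n_radial, g.n_tof_bins, nz)
            else:
                proj = proj.reshape(g.n_angles, g.n_radial, nz)
            return proj * self._factors(tof)
        mat, _ = self._subset_matrix(angles, tof)
        proj = mat @ flat
        na = len(angles)
        idx = np.asarray(angles)
        if tof:
            proj = proj.reshape(na, g.n_radial, g.n_tof_bins, nz)
            return proj * self._factors(tof)[idx]
        proj = proj.reshape(na, g.n_radial, nz)
        return proj * self._factors(tof)[idx]

    def _apply_adjoint(self, sino, tof, rows, angles=None):
        g = self.geometry
        nx, ny, nz = g.grid_shape
        if angles is None:
            weighted = np.asarray(sino, float) * self._factors(tof)
            mat = self._mats["tof" if tof else "nontof"]
            img = (mat.T @ weighted.reshape(-1, nz)).reshape(nx, ny, nz)
        else:
            idx = np.asarray(angles)
            weighted = np.asarray(sino, float) * self._factors(tof)[idx]
            _, mat_t = self._subset_matrix(angles, tof)
            img = (mat_t @ weighted.reshape(-1, nz)).reshape(nx, ny, nz)
        return self._blur(img)

    def forward_subset(self, image, angles: tuple, tof: bool = True):
        """Forward projection restricted to a tuple of angle indices."""
        if np.any(np.asarray(image) < 0):
            raise ValueError("negative image values rejected")
        return self._apply(image, tof, rows=None, angles=angles)

    def back_subset(self, sino, angles: tuple, tof: bool = True):
        return self._apply_adjoint(sino, tof, rows=None, angles=angles)

    # -- sensitivity -------------------------------------------------------

    def sensitivity(self, tof: bool = True, angles: tuple | None = None) -> np.ndarray:
        """Back-projection of unit weights: the EM update denominator."""
        key = (tof, angles)
        if key not in self._sens_cache:
            g = self.geometry
            if angles is None:
                ones = np.ones(g.sino_shape_tof if tof else g.sino_shape_nontof)
                self._sens_cache[key] = self._apply_adjoint(ones, tof, rows=None)
            else:
                T = g.n_tof_bins if tof else 1
                shape = (
                    (len(angles), g.n_radial, T, g.grid_shape[2])
                    if tof
                    else (len(angles), g.n_radial, g.grid_shape[2])
                )
                self._sens_cache[key] = self._apply_adjoint(
                    np.ones(shape), tof, rows=None, angles=angles
                )
        return self._sens_cache[key]


# ---------------------------------------------------------------------------
# functional wrappers


def forward_project(
    image: np.ndarray,
    geometry: ScannerGeometry,
    tof: bool = True,
    atten: np.ndarray | None = None,
    norm: np.ndarray | None = None,
) -> np.ndarray:
    """Expected sinogram of an activity image (see :class:`SystemModel`)."""
    return SystemModel(geometry, atten, norm).forward(image, tof=tof)


def back_project(
    sino: np.ndarray,
    geometry: ScannerGeometry,
    tof: bool = True,
    atten: np.ndarray | None = None,
    norm: np.ndarray | None = None,
) -> np.ndarray:
    """Exact adjoint of :func:`forward_project`."""
    return SystemModel(geometry, atten, norm).back(sino, tof=tof)


def attenuation_factors(mu_map: np.ndarray, geometry: ScannerGeometry) -> np.ndarray:
    """Survival factors exp(-integral mu dl) per (angle, radial, slice).

    ``mu_map`` is in 1/cm; line integrals are computed with the same Joseph
    projector as the emission data (no PSF, no TOF).
    """
    if mu_map.shape != geometry.grid_shape:
        raise ValueError("mu_map shape does not match geometry grid")
    if np.any(mu_map < 0):
        raise ValueError("negative attenuation coefficients rejected")
    nx, ny, nz = geometry.grid_shape
    mat = _matrices(geometry)["nontof"]
    line_mm = (mat @ mu_map.reshape(nx * ny, nz)).reshape(geometry.sino_shape_nontof)
    return np.exp(-line_mm / 10.0)  # mm -> cm
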