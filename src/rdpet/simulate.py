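"""Poisson TOF emission simulation at a 2-minute-acquisition count level.

Produces measured counts y ~ Poisson(ybar + b) where ybar is the attenuated
TOF forward projection of the phantom activity scaled by ``count_scale``,
and b is a smooth additive randoms+scatter background whose total equals a
fixed fraction of the total trues.  The reconstructor receives b exactly as
used, i.e. the scatter/randoms estimation stage is assumed ideal — this
isolates the optimizer comparison from correction-accuracy effects.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass

import numpy as np

from .phantom import PhantomImage
from .system_model import (
    ScannerGeometry,
    SinogramData,
    SystemModel,
    attenuation_factors,
)

__all__ = ["NoiseSpec", "simulate_sinogram", "split_subsets", "save_sinogram", "load_sinogram"]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise/count-level parameters for one simulated acquisition.

    ``background_fraction`` is the fraction of total trues added as the
    smooth randoms+scatter background b (typical clinical pelvic frames sit
    near 0.3).  ``count_scale`` overrides the geometry's value when given.
    """

    background_fraction: float = 0.3
    count_scale: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must be in [0, 1)")
        if self.count_scale is not None and self.count_scale <= 0:
            raise ValueError("count_scale must be > 0")


def _background_sinogram(geometry: ScannerGeometry, total: float) -> np.ndarray:
    """Radially smooth, angle- and TOF-uniform background with given total."""
    if total <= 0:
        return np.zeros(geometry.sino_shape_tof)
    r = np.arange(geometry.n_radial) - (geometry.n_radial - 1) / 2.0
    sigma = geometry.n_radial / 4.0
    profile = np.exp(-(r**2) / (2.0 * sigma**2))
    b = np.broadcast_to(
        profile[None, :, None, None], geometry.sino_shape_tof
    ).copy()
    return b * (total / b.sum())


def simulate_sinogram(
    phantom: PhantomImage, geometry: ScannerGeometry, noise: NoiseSpec
) -> SinogramData:
    """Simulate one Poisson TOF acquisition of a phantom.

    Deterministic in ``noise.rng_seed``: the same (phantom, geometry, noise)
    triple yields bit-identical counts.
    """
    if noise.count_scale is not None:
        geometry = dataclasses.replace(geometry, count_scale=noise.count_scale)
    atten = attenuation_factors(phantom.mu_map, geometry)
    system = SystemModel(geometry, atten=atten)
    ybar = system.forward(phantom.activity, tof=True)
    total_trues = float(ybar.sum())
    b = _background_sinogram(geometry, noise.background_fraction * total_trues)
    rng = np.random.default_rng(noise.rng_seed)
    y = rng.poisson(ybar + b).astype(np.int64)
    return SinogramData(
        y=y, b=b, atten=atten, norm=np.ones_like(atten), geometry=geometry,
        rng_seed=noise.rng_seed,
    )


def _bit_reversal_order(n: int) -> list[int]:
    """Permutation of range(n) by bit-reversed index (generalized to any n)."""
    bits = max(1, int(np.ceil(np.log2(max(n, 2)))))
    rev = []
    for i in range(1 << bits):
        r = int(format(i, f"0{bits}b")[::-1], 2)
        if r < n:
            rev.append(r)
    return rev


def split_subsets(geometry: ScannerGeometry, n_subsets: int) -> list[tuple[int, ...]]:
    """Interleaved partition of projection angles into ordered subsets.

    Subset m contains angles m, m + n_subsets, ...; subsets are returned in
    bit-reversal visit order so successive subsets are angularly
    decorrelated.  Sets are disjoint, cover all angles, and their sizes
    differ by at most one.
    """
    n_angles = geometry.n_angles
    if not 1 <= n_subsets <= n_angles:
        raise ValueError("need 1 <= n_subsets <= n_angles")
    subsets = [
        tuple(range(m, n_angles, n_subsets)) for m in range(n_subsets)
    ]
    return [subsets[m] for m in _bit_reversal_order(n_subsets)]


# ---------------------------------------------------------------------------
# persistence: portable arrays + JSON sidecar


def save_sinogram(sino: SinogramData, path: str | pathlib.Path) -> None:
    """Write counts/background/factors as .npz with a JSON geometry sidecar."""
    path = pathlib.Path(path)
    np.savez_compressed(path, y=sino.y, b=sino.b, atten=sino.atten, norm=sino.norm)
    sidecar = {
        "geometry": dataclasses.asdict(sino.geometry),
        "rng_seed": sino.rng_seed,
        "axis_order": "(angle, radial, tof, slice); atten/norm (angle, radial, slice)",
        "byte_order": "native (numpy .npz)",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_sinogram(path: str | pathlib.Path) -> SinogramData:
    path = pathlib.Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    gd = sidecar["geometry"]
    geometry = ScannerGeometry(
        grid_shape=tuple(gd["grid_shape"]),
        voxel_size_mm=tuple(gd["voxel_size_mm"]),
        n_angles=gd["n_angles"],
        n_radial=gd["n_radial"],
        radial_spacing_mm=gd["radial_spacing_mm"],
        n_tof_bins=gd["n_tof_bins"],
        tof_fwhm_mm=gd["tof_fwhm_mm"],
        psf_fwhm_mm=gd["psf_fwhm_mm"],
        count_scale=gd["count_scale"],
    )
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        return SinogramData(
            y=data["y"], b=data["b"], atten=data["atten"], norm=data["norm"],
            geometry=geometry, rng_seed=sidecar["rng_seed"],
        )
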