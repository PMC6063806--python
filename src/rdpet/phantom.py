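"""Digital pelvic phantoms for PET reconstruction experiments.

A phantom is a voxel grid of true tracer activity in SUV units (g/ml)
together with a 511 keV attenuation map and a set of named ROI masks.
The default phantom emulates a pelvic ^68Ga-PSMA acquisition on PET/MR:
a uniform soft-tissue background inside an elliptic body outline, a hot
urinary bladder, and spherical lesions spanning three size/uptake strata
(small & low uptake, medium, large or high uptake).  The attenuation map
contains no bone, matching MR-based attenuation correction in the pelvis.

Coordinates are voxel-centered, in mm, axis order (x, y, z) with z axial;
the grid origin is the volume center.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "PhantomValidationError",
    "Sphere",
    "Lesion",
    "PhantomSpec",
    "PhantomImage",
    "make_pelvic_phantom",
    "lesion_true_volume",
    "default_pelvic_spec",
    "sample_pelvic_spec",
    "save_phantom",
    "load_phantom",
]

#: linear attenuation of water at 511 keV, 1/cm (config constant, soft tissue)
MU_SOFT_DEFAULT = 0.096


class PhantomValidationError(ValueError):
    """Raised when a PhantomSpec violates its geometric invariants."""


@dataclass(frozen=True)
class Sphere:
    center_mm: tuple[float, float, float]
    radius_mm: float
    suv: float = 0.0


@dataclass(frozen=True)
class Lesion:
    lesion_id: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    suv: float


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a pelvic phantom.

    ``body_axes_mm`` are the in-plane semi-axes of the elliptic body
    outline (the body spans all axial slices).  ``background_roi`` is a
    sphere placed in uniform soft tissue, used for noise measurements.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 16)
    voxel_size_mm: tuple[float, float, float] = (2.34, 2.34, 2.78)
    background_suv: float = 1.0
    body_axes_mm: tuple[float, float] = (95.0, 80.0)
    bladder: Sphere | None = Sphere((0.0, -30.0, 0.0), 22.0, 7.7)
    lesions: tuple[Lesion, ...] = ()
    background_roi: Sphere = Sphere((-45.0, -35.0, 0.0), 12.0)
    mu_soft: float = MU_SOFT_DEFAULT
    rng_seed: int = 0

    def validate(self) -> None:
        if self.background_suv <= 0:
            raise PhantomValidationError("background_suv must be > 0")
        if self.background_roi.radius_mm <= 0:
            raise PhantomValidationError("background ROI radius must be > 0")
        spheres: list[tuple[str, Sphere]] = [
            (les.lesion_id, Sphere(les.center_mm, les.radius_mm, les.suv))
            for les in self.lesions
        ]
        ids = [name for name, _ in spheres]
        if len(set(ids)) != len(ids):
            raise PhantomValidationError("duplicate lesion ids")
        if self.bladder is not None:
            spheres.append(("bladder", self.bladder))
        spheres.append(("background", self.background_roi))
        ax, ay = self.body_axes_mm
        for name, sph in spheres:
            if sph.radius_mm <= 0:
                raise PhantomValidationError(f"{name}: radius must be > 0")
            cx, cy, _ = sph.center_mm
            # sphere must sit inside the elliptic body outline (conservative:
            # inflate the test point by the radius along both semi-axes)
            if ((abs(cx) + sph.radius_mm) / ax) ** 2 + (
                (abs(cy) + sph.radius_mm) / ay
            ) ** 2 > 1.0:
                raise PhantomValidationError(f"{name}: not inside body outline")
        # pairwise disjointness of lesions, bladder and background ROI
        for i in range(len(spheres)):
            for j in range(i + 1, len(spheres)):
                (na, a), (nb, b) = spheres[i], spheres[j]
                d = np.linalg.norm(np.subtract(a.center_mm, b.center_mm))
                if d < a.radius_mm + b.radius_mm:
                    raise PhantomValidationError(f"overlapping ROIs: {na} / {nb}")


@dataclass
class PhantomImage:
    """Voxelized phantom: activity (SUV), attenuation map, named ROI masks."""

    activity: np.ndarray
    mu_map: np.ndarray
    masks: dict[str, np.ndarray]
    voxel_size_mm: tuple[float, float, float]
    spec: PhantomSpec

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


def voxel_centers(
    grid_shape: tuple[int, int, int], voxel_size_mm: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-axis voxel-center coordinates in mm, origin at the grid center."""
    return tuple(
        (np.arange(n) - (n - 1) / 2.0) * dv
        for n, dv in zip(grid_shape, voxel_size_mm)
    )


def _sphere_mask(spec: PhantomSpec, sph: Sphere) -> np.ndarray:
    # center-in-sphere voxelization: a voxel belongs to the sphere iff its
    # center does (simplest reproducible partial-volume rule)
    xs, ys, zs = voxel_centers(spec.grid_shape, spec.voxel_size_mm)
    cx, cy, cz = sph.center_mm
    d2 = (
        (xs[:, None, None] - cx) ** 2
        + (ys[None, :, None] - cy) ** 2
        + (zs[None, None, :] - cz) ** 2
    )
    return d2 <= sph.radius_mm**2


def _body_mask(spec: PhantomSpec) -> np.ndarray:
    xs, ys, _ = voxel_centers(spec.grid_shape, spec.voxel_size_mm)
    ax, ay = spec.body_axes_mm
    inplane = (xs[:, None] / ax) ** 2 + (ys[None, :] / ay) ** 2 <= 1.0
    return np.broadcast_to(inplane[:, :, None], spec.grid_shape).copy()


def make_pelvic_phantom(spec: PhantomSpec) -> PhantomImage:
    """Voxelize a PhantomSpec into activity, attenuation map and ROI masks.

    Activity equals ``background_suv`` inside the body and 0 outside;
    bladder/lesion voxels are overwritten with their SUV.  The attenuation
    map is ``mu_soft`` inside the body, 0 outside (no bone).  Raises
    :class:`PhantomValidationError` on overlapping ROI definitions.
    """
    spec.validate()
    body = _body_mask(spec)
    activity = np.where(body, spec.background_suv, 0.0)
    mu_map = np.where(body, spec.mu_soft, 0.0)
    masks: dict[str, np.ndarray] = {"body": body}

    if spec.bladder is not None:
        m = _sphere_mask(spec, spec.bladder) & body
        activity[m] = spec.bladder.suv
        masks["bladder"] = m
    for les in spec.lesions:
        m = _sphere_mask(spec, Sphere(les.center_mm, les.radius_mm)) & body
        if not m.any():
            raise PhantomValidationError(
                f"lesion {les.lesion_id!r} voxelizes to an empty mask"
            )
        activity[m] = les.suv
        masks[les.lesion_id] = m
    masks["background"] = _sphere_mask(spec, spec.background_roi) & body

    return PhantomImage(
        activity=activity,
        mu_map=mu_map,
        masks=masks,
        voxel_size_mm=spec.voxel_size_mm,
        spec=spec,
    )


def lesion_true_volume(phantom: PhantomImage, lesion_id: str) -> float:
    """True lesion volume in cm^3: mask voxel count x voxel volume."""
    if lesion_id not in phantom.masks:
        raise KeyError(f"unknown lesion id {lesion_id!r}")
    n = int(phantom.masks[lesion_id].sum())
    if n == 0:
        raise PhantomValidationError(f"lesion {lesion_id!r} has an empty mask")
    return n * phantom.voxel_volume_cm3


def _radius_for_volume(volume_cm3: float) -> float:
    """Radius in mm of a sphere with the given volume in cm^3."""
    return float((3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def default_pelvic_spec(rng_seed: int = 0) -> PhantomSpec:
    """Default phantom: one lesion per stratum plus bladder and background ROI.

    Lesion volumes 0.5 / 3 / 12 cm^3 with SUV 4 / 7 / 20 g/ml, so that on a
    reference reconstruction they fall in the small&low, medium and
    large-or-high strata respectively.  Bladder SUV 7.7 g/ml (furosemide-
    reduced bladder uptake level).
    """
    lesions = (
        Lesion("lesion_small_low", (50.0, 20.0, 0.0), _radius_for_volume(0.5), 4.0),
        Lesion("lesion_medium", (-50.0, 20.0, 0.0), _radius_for_volume(3.0), 7.0),
        Lesion("lesion_large_high", (0.0, 45.0, 0.0), _radius_for_volume(12.0), 20.0),
    )
    return PhantomSpec(lesions=lesions, rng_seed=rng_seed)


def sample_pelvic_spec(rng_seed: int) -> PhantomSpec:
    """Draw a population variant of the default phantom.

    Lesion radii and SUVs are jittered (+-15%) and centers displaced by up
    to 3 mm in-plane, emulating between-patient lesion diversity while
    keeping each lesion well inside its intended stratum.  Deterministic in
    ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    base = default_pelvic_spec(rng_seed)
    lesions = []
    for les in base.lesions:
        scale_r = 1.0 + rng.uniform(-0.15, 0.15)
        scale_s = 1.0 + rng.uniform(-0.15, 0.15)
        dx, dy = rng.uniform(-3.0, 3.0, size=2)
        lesions.append(
            Lesion(
                les.lesion_id,
                (les.center_mm[0] + dx, les.center_mm[1] + dy, les.center_mm[2]),
                les.radius_mm * scale_r,
                les.suv * scale_s,
            )
        )
    bl = base.bladder
    bladder = Sphere(bl.center_mm, bl.radius_mm, bl.suv * (1.0 + rng.uniform(-0.2, 0.2)))
    return dataclasses.replace(
        base, lesions=tuple(lesions), bladder=bladder, rng_seed=rng_seed
    )


# ---------------------------------------------------------------------------
# NIfTI + JSON-sidecar persistence


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_phantom(phantom: PhantomImage, out_dir: str | pathlib.Path) -> None:
    """Write activity, mu_map and each mask as NIfTI plus a JSON sidecar."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(phantom.voxel_size_mm)
    nib.save(nib.Nifti1Image(phantom.activity.astype(np.float64), aff), out / "activity.nii")
    nib.save(nib.Nifti1Image(phantom.mu_map.astype(np.float64), aff), out / "mu_map.nii")
    for name, mask in phantom.masks.items():
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff), out / f"mask_{name}.nii")
    sidecar = {
        "spec": dataclasses.asdict(phantom.spec),
        "axis_order": "xyz (z axial)",
        "units": {"activity": "SUV g/ml", "mu_map": "1/cm", "coordinates": "mm"},
    }
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(in_dir: str | pathlib.Path) -> PhantomImage:
    src = pathlib.Path(in_dir)
    sidecar = json.loads((src / "phantom.json").read_text())
    sp = sidecar["spec"]
    spec = PhantomSpec(
        grid_shape=tuple(sp["grid_shape"]),
        voxel_size_mm=tuple(sp["voxel_size_mm"]),
        background_suv=sp["background_suv"],
        body_axes_mm=tuple(sp["body_axes_mm"]),
        bladder=Sphere(tuple(sp["bladder"]["center_mm"]), sp["bladder"]["radius_mm"], sp["bladder"]["suv"])
        if sp["bladder"]
        else None,
        lesions=tuple(
            Lesion(l["lesion_id"], tuple(l["center_mm"]), l["radius_mm"], l["suv"])
            for l in sp["lesions"]
        ),
        background_roi=Sphere(
            tuple(sp["background_roi"]["center_mm"]),
            sp["background_roi"]["radius_mm"],
            sp["background_roi"]["suv"],
        ),
        mu_soft=sp["mu_soft"],
        rng_seed=sp["rng_seed"],
    )
    activity = np.asarray(nib.load(src / "activity.nii").dataobj, dtype=np.float64)
    mu_map = np.asarray(nib.load(src / "mu_map.nii").dataobj, dtype=np.float64)
    masks = {
        p.stem[len("mask_"):]: np.asarray(nib.load(p).dataobj).astype(bool)
        for p in sorted(src.glob("mask_*.nii"))
    }
    return PhantomImage(activity, mu_map, masks, spec.voxel_size_mm, spec)
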