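"""MLEM/OSEM and BSREM optimizers for penalized Poisson likelihood.

The objective maximized by BSREM is

    Phi(x) = sum_i [ y_i log([Px]_i + b_i) - ([Px]_i + b_i) ] - beta R(x)

with P the TOF system operator, b the additive randoms+scatter background
and R the relative difference penalty (gamma = 2 by default):

    R(x) = sum_j sum_{k in N_j} w_j w_k  (x_j - x_k)^2
           / ((x_j + x_k) + gamma |x_j - x_k|)

over a 3D 26-neighborhood with edge weights proportional to the inverse
center-to-center distance in voxel units.  The penalty is degree-1
homogeneous, which makes the noise control activity-dependent, and gamma
controls edge preservation.

BSREM cycles through angular subsets; each sub-iteration for subset m is a
preconditioned, relaxed, clipped ascent step

    x <- clip( x + alpha_k D(x) grad Phi_m(x), [0, U] ),
    Phi_m = M * (subset log-likelihood) - beta R,   D = diag((x+eps)/s),

with s the full sensitivity image, M the number of subsets and
alpha_k = alpha0 / (1 + decay * k) decaying over full iterations k.  With
beta=0, one subset, alpha=1 and eps=0 a BSREM step reduces exactly to MLEM.
The default schedule initializes with 2 iterations of non-TOF OSEM and 3
iterations of non-TOF BSREM followed by 8 iterations of TOF BSREM, all
with 28 subsets; non-TOF stages run on the TOF sinogram summed over TOF
bins.  OSEM is the classical ordered-subset EM; the clinical reference
protocol is OSEM with 2 iterations / 28 subsets followed by the
:func:`post_filter` (BSREM results are not post-filtered).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from numba import njit

from .simulate import split_subsets
from .system_model import SinogramData, SystemModel

__all__ = [
    "RDPParams",
    "ReconStage",
    "ReconSchedule",
    "ReconResult",
    "default_schedule",
    "rdp_value",
    "rdp_gradient",
    "poisson_loglik",
    "objective_value",
    "mlem_update",
    "osem_reconstruct",
    "bsrem_reconstruct",
    "post_filter",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# 13 unique neighbor offsets of the 26-neighborhood (the other 13 are their
# negatives); paired with inverse-distance edge weights in voxel units
_OFFSETS = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)
_OFFSET_W = 1.0 / np.sqrt((_OFFSETS**2).sum(axis=1).astype(np.float64))


@dataclass(frozen=True)
class RDPParams:
    """Relative difference penalty parameters.

    ``beta`` is the global regularization strength; ``gamma`` the edge
    preservation parameter; ``local_weights`` optional per-voxel multipliers
    w_j (default 1 everywhere).
    """

    beta: float
    gamma: float = 2.0
    local_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.local_weights is not None and np.any(self.local_weights < 0):
            raise ValueError("local weights must be >= 0")


@njit(cache=False)
def _rdp_kernels(x, wloc, offsets, offw, gamma, grad, compute_grad):
    nx, ny, nz = x.shape
    total = 0.0
    for m in range(offsets.shape[0]):
        ox, oy, oz = offsets[m, 0], offsets[m, 1], offsets[m, 2]
        w0 = offw[m]
        for i in range(max(0, -ox), min(nx, nx - ox)):
            for j in range(max(0, -oy), min(ny, ny - oy)):
                for k in range(max(0, -oz), min(nz, nz - oz)):
                    xj = x[i, j, k]
                    xk = x[i + ox, j + oy, k + oz]
                    d = xj - xk
                    ad = abs(d)
                    den = xj + xk + gamma * ad
                    if den <= 0.0:
                        continue
                    w = w0 * wloc[i, j, k] * wloc[i + ox, j + oy, k + oz]
                    # each unordered pair appears twice in the double sum
                    total += 2.0 * w * d * d / den
                    if compute_grad:
                        # d psi/d x_j = d (x_j + 3 x_k + gamma|d|) / den^2
                        den2 = den * den
                        grad[i, j, k] += 2.0 * w * d * (xj + 3.0 * xk + gamma * ad) / den2
                        grad[i + ox, j + oy, k + oz] += (
                            -2.0 * w * d * (xk + 3.0 * xj + gamma * ad) / den2
                        )
    return total


def _weights_array(x: np.ndarray, params: RDPParams) -> np.ndarray:
    if params.local_weights is None:
        return np.ones_like(x)
    w = np.asarray(params.local_weights, dtype=np.float64)
    if w.shape != x.shape:
        raise ValueError("local_weights shape must match image")
    return w


def rdp_value(x: np.ndarray, params: RDPParams) -> float:
    """Relative difference penalty R(x); pairs with x_j = x_k = 0 contribute 0."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    dummy = np.zeros((1, 1, 1))
    return float(
        _rdp_kernels(
            x, _weights_array(x, params), _OFFSETS, _OFFSET_W, params.gamma, dummy, False
        )
    )


def rdp_gradient(x: np.ndarray, params: RDPParams) -> np.ndarray:
    """Exact gradient of :func:`rdp_value`; zero on constant images."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    grad = np.zeros_like(x)
    _rdp_kernels(
        x, _weights_array(x, params), _OFFSETS, _OFFSET_W, params.gamma, grad, True
    )
    return grad


# ---------------------------------------------------------------------------
# likelihood and objective


def poisson_loglik(
    x: np.ndarray, sinogram: SinogramData, system: SystemModel, tof: bool = True
) -> float:
    """Poisson log-likelihood sum_i [y_i log(ybar_i) - ybar_i], ybar = Px + b.

    Uses the 0*log 0 = 0 convention; returns -inf if some bin has counts but
    zero expectation.
    """
    if np.any(np.asarray(x) < 0):
        raise ValueError("x must be nonnegative")
    y = sinogram.y if tof else sinogram.y_nontof
    b = sinogram.b if tof else sinogram.b_nontof
    ybar = system.forward(x, tof=tof) + b
    pos = ybar > 0
    if np.any((~pos) & (y > 0)):
        return float("-inf")
    return float(np.sum(y[pos] * np.log(ybar[pos])) - float(ybar.sum()))


def objective_value(
    x: np.ndarray,
    sinogram: SinogramData,
    system: SystemModel,
    rdp: RDPParams,
    tof: bool = True,
) -> float:
    """Penalized likelihood: poisson_loglik(x) - beta * rdp_value(x)."""
    pen = rdp.beta * rdp_value(x, rdp) if rdp.beta > 0 else 0.0
    return poisson_loglik(x, sinogram, system, tof=tof) - pen


# ---------------------------------------------------------------------------
# EM updates


def _em_ratio_back(x, sinogram, system, tof, angles=None):
    """Back-projection of y / (Px + b), restricted to a subset if given."""
    if angles is None:
        y = sinogram.y if tof else sinogram.y_nontof
        b = sinogram.b if tof else sinogram.b_nontof
        ybar = system.forward(x, tof=tof) + b
        ratio = np.where(ybar > 0, y / np.where(ybar > 0, ybar, 1.0), 0.0)
        return system.back(ratio, tof=tof)
    idx = np.asarray(angles)
    y = (sinogram.y if tof else sinogram.y_nontof)[idx]
    b = (sinogram.b if tof else sinogram.b_nontof)[idx]
    ybar = system.forward_subset(x, angles, tof=tof) + b
    ratio = np.where(ybar > 0, y / np.where(ybar > 0, ybar, 1.0), 0.0)
    return system.back_subset(ratio, angles, tof=tof)


def mlem_update(
    x: np.ndarray,
    sinogram: SinogramData,
    system: SystemModel,
    tof: bool = True,
    angles: tuple | None = None,
) -> np.ndarray:
    """One (subset-)EM multiplicative update x' = (x/s) * P^T(y / (Px+b))."""
    if np.any(np.asarray(x) < 0):
        raise ValueError("x must be nonnegative")
    s = system.sensitivity(tof=tof, angles=angles)
    fov = s > 0
    if not fov.any():
        raise ValueError("zero sensitivity everywhere")
    num = _em_ratio_back(x, sinogram, system, tof, angles)
    out = np.zeros_like(np.asarray(x, dtype=np.float64))
    out[fov] = x[fov] / s[fov] * num[fov]
    return out


# ---------------------------------------------------------------------------
# schedules and results


@dataclass(frozen=True)
class ReconStage:
    algorithm: str  # "osem" | "bsrem"
    tof: bool
    n_iterations: int

    def __post_init__(self) -> None:
        if self.algorithm not in ("osem", "bsrem"):
            raise ValueError("algorithm must be 'osem' or 'bsrem'")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class ReconSchedule:
    """Staged reconstruction schedule with relaxation and bound parameters.

    Defaults follow the clinical BSREM protocol: 2 iterations of non-TOF
    OSEM, 3 of non-TOF BSREM, then 8 of TOF BSREM, all with 28 subsets.
    ``upper_bound`` caps the image (SUV); ``epsilon`` stabilizes the
    preconditioner near zero.
    """

    n_subsets: int = 28
    stages: tuple[ReconStage, ...] = (
        ReconStage("osem", False, 2),
        ReconStage("bsrem", False, 3),
        ReconStage("bsrem", True, 8),
    )
    alpha0: float = 1.0
    decay: float = 0.05
    upper_bound: float = 200.0
    epsilon: float | None = None  # None -> 1e-6 * upper_bound

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be > 0")
        if self.upper_bound <= 0:
            raise ValueError("upper_bound must be > 0")

    @property
    def eps(self) -> float:
        return 1e-6 * self.upper_bound if self.epsilon is None else self.epsilon


def default_schedule(**kwargs) -> ReconSchedule:
    return ReconSchedule(**kwargs)


@dataclass
class ReconResult:
    """Reconstructed SUV image with provenance and an optional objective trace."""

    image: np.ndarray
    algorithm: str
    schedule: ReconSchedule | None
    beta: float
    post_filtered: bool
    objective_trace: np.ndarray
    trace_granularity: str  # "none" | "iteration" | "subiteration"
    rng_seed: int | None = None
    n_iterations: int | None = None
    n_subsets: int | None = None


# ---------------------------------------------------------------------------
# OSEM


def osem_reconstruct(
    sinogram: SinogramData,
    system: SystemModel,
    n_iterations: int,
    n_subsets: int,
    tof: bool = True,
    init: np.ndarray | None = None,
    track_objective: str = "none",
    callback=None,
) -> ReconResult:
    """Ordered-subset EM from a uniform start image; result is unfiltered.

    With ``n_subsets=1`` this is exactly ``n_iterations`` MLEM updates.
    ``callback(iteration, image)`` is invoked after each full iteration.
    """
    g = system.geometry
    subsets = split_subsets(g, n_subsets)
    x = np.ones(g.grid_shape) if init is None else np.asarray(init, float).copy()
    fov = system.sensitivity(tof=tof) > 0
    x *= fov
    trace = []
    for it in range(n_iterations):
        for sub in subsets:
            x = mlem_update(x, sinogram, system, tof=tof, angles=sub)
            if track_objective == "subiteration":
                trace.append(poisson_loglik(x, sinogram, system, tof=tof))
        if track_objective == "iteration":
            trace.append(poisson_loglik(x, sinogram, system, tof=tof))
        if callback is not None:
            callback(it + 1, x)
    return ReconResult(
        image=x,
        algorithm="OSEM" if n_subsets > 1 else "MLEM",
        schedule=None,
        beta=0.0,
        post_filtered=False,
        objective_trace=np.asarray(trace),
        trace_granularity=track_objective,
        rng_seed=sinogram.rng_seed,
        n_iterations=n_iterations,
        n_subsets=n_subsets,
    )


# ---------------------------------------------------------------------------
# BSREM


def _bsrem_subiteration(x, sinogram, system, rdp, schedule, tof, angles, alpha, sens):
    """One relaxed preconditioned ascent step on the subset objective."""
    n_subsets = schedule.n_subsets
    idx = np.asarray(angles)
    y = (sinogram.y if tof else sinogram.y_nontof)[idx]
    b = (sinogram.b if tof else sinogram.b_nontof)[idx]
    ybar = system.forward_subset(x, angles, tof=tof) + b
    ratio = np.where(ybar > 0, y / np.where(ybar > 0, ybar, 1.0), 0.0)
    # grad of subset log-likelihood: P_m^T (y/ybar - 1)
    grad_ll = system.back_subset(ratio - 1.0, angles, tof=tof)
    grad = n_subsets * grad_ll
    if rdp.beta > 0:
        grad -= rdp.beta * rdp_gradient(x, rdp)
    fov = sens > 0
    step = np.zeros_like(x)
    step[fov] = alpha * (x[fov] + schedule.eps) / sens[fov] * grad[fov]
    return np.clip(x + step, 0.0, schedule.upper_bound)


def bsrem_reconstruct(
    sinogram: SinogramData,
    system: SystemModel,
    rdp: RDPParams,
    schedule: ReconSchedule | None = None,
    init: np.ndarray | None = None,
    track_objective: str = "none",
    callback=None,
) -> ReconResult:
    """Run the staged BSREM schedule; the result is not post-filtered.

    ``track_objective`` records the full-data TOF penalized objective after
    each full iteration ("iteration") or each sub-iteration
    ("subiteration"); tracking costs one full forward projection per entry.
    ``callback(full_iteration, image)`` fires after every full iteration,
    counted across all stages.  Raises if the objective becomes non-finite
    (flagged with the sub-iteration index).
    """
    schedule = default_schedule() if schedule is None else schedule
    g = system.geometry
    subsets = split_subsets(g, schedule.n_subsets)
    x = np.ones(g.grid_shape) if init is None else np.asarray(init, float).copy()
    fov = system.sensitivity(tof=True) > 0
    x *= fov
    trace = []
    k_bsrem = 0  # relaxation index: full iterations of BSREM stages
    it_total = 0
    sub_total = 0
    for stage in schedule.stages:
        sens = system.sensitivity(tof=stage.tof)
        for _ in range(stage.n_iterations):
            if stage.algorithm == "osem":
                for sub in subsets:
                    x = mlem_update(x, sinogram, system, tof=stage.tof, angles=sub)
                    sub_total += 1
                    if track_objective == "subiteration":
                        trace.append(
                            objective_value(x, sinogram, system, rdp, tof=True)
                        )
            else:
                alpha = schedule.alpha0 / (1.0 + schedule.decay * k_bsrem)
                for sub in subsets:
                    x = _bsrem_subiteration(
                        x, sinogram, system, rdp, schedule, stage.tof, sub, alpha, sens
                    )
                    sub_total += 1
                    if not np.all(np.isfinite(x)):
                        raise FloatingPointError(
                            f"non-finite image at sub-iteration {sub_total}"
                        )
                    if track_objective == "subiteration":
                        val = objective_value(x, sinogram, system, rdp, tof=True)
                        if not np.isfinite(val):
                            raise FloatingPointError(
                                f"non-finite objective at sub-iteration {sub_total}"
                            )
                        trace.append(val)
                k_bsrem += 1
            it_total += 1
            if track_objective == "iteration":
                trace.append(objective_value(x, sinogram, system, rdp, tof=True))
            if callback is not None:
                callback(it_total, x)
    return ReconResult(
        image=x,
        algorithm="BSREM",
        schedule=schedule,
        beta=rdp.beta,
        post_filtered=False,
        objective_trace=np.asarray(trace),
        trace_granularity=track_objective,
        rng_seed=sinogram.rng_seed,
        n_iterations=it_total,
        n_subsets=schedule.n_subsets,
    )


# ---------------------------------------------------------------------------
# post-filter


def post_filter(
    image: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    in_plane_fwhm_mm: float = 5.0,
    axial_weights: tuple[float, float, float] = (1.0, 4.0, 1.0),
) -> np.ndarray:
    """Clinical OSEM post-filter: 5 mm in-plane Gaussian, then 1:4:1 axially.

    Both kernels are normalized to unit sum; edges are handled by
    renormalized truncation, so a constant image is left unchanged.
    Requires at least 3 axial slices.
    """
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("post_filter requires a 3D image with >= 3 slices")
    sig = (
        in_plane_fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm[0],
        in_plane_fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm[1],
        0.0,
    )
    blurred = ndi.gaussian_filter(np.asarray(image, float), sigma=sig, mode="constant")
    support = ndi.gaussian_filter(np.ones_like(image, dtype=float), sigma=sig, mode="constant")
    blurred = blurred / support
    w = np.asarray(axial_weights, dtype=np.float64)
    out = np.zeros_like(blurred)
    norm = np.zeros(image.shape[2])
    acc = np.zeros_like(blurred)
    for off, wi in zip((-1, 0, 1), w):
        lo, hi = max(0, -off), min(image.shape[2], image.shape[2] - off)
        acc[:, :, lo:hi] += wi * blurred[:, :, lo + off : hi + off]
        norm[lo:hi] += wi
    out = acc / norm[None, None, :]
    return out
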