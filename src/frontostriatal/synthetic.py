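"""Synthetic BOLD runs, physiological traces and diffusion-tensor phantoms.

Everything downstream (GLM, cluster inference, FIR time courses, FACT
tracking, fiber connectivity) is exercised on data from this module, with
ground truth known by construction:

* BOLD runs: baseline + canonical-HRF responses per region and condition
  + low-frequency cosine drift + cardiac/respiratory pulsatility built
  from the RETROICOR basis of a simulated trace + AR(1) noise.
* Physio traces: spike-like ECG at the cardiac rate (Gaussian beat
  jitter) and a quasi-sinusoidal respiration channel, both at 500 Hz.
* Tensor phantoms: tubular bundles around parametric curves whose
  principal eigenvector follows the local tangent at a prescribed FA,
  on an isotropic background (fixed tensor trace 2.1e-3 mm^2/s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import physio as phys
from .designs import AMPLITUDES, BlockSchedule, EventSchedule, SIDES
from .glm import hrf_regressor

__all__ = [
    "NoiseParams", "PhysioParams", "GroundTruth", "SimulatedPhysio",
    "BundleCurve", "line_curve", "arc_curve", "simulate_physio",
    "simulate_bold_run", "simulate_tensor_phantom", "set_region_fa",
    "tensor_from_direction", "DEFAULT_SHAPE", "DEFAULT_VOXEL_MM", "BASELINE",
]

log = logging.getLogger(__name__)

#: Desk-scale analogue of a 2 mm isotropic acquisition.
DEFAULT_SHAPE = (24, 24, 18)
DEFAULT_VOXEL_MM = 2.0
BASELINE = 100.0
TENSOR_TRACE = 2.1e-3  # mm^2/s, fixed so FA is the single free parameter


@dataclass
class NoiseParams:
    """Temporal noise: AR(1) coefficient, stationary SD, cosine drift.

    Drift is a random combination of the *drift_components* slowest
    discrete-cosine basis functions of the run (all with period above the
    128 s high-pass cutoff), so the planted drift lies in the null space
    of the high-pass filter and planted task effects stay identifiable.
    """

    rho: float = 0.3
    sd: float = 1.0                      # stationary SD, units of raw signal (1 == 1% of baseline)
    drift_sd: float = 1.0                # per-component voxel-wise coefficient SD
    drift_components: int = 3
    drift_cutoff_s: float = 128.0

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("AR(1) rho must lie in [0, 1)")
        if self.drift_components < 0:
            raise ValueError("drift_components must be >= 0")


@dataclass
class PhysioParams:
    """Cardiac/respiratory rates and voxel-wise pulsatility strength."""

    cardiac_hz: float = 1.0
    resp_hz: float = 0.25
    pulsatility_sd: float = 0.5  # SD of per-voxel coefficients on the RETROICOR basis

    def __post_init__(self) -> None:
        if self.cardiac_hz <= 0 or self.resp_hz <= 0:
            raise ValueError("physiological rates must be positive")


@dataclass
class GroundTruth:
    """Planted structure of one simulated participant.

    ``effect_amplitudes`` maps region label -> {condition: percent signal
    change}.  Conditions name groups of schedule events: ``pro``/``anti``
    (all target events of that task), side-specific ``pro_L`` .. ``anti_R``,
    ``cue_pro``/``cue_anti``, ``return``, or any block label.
    """

    region_masks: dict
    effect_amplitudes: dict
    noise: NoiseParams = field(default_factory=NoiseParams)
    physio: PhysioParams = field(default_factory=PhysioParams)
    bundle_geometries: list = field(default_factory=list)
    shape: tuple = DEFAULT_SHAPE
    voxel_mm: float = DEFAULT_VOXEL_MM
    origin_mm: tuple = (0.0, 0.0, 0.0)  # world position of voxel (0,0,0) center

    def __post_init__(self) -> None:
        for label, mask in self.region_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != tuple(self.shape):
                raise ValueError(f"region {label!r} mask does not match the grid")
            if not mask.any():
                raise ValueError(f"region {label!r} is empty")
            self.region_masks[label] = mask
        for label in self.effect_amplitudes:
            if label not in self.region_masks:
                raise ValueError(f"amplitudes given for unknown region {label!r}")
        lo = np.asarray(self.origin_mm) - self.voxel_mm
        hi = np.asarray(self.origin_mm) + np.asarray(self.shape) * self.voxel_mm
        for curve in self.bundle_geometries:
            pts = np.asarray(curve.points)
            if np.any(pts < lo) or np.any(pts > hi):
                raise ValueError("bundle curve leaves the volume bounding box")

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[0, 0] = A[1, 1] = A[2, 2] = self.voxel_mm
        A[:3, 3] = self.origin_mm
        return A


@dataclass
class SimulatedPhysio:
    """A physio trace together with its ground-truth R-peak times."""

    trace: phys.PhysioTrace
    r_peak_times: np.ndarray


def simulate_physio(
    duration_s: float,
    cardiac_hz: float = 1.0,
    resp_hz: float = 0.25,
    seed: int = 0,
    beat_jitter_frac: float = 0.02,
    spike_width_s: float = 0.015,
    noise_sd: float = 0.02,
) -> SimulatedPhysio:
    """Two-channel physiological recording with known beat times.

    R peaks sit at multiples of the beat interval with Gaussian jitter
    (SD = *beat_jitter_frac* of the interval); each renders as a narrow
    unit-height Gaussian spike.  Respiration is a sinusoid at *resp_hz*
    with slow amplitude modulation.  Ground-truth peak times (including a
    peak at exactly t = duration when the rate divides it) are returned
    alongside the trace.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not (0.05 < cardiac_hz < 3) or not (0.05 < resp_hz < 3):
        raise ValueError("physiological rates must lie in (0.05, 3) Hz")
    rng = np.random.default_rng(seed)
    fs = phys.PHYSIO_RATE_HZ
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    interval = 1.0 / cardiac_hz
    nominal = np.arange(0.0, duration_s + interval / 2, interval)
    nominal = nominal[nominal <= duration_s + 1e-9]
    jitter = rng.normal(0.0, beat_jitter_frac * interval, size=nominal.size)
    if beat_jitter_frac == 0:
        jitter[:] = 0.0
    peaks = np.sort(np.clip(nominal + jitter, 0.0, duration_s))

    ecg = np.zeros(n)
    for pk in peaks:
        lo = max(0, int((pk - 5 * spike_width_s) * fs))
        hi = min(n, int((pk + 5 * spike_width_s) * fs) + 1)
        ecg[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - pk) / spike_width_s) ** 2)
    ecg += rng.normal(0.0, noise_sd, size=n)

    am = 1.0 + 0.1 * np.sin(2 * np.pi * 0.01 * t + rng.uniform(0, 2 * np.pi))
    resp = am * np.sin(2 * np.pi * resp_hz * t + rng.uniform(0, 2 * np.pi))
    resp += rng.normal(0.0, noise_sd, size=n)

    trace = phys.PhysioTrace(ecg=ecg, respiration=resp)
    return SimulatedPhysio(trace=trace, r_peak_times=peaks)


# condition key -> schedule event labels
def _condition_labels(condition: str) -> list[str]:
    if condition in ("pro", "anti"):
        return [f"target_{s}_{a}_{condition}" for s in SIDES for a in AMPLITUDES]
    if condition.startswith(("pro_", "anti_")):
        task, side = condition.split("_")
        return [f"target_{side}_{a}_{task}" for a in AMPLITUDES]
    if condition in ("cue_pro", "cue_anti"):
        return [condition]
    if condition == "return":
        return [f"return_{s}_{a}" for s in SIDES for a in AMPLITUDES]
    return [condition]  # block label


def _condition_regressor(schedule, condition: str, n_volumes: int, tr: float) -> np.ndarray:
    if isinstance(schedule, BlockSchedule):
        sel = schedule.blocks[schedule.blocks["trial_type"] == condition]
        if sel.empty:
            raise ValueError(f"block label {condition!r} not in schedule")
        return hrf_regressor(sel["onset"].to_numpy(), n_volumes, tr,
                             durations=sel["duration"].to_numpy())
    onsets = np.concatenate([schedule.onsets(lab) for lab in _condition_labels(condition)])
    onsets = onsets[(onsets >= 0) & (onsets < n_volumes * tr)]
    if onsets.size == 0:
        raise ValueError(f"no events for planted condition {condition!r}")
    return hrf_regressor(np.sort(onsets), n_volumes, tr)


def simulate_bold_run(
    schedule,
    truth: GroundTruth,
    tr: float = 2.1,
    n_volumes: int | None = None,
    seed: int = 0,
    physio_sim: SimulatedPhysio | None = None,
    baseline: float = BASELINE,
) -> np.ndarray:
    """4-D BOLD series (x, y, z, t) with planted effects; bit-reproducible.

    Signal = baseline + HRF-convolved condition responses per region
    (percent of baseline) + cosine drift + pulsatility in the span of the
    RETROICOR basis of *physio_sim* + AR(1) noise.
    """
    if n_volumes is None:
        n_volumes = int(np.ceil(schedule.run_duration / tr))
    if schedule.run_duration > n_volumes * tr + 1e-9:
        raise ValueError("schedule is longer than the simulated series")
    rng = np.random.default_rng(seed)
    shape = tuple(truth.shape)
    n_vox = int(np.prod(shape))
    Y = np.full((n_volumes, n_vox), float(baseline))

    # planted regional responses
    for region, amps in truth.effect_amplitudes.items():
        idx = np.flatnonzero(truth.region_masks[region].ravel())
        for condition, amp_pct in amps.items():
            if amp_pct == 0:
                continue
            reg = _condition_regressor(schedule, condition, n_volumes, tr)
            Y[:, idx] += (amp_pct / 100.0 * baseline) * reg[:, None]

    # low-frequency drift: slow cosines with periods beyond the 128 s cutoff
    tvol = np.arange(n_volumes) * tr
    if truth.noise.drift_sd > 0 and truth.noise.drift_components > 0:
        from .glm import dct_highpass_basis

        basis = dct_highpass_basis(n_volumes, tr, truth.noise.drift_cutoff_s)
        k = min(truth.noise.drift_components, basis.shape[1])
        if k:
            # scale so a unit coefficient has unit peak amplitude
            comp = basis[:, :k] / np.abs(basis[:, :k]).max(axis=0)
            coefs = rng.normal(0.0, truth.noise.drift_sd, size=(k, n_vox))
            Y += comp @ coefs

    # physiological pulsatility, exactly in the span of the RETROICOR basis
    if physio_sim is not None and truth.physio.pulsatility_sd > 0:
        vt = tvol + tr / 2.0
        phases = phys.PhaseSeries(
            volume_times=vt,
            cardiac_phase=phys.cardiac_phase_at(physio_sim.r_peak_times, vt),
            respiratory_phase=phys.respiratory_phase_at(
                physio_sim.trace, np.clip(vt, 0, physio_sim.trace.duration)
            ),
        )
        basis = phys.retroicor_matrix(phases, order=5).to_numpy()
        coefs = rng.normal(0.0, truth.physio.pulsatility_sd, size=(basis.shape[1], n_vox))
        Y += basis @ coefs

    # AR(1) noise at the requested stationary SD
    if truth.noise.sd > 0:
        rho = truth.noise.rho
        innov_sd = truth.noise.sd * np.sqrt(1.0 - rho**2)
        noise = np.empty((n_volumes, n_vox))
        noise[0] = rng.normal(0.0, truth.noise.sd, size=n_vox)
        eps = rng.normal(0.0, innov_sd, size=(n_volumes - 1, n_vox))
        for i in range(1, n_volumes):
            noise[i] = rho * noise[i - 1] + eps[i - 1]
        Y += noise

    return Y.T.reshape(shape + (n_volumes,))


# ---------------------------------------------------------------------------
# diffusion-tensor phantoms


@dataclass
class BundleCurve:
    """A tubular fiber bundle: dense polyline (world mm) plus radius."""

    points: np.ndarray
    radius_mm: float
    fa: float | None = None  # per-bundle FA override

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or self.points.shape[0] < 2:
            raise ValueError("curve needs >= 2 3-D points")


def line_curve(start, end, radius_mm: float, step_mm: float = 0.5, fa=None) -> BundleCurve:
    start, end = np.asarray(start, float), np.asarray(end, float)
    n = max(2, int(np.ceil(np.linalg.norm(end - start) / step_mm)) + 1)
    pts = start + np.linspace(0, 1, n)[:, None] * (end - start)
    return BundleCurve(points=pts, radius_mm=radius_mm, fa=fa)


def arc_curve(center, arc_radius_mm, theta0, theta1, radius_mm, plane="xy",
              step_deg: float = 2.0, offset_axis: float = 0.0, fa=None) -> BundleCurve:
    """Circular arc in a coordinate plane at a constant third coordinate.

    *center* gives the two in-plane center coordinates (mm); *offset_axis*
    the constant value of the remaining axis.
    """
    n = max(2, int(np.ceil(abs(np.degrees(theta1 - theta0)) / step_deg)) + 1)
    th = np.linspace(theta0, theta1, n)
    c = np.asarray(center, float)
    u, v = np.cos(th), np.sin(th)
    axes = {"xy": (0, 1, 2), "xz": (0, 2, 1), "yz": (1, 2, 0)}[plane]
    pts = np.empty((n, 3))
    pts[:, axes[0]] = c[0] + arc_radius_mm * u
    pts[:, axes[1]] = c[1] + arc_radius_mm * v
    pts[:, axes[2]] = offset_axis
    return BundleCurve(points=pts, radius_mm=radius_mm, fa=fa)


def _fa_lambda_ratio(fa: float) -> float:
    """lambda2/lambda1 of an axially symmetric tensor with the given FA."""
    if fa == 0:
        return 1.0
    a = 2 * fa**2 - 1
    b, c = 2.0, fa**2 - 1
    if abs(a) < 1e-12:
        x = -c / b
    else:
        disc = np.sqrt(b * b - 4 * a * c)
        roots = [(-b + disc) / (2 * a), (-b - disc) / (2 * a)]
        x = next(r for r in roots if 0 <= r <= 1 + 1e-12)
    return float(np.clip(x, 0.0, 1.0))


def tensor_from_direction(direction, fa: float, trace: float = TENSOR_TRACE) -> np.ndarray:
    """Axially symmetric tensor with principal axis *direction* and given FA."""
    e = np.asarray(direction, float)
    e = e / np.linalg.norm(e)
    x = _fa_lambda_ratio(fa)
    lam1 = trace / (1.0 + 2.0 * x)
    lam2 = x * lam1
    return lam1 * np.outer(e, e) + lam2 * (np.eye(3) - np.outer(e, e))


def simulate_tensor_phantom(
    geometry,
    shape=DEFAULT_SHAPE,
    voxel_mm: float = DEFAULT_VOXEL_MM,
    fa_inside: float = 0.8,
    fa_outside: float = 0.1,
    trace: float = TENSOR_TRACE,
    origin_mm=(0.0, 0.0, 0.0),
):
    """Tensor field and FA map for a set of tubular bundles.

    Voxels whose center lies within a curve's radius get an anisotropic
    tensor along the local tangent at FA *fa_inside* (or the curve's own
    ``fa``); the background is isotropic at FA *fa_outside*.  Overlapping
    bundles resolve last-writer-wins (logged).  Returns ``(tensors, fa,
    affine)`` with tensors shaped (x, y, z, 3, 3).
    """
    if not (0 <= fa_outside < fa_inside <= 1):
        raise ValueError("need 0 <= fa_outside < fa_inside <= 1")
    shape = tuple(shape)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_mm
    affine[:3, 3] = origin_mm
    tensors = np.empty(shape + (3, 3))
    tensors[...] = _isotropic_like(fa_outside, trace)
    fa_map = np.full(shape, float(fa_outside))

    centers = (np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
               .reshape(-1, 3) * voxel_mm + np.asarray(origin_mm, dtype=float))
    claimed = np.zeros(int(np.prod(shape)), dtype=bool)
    for curve in geometry:
        fa_c = curve.fa if curve.fa is not None else fa_inside
        pts = curve.points
        segs = np.diff(pts, axis=0)
        inside_idx, tangents = _nearest_on_polyline(centers, pts, segs, curve.radius_mm)
        overlap = claimed[inside_idx]
        if overlap.any():
            log.warning("bundle overlap: %d voxels rewritten (last writer wins)", overlap.sum())
        for vi, tan in zip(inside_idx, tangents):
            ijk = np.unravel_index(vi, shape)
            tensors[ijk] = tensor_from_direction(tan, fa_c, trace)
            fa_map[ijk] = fa_c
        claimed[inside_idx] = True
    return tensors, fa_map, affine


def _isotropic_like(fa: float, trace: float) -> np.ndarray:
    # isotropic voxels must carry FA == fa_outside exactly; for fa > 0 the
    # tensor is axially symmetric along +x (an arbitrary, documented axis)
    if fa == 0:
        return (trace / 3.0) * np.eye(3)
    return tensor_from_direction((1.0, 0.0, 0.0), fa, trace)


def _nearest_on_polyline(centers, pts, segs, radius):
    """Voxel indices within *radius* of the polyline and local tangents."""
    best_d2 = np.full(centers.shape[0], np.inf)
    best_seg = np.zeros(centers.shape[0], dtype=int)
    for k, (p0, d) in enumerate(zip(pts[:-1], segs)):
        L2 = d @ d
        if L2 == 0:
            continue
        tpar = np.clip(((centers - p0) @ d) / L2, 0.0, 1.0)
        diff = centers - (p0 + tpar[:, None] * d)
        d2 = np.einsum("ij,ij->i", diff, diff)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_seg[closer] = k
    inside = np.flatnonzero(best_d2 <= radius**2)
    tangents = segs[best_seg[inside]]
    tangents = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    return inside, tangents


def set_region_fa(tensors: np.ndarray, fa_map: np.ndarray, mask: np.ndarray,
                  fa: float, trace: float = TENSOR_TRACE) -> None:
    """Rescale tensors inside *mask* to a new FA, keeping principal axes.

    Used to emulate gray-matter targets (e.g. striatal nuclei) where
    diffusion anisotropy drops but the local orientation is preserved.
    """
    for ijk in zip(*np.nonzero(mask)):
        w, v = np.linalg.eigh(tensors[ijk])
        tensors[ijk] = tensor_from_direction(v[:, np.argmax(w)], fa, trace)
        fa_map[ijk] = fa
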