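"""RETROICOR nuisance regressors from ECG and respiratory-belt traces.

Cardiac phase is linear between successive R peaks; respiratory phase uses
the histogram-equalized amplitude transfer, signed by the derivative of the
belt signal.  Low-order Fourier expansions (default order 5) of both phases
give the nuisance regressors added to every first-level GLM: cos/sin of
m*phase for m = 1..order and both modalities, i.e. 20 columns at order 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "PhysioTrace", "PhaseSeries", "detect_r_peaks", "cardiac_phase_at",
    "respiratory_phase_at", "retroicor_matrix", "phases_for_run",
]

PHYSIO_RATE_HZ = 500.0


@dataclass
class PhysioTrace:
    """Two-channel physiological recording sampled at 500 Hz."""

    ecg: np.ndarray
    respiration: np.ndarray
    sampling_rate: float = PHYSIO_RATE_HZ

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.respiration = np.asarray(self.respiration, dtype=float)
        if self.ecg.shape != self.respiration.shape or self.ecg.ndim != 1:
            raise ValueError("ecg and respiration must be equal-length 1-D arrays")
        if not (np.isfinite(self.ecg).all() and np.isfinite(self.respiration).all()):
            raise ValueError("physio channels must be finite")

    @property
    def duration(self) -> float:
        return self.ecg.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.ecg.size) / self.sampling_rate

    def to_log(self, path) -> None:
        """Two-column plain-text log (ecg, respiration), one row per sample."""
        np.savetxt(path, np.column_stack([self.ecg, self.respiration]), fmt="%.6f")

    @classmethod
    def from_log(cls, path, sampling_rate: float = PHYSIO_RATE_HZ) -> "PhysioTrace":
        a = np.loadtxt(path)
        return cls(ecg=a[:, 0], respiration=a[:, 1], sampling_rate=sampling_rate)


@dataclass
class PhaseSeries:
    """Cardiac and respiratory phase sampled once per fMRI volume."""

    volume_times: np.ndarray
    cardiac_phase: np.ndarray
    respiratory_phase: np.ndarray

    def __post_init__(self) -> None:
        for ph in (self.cardiac_phase, self.respiratory_phase):
            if ph.shape != self.volume_times.shape:
                raise ValueError("one phase pair per volume required")
            if np.any((ph < 0) | (ph >= 2 * np.pi)):
                raise ValueError("phases must be wrapped to [0, 2pi)")


def detect_r_peaks(
    trace: PhysioTrace,
    threshold_frac: float = 0.5,
    refractory_s: float = 0.25,
) -> np.ndarray:
    """R-peak times (s) via an amplitude threshold with a refractory window.

    The threshold sits at *threshold_frac* of the maximum excursion above
    the median, and peaks closer than *refractory_s* are suppressed
    (keeping the larger).  Sufficient for spike-like synthetic ECG.
    """
    x = trace.ecg - np.median(trace.ecg)
    if np.ptp(x) == 0:
        raise ValueError("flat ECG trace: no R peaks")
    height = threshold_frac * x.max()
    distance = max(1, int(round(refractory_s * trace.sampling_rate)))
    idx, _ = signal.find_peaks(x, height=height, distance=distance)
    if idx.size < 2:
        raise ValueError(f"found {idx.size} R peaks; need >= 2 to define phase")
    return idx / trace.sampling_rate


def cardiac_phase_at(peak_times: np.ndarray, t) -> np.ndarray:
    """Linear cardiac phase: 2*pi*(t - t_prev) / (t_next - t_prev).

    Times outside [first, last] peak are assigned the phase of the nearest
    beat interval extrapolated linearly (with a warning), then wrapped.
    """
    peaks = np.asarray(peak_times, dtype=float)
    if peaks.size < 2 or np.any(np.diff(peaks) <= 0):
        raise ValueError("need >= 2 strictly increasing peak times")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < peaks[0]) or np.any(t > peaks[-1]):
        warnings.warn("times outside the R-peak range: extrapolating phase from nearest interval")
    # interval index of each t, clipped to the outermost intervals
    k = np.clip(np.searchsorted(peaks, t, side="right") - 1, 0, peaks.size - 2)
    frac = (t - peaks[k]) / (peaks[k + 1] - peaks[k])
    return np.mod(2 * np.pi * frac, 2 * np.pi)


def respiratory_phase_at(
    trace: PhysioTrace,
    t,
    n_bins: int = 100,
    smooth_s: float = 0.2,
) -> np.ndarray:
    """Histogram-equalized respiratory phase, signed by the belt derivative.

    phi(t) = pi * H(R(t)) * sign(dR/dt), where H is the cumulative
    amplitude histogram (n_bins bins over the observed range), wrapped to
    [0, 2pi).  At the amplitude maximum on an inhale the phase approaches
    pi; the exhale half-cycle maps to (pi, 2pi).
    """
    r = trace.respiration
    if np.ptp(r) == 0:
        raise ValueError("constant respiration channel: phase undefined")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0) or np.any(t > trace.duration):
        raise ValueError("requested times not covered by the trace")
    # light smoothing stabilizes the derivative sign against sample noise
    r_s = gaussian_filter1d(r, sigma=max(1.0, smooth_s * trace.sampling_rate))
    hist, edges = np.histogram(r, bins=n_bins)
    cum = np.concatenate([[0.0], np.cumsum(hist)]) / r.size
    amp = np.interp(t, trace.times, r)
    h = np.interp(amp, edges, cum)
    drdt = np.interp(t, trace.times, np.gradient(r_s) * trace.sampling_rate)
    sign = np.where(drdt >= 0, 1.0, -1.0)
    return np.mod(np.pi * h * sign, 2 * np.pi)


def phases_for_run(
    trace: PhysioTrace,
    n_volumes: int,
    tr: float,
    sample_offset: float | None = None,
) -> PhaseSeries:
    """Phase pair per volume, sampled at mid-volume by default.

    The middle-slice convention (volume onset + TR/2) matches slice-time
    correction to the middle slice; override with *sample_offset*.
    """
    if sample_offset is None:
        sample_offset = tr / 2.0
    vt = np.arange(n_volumes) * tr + sample_offset
    peaks = detect_r_peaks(trace)
    return PhaseSeries(
        volume_times=vt,
        cardiac_phase=cardiac_phase_at(peaks, vt),
        respiratory_phase=respiratory_phase_at(trace, np.clip(vt, 0, trace.duration)),
    )


def retroicor_matrix(phases: PhaseSeries, order: int = 5) -> pd.DataFrame:
    """Fourier-expansion nuisance matrix, 4*order columns.

    Column order: for m = 1..order, (cardiac_cos_m, cardiac_sin_m,
    resp_cos_m, resp_sin_m).  Order 5 gives the standard 20 columns.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    cols: dict[str, np.ndarray] = {}
    for m in range(1, order + 1):
        cols[f"cardiac_cos_{m}"] = np.cos(m * phases.cardiac_phase)
        cols[f"cardiac_sin_{m}"] = np.sin(m * phases.cardiac_phase)
        cols[f"resp_cos_{m}"] = np.cos(m * phases.respiratory_phase)
        cols[f"resp_sin_{m}"] = np.sin(m * phases.respiratory_phase)
    return pd.DataFrame(cols, index=np.arange(phases.volume_times.size))
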