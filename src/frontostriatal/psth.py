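"""FIR peri-stimulus time courses ("selective averaging") and ROI statistics.

A finite-impulse-response design models each condition's response in 0.5 s
bins over a 12 s window aligned at peripheral-target onset, correcting for
overlap between the closely spaced trials.  Its regression coefficients
form the PSTH, expressed in percent of the voxel's run mean.  ROI
statistics follow: a paired test of anti vs pro amplitude at the peak
sample, and a lateralization test contrasting the leftward-rightward
antisaccade difference between the left and right ROI of a pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .designs import AMPLITUDES, EventSchedule, SIDES, TASKS
from .glm import dct_highpass_basis

__all__ = [
    "PSTH_CONDITIONS", "PSTHSet", "fir_design", "estimate_psth",
    "group_psth", "peak_anti_vs_pro_test", "lateralization_test",
]

#: The four pooled conditions: task x saccade direction (amplitudes pooled).
PSTH_CONDITIONS = [f"{t}_{s}" for t in TASKS for s in SIDES]


def _condition_onsets(schedule: EventSchedule, condition: str) -> np.ndarray:
    task, side = condition.split("_")
    labels = [f"target_{side}_{a}_{task}" for a in AMPLITUDES]
    return np.sort(schedule.onsets(labels))


@dataclass
class FIRDesign:
    """FIR indicator matrix with its bin bookkeeping."""

    matrix: np.ndarray           # (n_volumes, n_cond*n_bins + n_nuisance)
    conditions: list
    n_bins: int
    bin_s: float
    window_s: float
    tr: float
    n_nuisance: int              # trailing high-pass + baseline columns

    @property
    def bin_times(self) -> np.ndarray:
        """Window-relative bin centers (s)."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_s

    def column(self, condition: str, b: int) -> int:
        return self.conditions.index(condition) * self.n_bins + b


@dataclass
class PSTHSet:
    """Per-participant, per-ROI condition time courses (% signal change).

    ``values[participant][roi]`` is a (n_conditions, n_bins) array; bins a
    participant's sampling never visited are NaN.
    """

    values: list              # list over participants of {roi: array}
    conditions: list
    bin_times: np.ndarray
    bin_s: float
    window_s: float

    @property
    def n_participants(self) -> int:
        return len(self.values)

    def roi_matrix(self, roi: str) -> np.ndarray:
        """(n_participants, n_conditions, n_bins) stack for one ROI."""
        return np.stack([p[roi] for p in self.values])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pidx, per_roi in enumerate(self.values):
            for roi, arr in per_roi.items():
                for ci, cond in enumerate(self.conditions):
                    for b, t in enumerate(self.bin_times):
                        rows.append({"participant": pidx, "roi": roi, "condition": cond,
                                     "bin_time_s": t, "value": arr[ci, b]})
        return pd.DataFrame(rows)


def fir_design(
    schedule: EventSchedule,
    n_volumes: int,
    tr: float,
    conditions=PSTH_CONDITIONS,
    window_s: float = 12.0,
    bin_s: float = 0.5,
    hp_cutoff_s: float = 128.0,
) -> FIRDesign:
    """Indicator FIR design sampled at volume times, plus high-pass columns.

    For each condition and bin j, the regressor counts events whose onset o
    satisfies o + j*bin <= t < o + (j+1)*bin at volume time t.  High-pass
    discrete-cosine columns (cutoff 128 s) and a baseline are appended.
    """
    ratio = window_s / bin_s
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("window must be an integer multiple of the bin size")
    n_bins = int(round(ratio))
    tvol = np.arange(n_volumes) * tr
    cols = []
    for cond in conditions:
        onsets = _condition_onsets(schedule, cond)
        onsets = onsets[(onsets >= 0) & (onsets < n_volumes * tr)]
        block = np.zeros((n_volumes, n_bins))
        if onsets.size == 0:
            warnings.warn(f"condition {cond!r} has no events: zero FIR columns")
        for o in onsets:
            rel = tvol - o
            sel = (rel >= 0) & (rel < window_s)
            b = np.floor(rel[sel] / bin_s).astype(int)
            block[np.flatnonzero(sel), b] += 1.0
        cols.append(block)
    hp = dct_highpass_basis(n_volumes, tr, hp_cutoff_s)
    nuisance = np.column_stack([hp, np.ones(n_volumes)]) if hp.size else np.ones((n_volumes, 1))
    M = np.column_stack(cols + [nuisance])
    return FIRDesign(matrix=M, conditions=list(conditions), n_bins=n_bins, bin_s=bin_s,
                     window_s=window_s, tr=tr, n_nuisance=nuisance.shape[1])


def estimate_psth(Y: np.ndarray, design: FIRDesign, scale_percent: bool = True) -> np.ndarray:
    """FIR coefficients per voxel, (n_conditions, n_bins, n_voxels).

    Fit by least squares on the estimable subspace: bins never sampled
    (all-zero columns) come back NaN.  With *scale_percent* the
    coefficients are expressed in percent of each voxel's run mean.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != design.matrix.shape[0]:
        raise ValueError("Y rows must match the FIR design")
    M = design.matrix
    n_fir = len(design.conditions) * design.n_bins
    sampled = np.any(M[:, :n_fir] != 0, axis=0)
    # bins whose sampling pattern is linearly dependent on other columns
    # (possible when overlapping windows share their only sampled volumes)
    # are unestimable: select an independent subset incrementally, with
    # the nuisance columns always retained, and report dropped bins NaN
    keep = np.concatenate([sampled, np.ones(design.n_nuisance, dtype=bool)])
    order = np.concatenate([np.arange(n_fir, M.shape[1]),  # nuisance first
                            np.flatnonzero(sampled)])
    Q = np.zeros((M.shape[0], 0))
    for j in order:
        col = M[:, j]
        r = col - Q @ (Q.T @ col)
        r = r - Q @ (Q.T @ r)  # re-orthogonalize for numerical stability
        if np.linalg.norm(r) > 1e-8 * max(np.linalg.norm(col), 1e-30):
            Q = np.column_stack([Q, r / np.linalg.norm(r)])
        elif j < n_fir:
            keep[j] = False
            warnings.warn("unestimable FIR bin dropped (aliased sampling)")
        else:
            raise ValueError("nuisance columns are collinear")
    Mk = M[:, keep]
    if np.linalg.matrix_rank(Mk) < Mk.shape[1]:
        raise ValueError("FIR design is rank deficient on its sampled bins; "
                         "event spacing leaves bins collinear")
    beta_k, *_ = np.linalg.lstsq(Mk, Y, rcond=None)
    beta = np.full((M.shape[1], Y.shape[1]), np.nan)
    beta[keep] = beta_k
    fir = beta[:n_fir].reshape(len(design.conditions), design.n_bins, Y.shape[1])
    if scale_percent:
        mean = Y.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            fir = 100.0 * fir / mean
    return fir


def group_psth(
    runs: list,
    roi_masks: dict,
    design_for_run,
) -> PSTHSet:
    """Per-participant ROI-average PSTHs from raw runs.

    *runs* is a list of (Y, schedule) pairs, one per participant, with Y of
    shape (n_volumes, n_voxels) over the flattened grid; *roi_masks* maps
    label -> boolean grid mask; *design_for_run* builds the FIRDesign from
    a schedule.
    """
    values = []
    design0 = None
    for Y, schedule in runs:
        design = design_for_run(schedule)
        design0 = design0 or design
        per_roi = {}
        for label, mask in roi_masks.items():
            idx = np.flatnonzero(np.asarray(mask, dtype=bool).ravel())
            fir = estimate_psth(Y[:, idx], design)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                per_roi[label] = np.nanmean(fir, axis=2)
        values.append(per_roi)
    return PSTHSet(values=values, conditions=design0.conditions,
                   bin_times=design0.bin_times, bin_s=design0.bin_s,
                   window_s=design0.window_s)


def _nearest_bin(psth: PSTHSet, time_s: float) -> int:
    if not 0 <= time_s <= psth.window_s:
        raise ValueError("timepoint outside the FIR window")
    return int(np.clip(np.floor(time_s / psth.bin_s), 0, len(psth.bin_times) - 1))


def _condition_rows(psth: PSTHSet, task: str) -> list:
    return [i for i, c in enumerate(psth.conditions) if c.startswith(task + "_")]


def peak_anti_vs_pro_test(psth: PSTHSet, roi: str, peak_bin: int | None = None):
    """Paired t-test of anti - pro amplitude at the PSTH peak sample.

    Directions (and amplitudes, already pooled) are averaged per
    participant.  The peak bin is located on the grand-mean curve over all
    conditions and participants unless given.  Returns (t, p, peak_bin);
    p is one-sided for anti > pro.
    """
    if psth.n_participants < 2:
        raise ValueError("need >= 2 participants")
    stack = psth.roi_matrix(roi)  # (n_part, n_cond, n_bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        anti = np.nanmean(stack[:, _condition_rows(psth, "anti"), :], axis=1)
        pro = np.nanmean(stack[:, _condition_rows(psth, "pro"), :], axis=1)
        if peak_bin is None:
            grand = np.nanmean(np.nanmean(stack, axis=1), axis=0)
            peak_bin = int(np.nanargmax(grand))
    diff = anti[:, peak_bin] - pro[:, peak_bin]
    diff = diff[np.isfinite(diff)]
    if diff.size < 2:
        raise ValueError("fewer than 2 participants with a defined peak sample")
    if np.all(diff == diff[0]):  # zero variance: identical values give t = 0
        t = 0.0 if diff[0] == 0 else np.inf * np.sign(diff[0])
        p_one = 0.5 if diff[0] == 0 else (0.0 if diff[0] > 0 else 1.0)
        return float(t), float(p_one), peak_bin
    t, p_two = stats.ttest_1samp(diff, 0.0)
    p_one = p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0
    return float(t), float(p_one), peak_bin


def lateralization_test(
    psth: PSTHSet,
    roi_left: str,
    roi_right: str,
    timepoints_s=(3.15, 5.25),
    variant: str = "paired",
):
    """Ipsilateral-antisaccade lateralization between an ROI pair.

    Per participant the leftward-minus-rightward antisaccade amplitude
    difference is computed in each ROI; the left-ROI difference is tested
    against the right-ROI difference at each timepoint (nearest FIR bin).
    Positive t means ipsilateral preference.  ``variant`` selects the
    paired test (default; participants are shared between ROIs) or the
    two-sample test.  Returns {timepoint: (t, p_two_sided)}.
    """
    if variant not in ("paired", "two_sample"):
        raise ValueError("variant must be 'paired' or 'two_sample'")
    iL = psth.conditions.index("anti_L")
    iR = psth.conditions.index("anti_R")
    left = psth.roi_matrix(roi_left)
    right = psth.roi_matrix(roi_right)
    out = {}
    for tp in timepoints_s:
        b = _nearest_bin(psth, tp)
        dL = left[:, iL, b] - left[:, iR, b]
        dR = right[:, iL, b] - right[:, iR, b]
        ok = np.isfinite(dL) & np.isfinite(dR)
        if ok.sum() < 2:
            raise ValueError("fewer than 2 participants with data at the timepoint")
        if np.all(dL[ok] == dR[ok]):  # identical ROIs: no lateralization
            out[tp] = (0.0, 1.0)
            continue
        if variant == "paired":
            t, p = stats.ttest_rel(dL[ok], dR[ok])
        else:
            t, p = stats.ttest_ind(dL[ok], dR[ok])
        out[tp] = (float(t), float(p))
    return out
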