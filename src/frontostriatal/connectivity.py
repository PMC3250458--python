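"""Fiber selection, prolongation, cutting, probability maps, connectograms.

The cortico-striatal connectivity procedure operates on brute-force FACT
bundles: striatal region masks (dilated 2 mm) select fibers that both pass
through the mask and have FA below 0.3 at the intersection (a proxy for
terminating in gray matter rather than skimming past); selected fibers are
prolonged 3 steps of 2 mm at both ends along the running mean of the last
4 segment vectors (fibers stop short of gray matter as FA drops), cut at
the midsagittal plane, rasterized into per-participant binary maps that
are dilated, smoothed and averaged into a group probability map, and
finally counted against dilated cortical activation clusters: a
participant is "connected" for a (cortical, striatal) pair when at least
one fiber links them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .glm import smooth_fwhm
from .tracking import Streamline, StreamlineBundle

__all__ = [
    "ROIMask", "Connectogram", "spherical_structure", "dilate_mask",
    "select_fibers", "prolong_fiber", "prolong_bundle", "cut_midsagittal",
    "cut_bundle_midsagittal", "bundle_probability_map", "connectogram",
]

log = logging.getLogger(__name__)


@dataclass
class ROIMask:
    """Binary region mask on a voxel grid with its world affine."""

    data: np.ndarray
    affine: np.ndarray
    label: str
    dilation_mm: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if not self.data.any():
            raise ValueError(f"ROI {self.label!r} is empty")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class Connectogram:
    """Participant counts of (cortical x striatal) structural connections."""

    counts: pd.DataFrame  # index: cortical labels, columns: striatal labels
    n_participants: int

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or np.any(vals > self.n_participants):
            raise ValueError("counts must lie in [0, n_participants]")

    def to_tsv(self, path) -> None:
        long = self.counts.stack().rename("n_connected").reset_index()
        long.columns = ["cortical_label", "striatal_label", "n_connected"]
        long["n_total"] = self.n_participants
        long.to_csv(path, sep="\t", index=False)


def spherical_structure(radius_mm: float, voxel_size_mm) -> np.ndarray:
    """Spherical structuring element in world mm on an anisotropic grid."""
    vs = np.broadcast_to(np.atleast_1d(voxel_size_mm).astype(float), (3,))
    r_vox = np.floor(radius_mm / vs).astype(int)
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in r_vox], indexing="ij")
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, vs))
    return dist2 <= radius_mm**2 + 1e-9


def dilate_mask(mask: ROIMask, radius_mm: float) -> ROIMask:
    """Morphological dilation with a spherical element of *radius_mm*."""
    if radius_mm < 0:
        raise ValueError("dilation radius must be >= 0")
    if radius_mm == 0:
        return ROIMask(mask.data.copy(), mask.affine, mask.label, mask.dilation_mm)
    struct = spherical_structure(radius_mm, mask.voxel_size_mm)
    out = ndimage.binary_dilation(mask.data, structure=struct)
    return ROIMask(out, mask.affine, mask.label, mask.dilation_mm + radius_mm)


def _points_to_voxels(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    return np.floor(vox + 0.5).astype(int)  # voxel centers at integer indices


def _in_mask_flags(points: np.ndarray, mask_data: np.ndarray, affine: np.ndarray) -> np.ndarray:
    vox = _points_to_voxels(points, affine)
    inside = np.all((vox >= 0) & (vox < mask_data.shape), axis=1)
    flags = np.zeros(len(points), dtype=bool)
    if inside.any():
        v = vox[inside]
        flags[inside] = mask_data[v[:, 0], v[:, 1], v[:, 2]]
    return flags


def select_fibers(
    bundle: StreamlineBundle,
    roi: ROIMask,
    fa: np.ndarray,
    fa_max: float = 0.3,
    rule: str = "any",
) -> StreamlineBundle:
    """Keep fibers that intersect *roi* with FA below *fa_max* there.

    A fiber qualifies when at least one of its points falls in an ROI voxel
    whose FA is < *fa_max* (``rule="any"``, default) or when the *first*
    ROI-intersecting point satisfies the FA criterion (``rule="first"``).
    FA is looked up at the voxel containing the point (nearest voxel, no
    interpolation).
    """
    if rule not in ("any", "first"):
        raise ValueError("rule must be 'any' or 'first'")
    kept = []
    for s in bundle:
        in_roi = _in_mask_flags(s.points, roi.data, roi.affine)
        if not in_roi.any():
            continue
        vox = _points_to_voxels(s.points, roi.affine)
        inside = np.all((vox >= 0) & (vox < fa.shape), axis=1)
        fa_pts = np.full(len(s.points), np.inf)
        v = vox[inside]
        fa_pts[inside] = fa[v[:, 0], v[:, 1], v[:, 2]]
        if rule == "any":
            ok = bool(np.any(in_roi & (fa_pts < fa_max)))
        else:
            first = int(np.argmax(in_roi))
            ok = bool(fa_pts[first] < fa_max)
        if ok:
            kept.append(s)
    return StreamlineBundle(streamlines=kept, affine=bundle.affine,
                            participant=bundle.participant)


def prolong_fiber(
    fiber: Streamline,
    n_steps: int = 3,
    step_mm: float = 2.0,
    lookback: int = 4,
) -> Streamline:
    """Extend both fiber ends by *n_steps* steps of *step_mm* each.

    Each step continues along the normalized mean of the *lookback* most
    recent segment vectors (updated as new points are appended), yielding a
    smooth 6 mm prolongation per end at the defaults.  Fibers with fewer
    than ``lookback + 1`` points are returned unchanged (flagged).
    """
    pts = fiber.points
    if len(pts) < lookback + 1:
        warnings.warn("fiber too short to prolong (needs >= %d points)" % (lookback + 1))
        return fiber

    def extend(p: np.ndarray) -> np.ndarray:
        p = list(p)
        for _ in range(n_steps):
            segs = np.diff(np.asarray(p[-(lookback + 1):]), axis=0)
            mean = segs.mean(axis=0)
            norm = np.linalg.norm(mean)
            if norm < 1e-12:
                break
            p.append(p[-1] + step_mm * mean / norm)
        return np.asarray(p)

    head = extend(pts[::-1])[::-1]  # prolong the start end
    full = extend(head)             # then the finish end
    return Streamline(points=full, seed_voxel=fiber.seed_voxel, termination=fiber.termination)


def prolong_bundle(bundle: StreamlineBundle, **kw) -> StreamlineBundle:
    return StreamlineBundle(
        streamlines=[prolong_fiber(s, **kw) for s in bundle],
        affine=bundle.affine, participant=bundle.participant,
    )


def cut_midsagittal(fiber: Streamline, side: int, plane_x_mm: float = 0.0) -> Streamline | None:
    """Cut a fiber at the midsagittal plane x = *plane_x_mm*.

    *side* is +1 (right) or -1 (left): the hemisphere of the originating
    mask.  Points are kept up to the first crossing into the far
    hemisphere; an interpolated point exactly on the plane is appended.  A
    fiber starting contralaterally yields ``None`` (flagged).
    """
    if side not in (-1, 1):
        raise ValueError("side must be +1 or -1")
    x = side * (fiber.points[:, 0] - plane_x_mm)
    if x[0] < 0:
        warnings.warn("fiber starts in the contralateral hemisphere: cut to empty")
        return None
    crossing = np.flatnonzero(x < 0)
    if crossing.size == 0:
        return fiber
    k = int(crossing[0])  # first point past the plane; k >= 1
    frac = x[k - 1] / (x[k - 1] - x[k])
    on_plane = fiber.points[k - 1] + frac * (fiber.points[k] - fiber.points[k - 1])
    pts = np.vstack([fiber.points[:k], on_plane])
    return Streamline(points=pts, seed_voxel=fiber.seed_voxel, termination=fiber.termination)


def cut_bundle_midsagittal(bundle: StreamlineBundle, side: int,
                           plane_x_mm: float = 0.0) -> StreamlineBundle:
    kept = []
    for s in bundle:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cut = cut_midsagittal(s, side, plane_x_mm)
        if cut is not None and len(cut.points) >= 2:
            kept.append(cut)
    return StreamlineBundle(streamlines=kept, affine=bundle.affine,
                            participant=bundle.participant)


def _rasterize(bundle: StreamlineBundle, shape, affine, step_mm: float | None = None) -> np.ndarray:
    """Binary map of voxels traversed by >= 1 fiber (segments densified)."""
    out = np.zeros(shape, dtype=bool)
    vs = float(np.min(np.linalg.norm(affine[:3, :3], axis=0)))
    step = step_mm if step_mm is not None else vs / 2.0
    for s in bundle:
        pts = s.points
        segs = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        dense = [pts[:1]]
        for i, L in enumerate(segs):
            n = max(1, int(np.ceil(L / step)))
            frac = np.linspace(0, 1, n + 1)[1:, None]
            dense.append(pts[i] + frac * (pts[i + 1] - pts[i]))
        vox = _points_to_voxels(np.vstack(dense), affine)
        inside = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
        v = vox[inside]
        out[v[:, 0], v[:, 1], v[:, 2]] = True
    return out


def bundle_probability_map(
    bundles: list[StreamlineBundle],
    shape,
    affine,
    dilate_vox: int = 3,
    smooth_fwhm_mm: float = 4.0,
) -> np.ndarray:
    """Group probability map of bundle occupancy.

    Per participant: binary traversal map, dilated by *dilate_vox* voxels
    (face-connected iterations), Gaussian-smoothed at *smooth_fwhm_mm*;
    then averaged voxel-wise over participants.  Values stay in [0, 1].
    """
    if not bundles:
        raise ValueError("need at least one participant bundle")
    vs = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
    acc = np.zeros(shape, dtype=float)
    for b in bundles:
        m = _rasterize(b, shape, affine).astype(float)
        if dilate_vox > 0:
            m = ndimage.binary_dilation(m > 0, iterations=dilate_vox).astype(float)
        if smooth_fwhm_mm > 0:
            m = smooth_fwhm(m, vs, smooth_fwhm_mm)
        acc += m
    return acc / len(bundles)


def connectogram(
    cortical_clusters: list[dict],
    striatal_bundles: list[dict],
) -> Connectogram:
    """Count participants with >= 1 fiber linking each (cortical, striatal) pair.

    *cortical_clusters*: per participant, label -> ROIMask (already dilated
    4 mm); *striatal_bundles*: per participant, label -> StreamlineBundle
    (already selected, prolonged and cut).  A participant missing a
    cortical cluster counts as not connected for that row (logged).
    """
    if len(cortical_clusters) != len(striatal_bundles):
        raise ValueError("one cluster dict and one bundle dict per participant")
    cort_labels = sorted({lab for d in cortical_clusters for lab in d})
    stri_labels = sorted({lab for d in striatal_bundles for lab in d})
    counts = pd.DataFrame(0, index=cort_labels, columns=stri_labels, dtype=int)
    for pidx, (clusters, bundles) in enumerate(zip(cortical_clusters, striatal_bundles)):
        for c_lab in cort_labels:
            roi = clusters.get(c_lab)
            if roi is None:
                log.info("participant %d missing cortical cluster %r: not connected", pidx, c_lab)
                continue
            for s_lab in stri_labels:
                bundle = bundles.get(s_lab)
                if bundle is None or len(bundle) == 0:
                    continue
                hit = any(_in_mask_flags(f.points, roi.data, roi.affine).any() for f in bundle)
                counts.loc[c_lab, s_lab] += int(hit)
    return Connectogram(counts=counts, n_participants=len(cortical_clusters))
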