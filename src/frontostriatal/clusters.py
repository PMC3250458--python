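"""Cluster-extent inference for group t-maps.

Supra-threshold voxels at a cluster-defining p < 0.001 (uncorrected) are
grouped into connected components; significance requires a minimum extent
k_min calibrated by Monte-Carlo simulation of smooth Gaussian null fields
so that the familywise rate of any supra-extent cluster is at most alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .glm import smooth_fwhm

__all__ = ["Cluster", "ClusterSet", "label_clusters", "monte_carlo_extent",
           "simulate_null_tfield"]


def simulate_null_tfield(rng, grid_shape, df, smoothness_fwhm_mm, voxel_size_mm=2.0):
    """One-sample t-field of df + 1 smoothed Gaussian noise images.

    The t statistic is scale-invariant, so no variance normalization of
    the smoothed per-subject fields is needed.
    """
    n = int(df) + 1
    subj = rng.standard_normal((n,) + tuple(grid_shape))
    if smoothness_fwhm_mm > 0:
        for k in range(n):
            subj[k] = smooth_fwhm(subj[k], voxel_size_mm, smoothness_fwhm_mm)
    mean = subj.mean(axis=0)
    sd = subj.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.nan_to_num(t, nan=0.0)


def _structure(connectivity: int) -> np.ndarray:
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, rank)


@dataclass
class Cluster:
    voxels: np.ndarray          # (n, 3) integer indices
    peak_t: float
    peak_world_mm: np.ndarray
    size: int


@dataclass
class ClusterSet:
    clusters: list = field(default_factory=list)
    cluster_defining_p: float = 0.001
    extent_threshold_k: int = 1
    alpha: float = 0.05
    t_threshold: float = float("nan")

    def significant(self) -> list:
        return [c for c in self.clusters if c.size >= self.extent_threshold_k]

    def table(self) -> pd.DataFrame:
        """Cluster table: peak coordinates (mm), T_max and extent."""
        rows = [
            {"peak_x_mm": c.peak_world_mm[0], "peak_y_mm": c.peak_world_mm[1],
             "peak_z_mm": c.peak_world_mm[2], "T_max": c.peak_t, "n_voxels": c.size}
            for c in sorted(self.significant(), key=lambda c: -c.peak_t)
        ]
        return pd.DataFrame(rows, columns=["peak_x_mm", "peak_y_mm", "peak_z_mm",
                                           "T_max", "n_voxels"])


def label_clusters(
    t_map: np.ndarray,
    df: float,
    affine: np.ndarray,
    p_def: float = 0.001,
    connectivity: int = 18,
    extent_threshold_k: int = 1,
    alpha: float = 0.05,
) -> ClusterSet:
    """Connected supra-threshold clusters of a t-map.

    Voxels with t above the one-sided t(df) quantile of *p_def* are grouped
    with the given connectivity (18 = faces + edges, the default).  NaN
    voxels (e.g. zero-variance) never enter a cluster.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t_crit = float(stats.t.isf(p_def, df))
    supra = np.nan_to_num(t_map, nan=-np.inf) > t_crit
    labels, n = ndimage.label(supra, structure=_structure(connectivity))
    clusters = []
    A, b = np.asarray(affine)[:3, :3], np.asarray(affine)[:3, 3]
    for k in range(1, n + 1):
        vox = np.argwhere(labels == k)
        tvals = t_map[labels == k]
        imax = int(np.argmax(tvals))
        clusters.append(Cluster(
            voxels=vox,
            peak_t=float(tvals[imax]),
            peak_world_mm=vox[imax] @ A.T + b,
            size=int(vox.shape[0]),
        ))
    return ClusterSet(clusters=clusters, cluster_defining_p=p_def,
                      extent_threshold_k=extent_threshold_k, alpha=alpha,
                      t_threshold=t_crit)


def monte_carlo_extent(
    grid_shape,
    smoothness_fwhm_mm: float,
    df: float,
    voxel_size_mm: float = 2.0,
    p_def: float = 0.001,
    alpha: float = 0.05,
    n_iter: int = 1000,
    seed: int = 0,
    connectivity: int = 18,
) -> int:
    """Minimum cluster extent k_min controlling the familywise rate at alpha.

    Each null iteration emulates the group analysis: df + 1 Gaussian white
    noise images smoothed to *smoothness_fwhm_mm* enter a one-sample
    t-field, which is thresholded at the one-sided t(df) quantile of
    *p_def*; k_min is the smallest k for which the fraction of null fields
    whose largest supra-threshold cluster reaches k is at most alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    rng = np.random.default_rng(seed)
    t_crit = float(stats.t.isf(p_def, df))
    struct = _structure(connectivity)
    max_sizes = np.zeros(n_iter, dtype=int)
    for i in range(n_iter):
        field = simulate_null_tfield(rng, grid_shape, df, smoothness_fwhm_mm,
                                     voxel_size_mm)
        labels, n = ndimage.label(field > t_crit, structure=struct)
        if n:
            max_sizes[i] = int(np.max(ndimage.sum_labels(
                np.ones_like(labels), labels, index=np.arange(1, n + 1))))
    # survival function of the max cluster size over null simulations
    for k in range(1, int(max_sizes.max()) + 2):
        if np.mean(max_sizes >= k) <= alpha:
            return k
    return int(max_sizes.max()) + 1
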