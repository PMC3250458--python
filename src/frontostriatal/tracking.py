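"""Deterministic FACT streamline tractography on diffusion-tensor fields.

Fiber assignment by continuous tracking: within each voxel the path
follows that voxel's principal eigenvector in a straight segment to the
voxel boundary, then adopts the next voxel's eigenvector (sign chosen for
continuity).  Brute-force seeding places 8 seeds per supra-FA voxel on a
2x2x2 sub-voxel grid and propagates each bidirectionally.  Termination:
entering a voxel with FA below threshold, a turn sharper than the maximum
angle, a mean angle with neighboring voxels' principal directions above
the neighborhood threshold, or leaving the volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

__all__ = [
    "Streamline", "StreamlineBundle", "fa_from_tensor", "fa_map_from_tensors",
    "principal_directions", "fact_track_all",
]

TERMINATION_REASONS = ("low_FA", "sharp_angle", "neighborhood_angle", "volume_edge", "max_steps")


def fa_from_tensor(tensor: np.ndarray) -> float:
    """Fractional anisotropy of one 3x3 tensor.

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||; a zero tensor
    maps to 0.
    """
    w = np.linalg.eigvalsh(np.asarray(tensor, dtype=float))
    if np.any(w < -1e-12 * max(1.0, np.abs(w).max())):
        raise ValueError("tensor has negative eigenvalues")
    norm = np.sqrt(np.sum(w**2))
    if norm == 0:
        return 0.0
    return float(np.sqrt(1.5) * np.sqrt(np.sum((w - w.mean()) ** 2)) / norm)


def fa_map_from_tensors(tensors: np.ndarray) -> np.ndarray:
    """Voxel-wise FA of a (x, y, z, 3, 3) tensor field."""
    w = np.linalg.eigvalsh(tensors)
    norm = np.sqrt(np.sum(w**2, axis=-1))
    dev = w - w.mean(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.sum(dev**2, axis=-1)) / norm
    return np.where(norm > 0, fa, 0.0)


def principal_directions(tensors: np.ndarray) -> np.ndarray:
    """Unit principal eigenvector per voxel, shape (x, y, z, 3)."""
    w, v = np.linalg.eigh(tensors)
    return v[..., :, -1]  # eigh sorts ascending


@dataclass
class Streamline:
    """Ordered polyline in world mm with its seed and termination record."""

    points: np.ndarray
    seed_voxel: tuple
    termination: tuple  # (reason at start end, reason at finish end)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)

    @property
    def length_mm(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class StreamlineBundle:
    """A set of streamlines from one participant."""

    streamlines: list = field(default_factory=list)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    participant: str | None = None

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def to_jsonl(self, path) -> None:
        """JSON-lines polylines: one fiber per line."""
        with open(path, "w") as fh:
            for s in self.streamlines:
                fh.write(json.dumps({
                    "points": np.round(s.points, 4).tolist(),
                    "seed_voxel": list(map(int, s.seed_voxel)),
                    "termination": list(s.termination),
                }) + "\n")

    @classmethod
    def from_jsonl(cls, path, participant=None) -> "StreamlineBundle":
        sl = []
        with open(path) as fh:
            for line in fh:
                d = json.loads(line)
                sl.append(Streamline(np.asarray(d["points"]), tuple(d["seed_voxel"]),
                                     tuple(d["termination"])))
        return cls(streamlines=sl, participant=participant)

    @classmethod
    def from_trk(cls, path, participant=None) -> "StreamlineBundle":
        """Load a TrackVis file (points in RAS mm); termination unknown."""
        trk = nib.streamlines.load(str(path))
        sl = [Streamline(np.asarray(pts, dtype=float), (-1, -1, -1),
                         ("unknown", "unknown")) for pts in trk.streamlines]
        return cls(streamlines=sl, affine=np.asarray(trk.header["voxel_to_rasmm"]),
                   participant=participant)

    def to_trk(self, path, shape, voxel_mm) -> None:
        """TrackVis file via nibabel (RAS mm coordinates)."""
        tractogram = nib.streamlines.Tractogram(
            [s.points for s in self.streamlines], affine_to_rasmm=np.eye(4)
        )
        hdr = {
            "dimensions": np.asarray(shape, dtype=np.int16),
            "voxel_sizes": np.broadcast_to(np.atleast_1d(voxel_mm), (3,)).astype(np.float32),
            "voxel_to_rasmm": self.affine.astype(np.float32),
            "voxel_order": "RAS",
        }
        nib.streamlines.save(nib.streamlines.TrkFile(tractogram, hdr), str(path))


# eight seeds per voxel: the 2x2x2 sub-grid cell centers (voxel coordinates
# relative to the voxel center at integer index)
_SEED_OFFSETS = np.array(
    [(sx, sy, sz) for sx in (-0.25, 0.25) for sy in (-0.25, 0.25) for sz in (-0.25, 0.25)]
)

_FACE_NEIGHBORS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
)
_ALL_NEIGHBORS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
     if (i, j, k) != (0, 0, 0)]
)


def _voxel_of(p: np.ndarray) -> np.ndarray:
    # voxel centers sit at integer indices; voxel i spans [i-0.5, i+0.5)
    return np.floor(p + 0.5).astype(int)


def _exit_length(p: np.ndarray, d: np.ndarray, vox: np.ndarray) -> float:
    """Distance along *d* from *p* to the boundary of voxel *vox*."""
    t = np.inf
    for ax in range(3):
        if d[ax] > 1e-12:
            t = min(t, (vox[ax] + 0.5 - p[ax]) / d[ax])
        elif d[ax] < -1e-12:
            t = min(t, (vox[ax] - 0.5 - p[ax]) / d[ax])
    return t


class _Tracker:
    def __init__(self, e1, fa, affine, min_fa, max_angle_deg, max_avg_neighbor_angle_deg,
                 neighborhood, max_steps):
        self.e1 = e1
        self.fa = fa
        self.shape = fa.shape
        self.A = affine[:3, :3]
        self.b = affine[:3, 3]
        self.min_fa = min_fa
        self.cos_max = np.cos(np.radians(max_angle_deg))
        self.max_avg = np.radians(max_avg_neighbor_angle_deg)
        self.neigh = _FACE_NEIGHBORS if neighborhood == 6 else _ALL_NEIGHBORS
        self.max_steps = max_steps

    def inside(self, vox) -> bool:
        return bool(np.all(vox >= 0) and np.all(vox < self.shape))

    def neighborhood_ok(self, vox, d) -> bool:
        angles = []
        for off in self.neigh:
            nb = vox + off
            if not self.inside(nb):
                continue
            e = self.e1[tuple(nb)]
            # orientation-invariant angle between the running direction and
            # the neighbor's principal axis (a line, not a vector)
            angles.append(np.arccos(min(1.0, abs(float(d @ e)))))
        if not angles:
            return True
        return np.mean(angles) <= self.max_avg + 1e-12

    def propagate(self, p0: np.ndarray, d0: np.ndarray):
        """March from p0 along d0 (voxel coords); return (points, reason)."""
        pts = [p0.copy()]
        vox = _voxel_of(p0)
        d = d0.copy()
        for _ in range(self.max_steps):
            t = _exit_length(pts[-1], d, vox)
            if not np.isfinite(t):
                return pts, "max_steps"
            p_new = pts[-1] + (t + 1e-6) * d
            pts.append(pts[-1] + t * d)
            new_vox = _voxel_of(p_new)
            if not self.inside(new_vox):
                return pts, "volume_edge"
            if self.fa[tuple(new_vox)] < self.min_fa:
                return pts, "low_FA"
            e = self.e1[tuple(new_vox)]
            d_new = e if (d @ e) >= 0 else -e
            if (d @ d_new) < self.cos_max - 1e-12:
                return pts, "sharp_angle"
            if not self.neighborhood_ok(new_vox, d_new):
                return pts, "neighborhood_angle"
            vox = new_vox
            d = d_new
        return pts, "max_steps"

    def to_world(self, pts_vox: np.ndarray) -> np.ndarray:
        return pts_vox @ self.A.T + self.b


def fact_track_all(
    tensors: np.ndarray | None,
    fa: np.ndarray,
    affine: np.ndarray,
    seeds_per_voxel: int = 8,
    min_fa: float = 0.2,
    max_angle_deg: float = 53.0,
    max_avg_neighbor_angle_deg: float = 90.0,
    neighborhood: int = 6,
    max_steps: int = 2000,
    e1: np.ndarray | None = None,
    participant: str | None = None,
) -> StreamlineBundle:
    """Brute-force FACT tracking from every voxel with FA >= *min_fa*.

    Either the tensor field or a precomputed principal-direction field
    *e1* must be given.  Only ``seeds_per_voxel == 8`` (the fixed 2x2x2
    sub-voxel grid) is supported; the tracker is fully deterministic.
    """
    if seeds_per_voxel != 8:
        raise ValueError("only the fixed 8-seed sub-voxel grid is supported")
    if e1 is None:
        if tensors is None:
            raise ValueError("provide tensors or a principal-direction field")
        e1 = principal_directions(tensors)
    tracker = _Tracker(e1, fa, affine, min_fa, max_angle_deg,
                       max_avg_neighbor_angle_deg, neighborhood, max_steps)
    bundle = StreamlineBundle(affine=np.asarray(affine, dtype=float), participant=participant)
    seed_voxels = np.argwhere(fa >= min_fa)
    for vox in seed_voxels:
        e = e1[tuple(vox)]
        for off in _SEED_OFFSETS:
            p0 = vox + off
            fwd_pts, fwd_reason = tracker.propagate(p0, e)
            bwd_pts, bwd_reason = tracker.propagate(p0, -e)
            pts_vox = np.vstack([np.asarray(bwd_pts)[::-1], np.asarray(fwd_pts)[1:]])
            keep = np.ones(len(pts_vox), dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(pts_vox, axis=0), axis=1) > 1e-12
            pts_vox = pts_vox[keep]
            if len(pts_vox) < 2:
                continue
            bundle.streamlines.append(
                Streamline(
                    points=tracker.to_world(pts_vox),
                    seed_voxel=tuple(int(v) for v in vox),
                    termination=(bwd_reason, fwd_reason),
                )
            )
    return bundle
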