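import numpy as np
import pytest

from frontostriatal import connectivity as C
from frontostriatal.tracking import Streamline, StreamlineBundle


def _affine(vox=2.0, origin=(0.0, 0.0, 0.0)):
    A = np.eye(4)
    A[0, 0] = A[1, 1] = A[2, 2] = vox
    A[:3, 3] = origin
    return A


def _mask(shape, idx):
    m = np.zeros(shape, dtype=bool)
    m[idx] = True
    return m


def _fiber(points, seed=(0, 0, 0)):
    return Streamline(points=np.asarray(points, float), seed_voxel=seed,
                      termination=("volume_edge", "volume_edge"))


def _bundle(fibers):
    return StreamlineBundle(streamlines=list(fibers), affine=_affine())


class TestDilation:
    def test_zero_radius_identity(self):
        roi = C.ROIMask(_mask((8, 8, 8), (4, 4, 4)), _affine(), "r")
        out = C.dilate_mask(roi, 0.0)
        assert np.array_equal(out.data, roi.data)

    def test_2mm_sphere_on_2mm_grid_is_face_cross(self):
        roi = C.ROIMask(_mask((8, 8, 8), (4, 4, 4)), _affine(2.0), "r")
        out = C.dilate_mask(roi, 2.0)
        assert out.data.sum() == 7  # center + 6 face neighbors
        assert out.data[4, 4, 4] and out.data[3, 4, 4] and out.data[4, 4, 5]
        assert not out.data[3, 3, 4]  # diagonal at 2*sqrt(2) mm stays out

    def test_monotone(self):
        rng = np.random.default_rng(0)
        roi = C.ROIMask(rng.random((8, 8, 8)) > 0.9, _affine(), "r")
        out = C.dilate_mask(roi, 4.0)
        assert np.all(out.data[roi.data])
        assert out.dilation_mm == 4.0


class TestSelectFibers:
    def _setup(self):
        shape = (10, 10, 10)
        fa = np.full(shape, 0.5)
        fa[5, 5, 5] = 0.25
        roi = C.ROIMask(_mask(shape, (slice(4, 7), slice(4, 7), slice(4, 7))),
                        _affine(), "striatum")
        return fa, roi

    def test_low_fa_intersection_selected(self):
        fa, roi = self._setup()
        f = _fiber([[10, 10, 10], [10, 10, 8], [10, 10, 6], [10, 10, 4], [10, 10, 2]])
        # passes through voxel (5,5,5..) at FA 0.25 < 0.3
        sel = C.select_fibers(_bundle([f]), roi, fa)
        assert len(sel) == 1

    def test_high_fa_skimmer_rejected(self):
        fa, roi = self._setup()
        f = _fiber([[8, 10, 10], [8, 10, 8], [8, 10, 6]])  # ROI voxels but FA 0.5
        sel = C.select_fibers(_bundle([f]), roi, fa)
        assert len(sel) == 0

    def test_never_touching_rejected(self):
        fa, roi = self._setup()
        f = _fiber([[0, 0, 0], [0, 0, 4]])
        assert len(C.select_fibers(_bundle([f]), roi, fa)) == 0

    def test_idempotent(self):
        fa, roi = self._setup()
        f = _fiber([[10, 10, 10], [10, 10, 8], [10, 10, 6], [10, 10, 4]])
        once = C.select_fibers(_bundle([f]), roi, fa)
        twice = C.select_fibers(once, roi, fa)
        assert len(once) == len(twice) == 1
        assert np.array_equal(once.streamlines[0].points, twice.streamlines[0].points)

    def test_first_vs_any_rule(self):
        fa, roi = self._setup()
        # first ROI entry at FA 0.5, later point at the FA 0.25 voxel
        f = _fiber([[8, 8, 12], [8, 8, 8], [10, 10, 10]])
        assert len(C.select_fibers(_bundle([f]), roi, fa, rule="any")) == 1
        assert len(C.select_fibers(_bundle([f]), roi, fa, rule="first")) == 0


class TestProlongation:
    def test_straight_fiber_adds_6mm_collinear(self):
        pts = np.column_stack([np.arange(0, 12, 2.0), np.zeros(6), np.zeros(6)])
        f = _fiber(pts)
        out = C.prolong_fiber(f)
        assert len(out.points) == 12  # 6 original + 3 per end
        added = out.points.copy()
        assert np.allclose(added[:, 1:], 0)  # stays collinear
        # arc length added per end is exactly 3 steps x 2 mm = 6 mm
        assert out.points[0, 0] == pytest.approx(-6.0)
        assert out.points[-1, 0] == pytest.approx(16.0)

    def test_short_fiber_unchanged_with_flag(self):
        f = _fiber([[0, 0, 0], [2, 0, 0], [4, 0, 0], [6, 0, 0]])  # 4 points
        with pytest.warns(UserWarning):
            out = C.prolong_fiber(f)
        assert np.array_equal(out.points, f.points)

    def test_arc_prolongation_turn_bounded(self):
        """Appended segments never turn faster than the recent fiber turns.

        Holds when the 2 mm prolongation step does not exceed the fiber's
        own segment spacing (here ~2.9 mm arc steps): the running mean of
        the last four directions is a low-pass filter on the tangent.
        """
        th = np.linspace(0, np.pi / 2, 12)
        pts = np.column_stack([20 * np.cos(th), 20 * np.sin(th), np.zeros_like(th)])
        f = _fiber(pts)
        out = C.prolong_fiber(f)
        segs = np.diff(out.points, axis=0)
        segs /= np.linalg.norm(segs, axis=1, keepdims=True)
        turn = np.arccos(np.clip(np.sum(segs[1:] * segs[:-1], axis=1), -1, 1))
        orig_segs = np.diff(pts, axis=0)
        orig_segs /= np.linalg.norm(orig_segs, axis=1, keepdims=True)
        orig_turn = np.arccos(np.clip(np.sum(orig_segs[1:] * orig_segs[:-1], axis=1), -1, 1))
        # turns between successive appended segments (the junction with the
        # fiber itself turns up to ~1.5 per-step angles, because the mean of
        # the last four directions lags the end tangent)
        appended = np.concatenate([turn[:2], turn[-2:]])
        assert np.max(appended) <= np.max(orig_turn) + 1e-9
        junctions = np.array([turn[2], turn[-3]])
        assert np.max(junctions) <= 2.0 * np.max(orig_turn)

    def test_prolong_then_select_never_loses_fibers(self):
        shape = (10, 10, 10)
        fa = np.full(shape, 0.25)
        roi = C.ROIMask(_mask(shape, (slice(4, 7), slice(4, 7), slice(4, 7))), _affine(), "r")
        fibers = [_fiber([[10, 10, 2 * k], [10, 10, 2 * k + 2], [10, 10, 2 * k + 4],
                          [10, 10, 2 * k + 6], [10, 10, 2 * k + 8]]) for k in range(3)]
        plain = C.select_fibers(_bundle(fibers), roi, fa)
        prolonged = C.prolong_bundle(_bundle(fibers))
        after = C.select_fibers(prolonged, roi, fa)
        assert len(after) >= len(plain)


class TestMidsagittalCut:
    def test_ipsilateral_fiber_unchanged(self):
        f = _fiber([[-4, 0, 0], [-2, 0, 0], [-1, 0, 0]])
        out = C.cut_midsagittal(f, side=-1)
        assert np.array_equal(out.points, f.points)

    def test_single_crossing_interpolated(self):
        f = _fiber([[-4, 0, 0], [-1, 1, 0], [3, 2, 0]])
        out = C.cut_midsagittal(f, side=-1)
        assert np.all(out.points[:-1, 0] <= 0)
        assert out.points[-1, 0] == pytest.approx(0.0, abs=1e-9)
        # interpolation: crossing of segment (-1,1,0)->(3,2,0) at x=0
        assert out.points[-1, 1] == pytest.approx(1.25)

    def test_multiple_crossings_cut_at_first(self):
        f = _fiber([[-4, 0, 0], [2, 0, 0], [-3, 0, 0], [5, 0, 0]])
        out = C.cut_midsagittal(f, side=-1)
        assert len(out.points) == 2  # first point + interpolated plane point
        assert out.points[-1, 0] == pytest.approx(0.0, abs=1e-9)

    def test_contralateral_fiber_flagged_empty(self):
        f = _fiber([[3, 0, 0], [5, 0, 0]])
        with pytest.warns(UserWarning):
            out = C.cut_midsagittal(f, side=-1)
        assert out is None


class TestProbabilityMap:
    def test_single_participant_unsmoothed_binary(self):
        b = _bundle([_fiber([[2, 2, 2], [2, 2, 10]])])
        m = C.bundle_probability_map([b], (8, 8, 8), _affine(),
                                     dilate_vox=0, smooth_fwhm_mm=0.0)
        assert set(np.unique(m)) <= {0.0, 1.0}
        assert m.sum() > 0

    def test_shared_bundle_gives_unit_core(self):
        fibers = [_fiber([[2, 2, 2], [2, 2, 10]])]
        bundles = [_bundle(fibers) for _ in range(5)]
        m = C.bundle_probability_map(bundles, (8, 8, 8), _affine(),
                                     dilate_vox=3, smooth_fwhm_mm=0.0)
        assert m.max() == pytest.approx(1.0)
        assert np.all((m == 0) | (m == 1))

    def test_values_within_unit_interval(self):
        rng = np.random.default_rng(0)
        bundles = []
        for p in range(4):
            pts = np.cumsum(rng.normal(0, 1.5, size=(6, 3)), axis=0) + 8
            bundles.append(_bundle([_fiber(pts)]))
        m = C.bundle_probability_map(bundles, (10, 10, 10), _affine())
        assert m.min() >= 0.0 and m.max() <= 1.0 + 1e-12


class TestConnectogram:
    def _cluster(self, shape=(10, 10, 10)):
        return {"ctx": C.ROIMask(_mask(shape, (slice(0, 2), slice(0, 2), slice(0, 2))),
                                 _affine(), "ctx")}

    def test_fiber_count_does_not_matter(self):
        hit = _fiber([[1, 1, 1], [5, 5, 5]])
        one = [{"stri": _bundle([hit])}]
        many = [{"stri": _bundle([hit] * 1000)}]
        a = C.connectogram([self._cluster()], one)
        b = C.connectogram([self._cluster()], many)
        assert a.counts.loc["ctx", "stri"] == b.counts.loc["ctx", "stri"] == 1

    def test_empty_bundles_all_zero(self):
        cg = C.connectogram([self._cluster()] * 3, [{"stri": _bundle([])}] * 3)
        assert (cg.counts.to_numpy() == 0).all()
        assert cg.n_participants == 3

    def test_missing_cluster_counts_as_unconnected(self):
        hit = _fiber([[1, 1, 1], [5, 5, 5]])
        clusters = [self._cluster(), {}]
        bundles = [{"stri": _bundle([hit])}, {"stri": _bundle([hit])}]
        cg = C.connectogram(clusters, bundles)
        assert cg.counts.loc["ctx", "stri"] == 1

    def test_fiber_order_invariance(self):
        hit = _fiber([[1, 1, 1], [5, 5, 5]])
        miss = _fiber([[9, 9, 9], [9, 9, 13]])
        a = C.connectogram([self._cluster()], [{"stri": _bundle([hit, miss])}])
        b = C.connectogram([self._cluster()], [{"stri": _bundle([miss, hit])}])
        assert a.counts.equals(b.counts)

    def test_tsv_output(self, tmp_path):
        hit = _fiber([[1, 1, 1], [5, 5, 5]])
        cg = C.connectogram([self._cluster()], [{"stri": _bundle([hit])}])
        p = tmp_path / "connectogram.tsv"
        cg.to_tsv(p)
        import pandas as pd
        df = pd.read_csv(p, sep="\t")
        assert list(df.columns) == ["cortical_label", "striatal_label",
                                    "n_connected", "n_total"]
        assert df["n_connected"].iloc[0] == 1
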