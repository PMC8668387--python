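"""Box-counting fractal dimension, Murray's deviation, bifurcation angle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselmorph import (
    BranchPoint,
    NoVesselsError,
    VesselGraph,
    VesselSegment,
    build_vessel_graph,
    compute_ba,
    compute_md,
    compute_mvfd,
    murray_deviation,
    rasterize,
    summarize,
)
from vesselmorph.synthetic_networks import Stroke, SyntheticNetworkSpec
from conftest import sierpinski_carpet


class TestMvfd:
    def test_filled_image_dimension_two(self):
        series = compute_mvfd(np.ones((256, 256), dtype=np.uint8))
        assert series.mvfd == pytest.approx(2.0, abs=0.05)

    def test_line_dimension_one(self):
        arr = np.zeros((256, 256), dtype=np.uint8)
        arr[100, :] = 1
        assert compute_mvfd(arr).mvfd == pytest.approx(1.0, abs=0.05)

    def test_sierpinski_carpet_matches_closed_form(self):
        target = np.log(8) / np.log(3)  # 1.8928
        series = compute_mvfd(sierpinski_carpet(5))
        assert series.mvfd == pytest.approx(target, abs=0.05)

    def test_counts_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        arr = (rng.random((100, 130)) < 0.2).astype(np.uint8)
        series = compute_mvfd(arr)
        counts = np.array(series.counts)  # S descending
        assert (np.diff(counts) >= 0).all(), "N_S never decreases as boxes shrink"
        assert counts[0] == 1 and counts[-1] == arr.sum()
        assert 0.0 <= series.mvfd <= 2.0

    def test_adding_pixels_never_decreases_counts(self):
        rng = np.random.default_rng(1)
        arr = (rng.random((64, 64)) < 0.1).astype(np.uint8)
        more = arr.copy()
        extra = rng.random((64, 64)) < 0.1
        more[extra] = 1
        c1 = np.array(compute_mvfd(arr).counts)
        c2 = np.array(compute_mvfd(more).counts)
        assert (c2 >= c1).all()

    def test_padding_beyond_required_is_irrelevant(self):
        rng = np.random.default_rng(2)
        arr = (rng.random((100, 100)) < 0.15).astype(np.uint8)
        bigger = np.zeros((128, 128), dtype=np.uint8)
        bigger[:100, :100] = arr
        assert compute_mvfd(arr).mvfd == pytest.approx(compute_mvfd(bigger).mvfd, abs=1e-12)

    def test_translation_by_largest_box_multiple(self):
        arr = np.zeros((256, 256), dtype=np.uint8)
        arr[10:40, 20:60] = np.random.default_rng(3).random((30, 40)) < 0.5
        shifted = np.zeros_like(arr)
        shifted[10 + 128 : 40 + 128, 20:60] = arr[10:40, 20:60]
        assert compute_mvfd(arr).mvfd == pytest.approx(compute_mvfd(shifted).mvfd, abs=1e-12)

    def test_single_pixel_degenerate(self):
        arr = np.zeros((32, 32), dtype=np.uint8)
        arr[5, 7] = 1
        with pytest.warns(UserWarning, match="degenerate"):
            series = compute_mvfd(arr)
        assert series.mvfd == 0.0 and series.degenerate

    def test_empty_raises(self):
        with pytest.raises(NoVesselsError):
            compute_mvfd(np.zeros((16, 16), dtype=np.uint8))


class TestMurrayDeviation:
    def test_hand_computed_examples(self):
        assert murray_deviation(3.0, [2.0, 2.0]) == pytest.approx(11.0 / 27.0)  # 0.4074
        assert murray_deviation(3.0, [3.0]) == pytest.approx(0.0)
        # Murray's law satisfied exactly: d = D / 2^(1/3) for two equal daughters
        d = 2.0 / 2.0 ** (1.0 / 3.0)
        assert murray_deviation(2.0, [d, d]) == pytest.approx(0.0, abs=1e-12)

    @given(
        dm=st.floats(0.5, 50.0),
        d1=st.floats(0.1, 50.0),
        d2=st.floats(0.1, 50.0),
        c=st.floats(0.01, 100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, dm, d1, d2, c):
        base = murray_deviation(dm, [d1, d2])
        scaled = murray_deviation(c * dm, [c * d1, c * d2])
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)


def _fake_graph(calibers, lengths, n_sv=None):
    """Build a minimal in-memory graph: one branch point, given segments."""
    segments = {}
    for i, (cal, ln) in enumerate(zip(calibers, lengths), start=1):
        path = np.array([[0, j] for j in range(max(int(ln), 2))])
        seg = VesselSegment(label=i, path=path, length_px=float(ln))
        seg.diameters_px = np.full(len(path), float(cal))
        seg.mean_diameter_px = float(cal)
        seg.caliber_px = float(cal)
        segments[i] = seg
    bp = BranchPoint(0, 0, members=[(0, 0)])
    bp.incident_labels = tuple(segments)
    bp.n_sv = len(segments)
    bp.degenerate = bp.n_sv < 2
    dummy = np.zeros((4, 4), dtype=bool)
    return VesselGraph(
        skeleton=dummy,
        segments=segments,
        branch_points=[bp],
        label_image=np.zeros((4, 4), dtype=int),
        excised_mask=dummy,
        mean_vessel_length_px=float(np.mean(lengths)),
    )


class TestComputeMd:
    def test_mother_is_largest_diameter(self):
        graph = _fake_graph([3.0, 2.0, 2.0], [30, 20, 20])
        (rec,) = compute_md(graph)
        assert rec.mother_diameter_px == 3.0
        assert rec.md == pytest.approx(11.0 / 27.0)

    def test_mother_tie_broken_by_length(self):
        graph = _fake_graph([3.0, 3.0, 2.0], [10, 40, 20])
        (rec,) = compute_md(graph)
        assert rec.mother_label == 2, "tied diameters: the longer segment is the mother"

    def test_degenerate_branch_skipped(self):
        graph = _fake_graph([3.0], [30])
        graph.branch_points[0].degenerate = True
        graph.branch_points[0].n_sv = 1
        assert compute_md(graph) == []


def _junction_spec(
    angle_deg,
    arm=45.0,
    width=4.0,
    mother_width=6.0,
    mother_len=70.0,
    orient=17.0,
    canvas=180,
):
    """One Y junction with daughters separated by a known analytic angle."""
    j = np.array([canvas / 2.0, canvas / 2.0])
    phi = np.radians(orient)

    def unit(t):
        return np.array([np.sin(t), np.cos(t)])

    a = np.radians(angle_deg)
    strokes = (
        Stroke((tuple(j - mother_len * unit(phi)), tuple(j)), mother_width),
        Stroke((tuple(j), tuple(j + arm * unit(phi + a / 2))), width),
        Stroke((tuple(j), tuple(j + arm * unit(phi - a / 2))), width),
    )
    return SyntheticNetworkSpec(strokes=strokes, canvas_px=(canvas, canvas))


class TestComputeBa:
    @pytest.mark.parametrize("angle", [60.0, 90.0, 120.0])
    @pytest.mark.parametrize("orient", [17.0, 80.0, 141.0])
    def test_matches_analytic_angle(self, angle, orient):
        arr = rasterize(
            _junction_spec(angle, arm=150.0, mother_len=200.0, canvas=480, orient=orient)
        )
        graph = build_vessel_graph(arr)
        records = compute_ba(graph, image=arr)
        measured = [r.ba_deg for r in records if r.ba_deg is not None]
        assert len(measured) == 1
        tol = 0.5 if angle == 90.0 else 1.0
        assert measured[0] == pytest.approx(angle, abs=tol)

    def test_rotation_invariance(self):
        # long straight arms: the fitted half-portion is ~45 px per daughter
        arr = rasterize(_junction_spec(100.0, arm=100.0, mother_len=110.0, canvas=320))
        base = [
            r.ba_deg
            for r in compute_ba(build_vessel_graph(arr), image=arr)
            if r.ba_deg is not None
        ][0]
        rot = np.rot90(arr).copy()
        rotated = [
            r.ba_deg
            for r in compute_ba(build_vessel_graph(rot), image=rot)
            if r.ba_deg is not None
        ][0]
        assert rotated == pytest.approx(base, abs=0.5)

    def test_only_three_subvessel_branches_get_angles(self, plus_cross):
        graph = build_vessel_graph(plus_cross)
        records = compute_ba(graph, image=plus_cross)
        assert all(r.ba_deg is None for r in records if r.n_sv != 3)


class TestSummarize:
    def test_stats_of_known_values(self):
        graph = _fake_graph([3.0, 2.0, 2.0], [30, 20, 20])
        recs = compute_md(graph)
        recs[0].md = 0.4
        more = [recs[0]]
        for md in (0.2, 0.6):
            g = _fake_graph([3.0, 2.0, 2.0], [30, 20, 20])
            r = compute_md(g)[0]
            r.md = md
            more.append(r)
        s = summarize(more)
        assert (s.md_mean, s.md_median, s.md_max, s.md_min) == pytest.approx(
            (0.4, 0.4, 0.6, 0.2)
        )
        assert s.n_bifurcations == 3

    def test_single_record_collapses(self):
        g = _fake_graph([3.0, 2.0, 2.0], [30, 20, 20])
        s = summarize(compute_md(g))
        assert s.md_mean == s.md_median == s.md_max == s.md_min

    def test_empty_reports_missing_not_zero(self):
        s = summarize([])
        assert s.md_mean is None and s.ba_mean is None
        assert s.n_bifurcations == 0

    def test_ordering_invariants(self):
        rng = np.random.default_rng(4)
        records = []
        for md in rng.uniform(0.05, 0.9, size=9):
            g = _fake_graph([3.0, 2.0, 2.0], [30, 20, 20])
            r = compute_md(g)[0]
            r.md = float(md)
            records.append(r)
        s = summarize(records)
        assert s.md_min <= s.md_median <= s.md_max
        assert s.md_min <= s.md_mean <= s.md_max
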