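"""Synthetic model generation: rasterization, preset constraints, cohorts."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.stats import truncnorm

from vesselmorph import (
    InputError,
    detect_branch_points,
    make_ba_model,
    make_cohort,
    make_complexity_models,
    make_md_model,
    make_pattern_model,
    rasterize,
    render_lesion_mask,
    skeletonize,
)
from vesselmorph.synthetic_networks import (
    COHORT_DISTRIBUTIONS,
    Stroke,
    SyntheticNetworkSpec,
)


class TestRasterize:
    def test_single_stroke_width(self):
        spec = SyntheticNetworkSpec(
            strokes=(Stroke(((50.0, 20.0), (50.0, 180.0)), 7.0),), canvas_px=(100, 200)
        )
        arr = rasterize(spec)
        _, n = ndi.label(arr, structure=np.ones((3, 3)))
        assert n == 1
        widths = arr[:, 60:140].sum(axis=0)
        assert widths[widths > 0].mean() == pytest.approx(7.0, abs=1.0)

    def test_crossing_strokes_single_component_one_branch_cluster(self):
        spec = SyntheticNetworkSpec(
            strokes=(
                Stroke(((30.0, 30.0), (170.0, 170.0)), 5.0),
                Stroke(((30.0, 170.0), (170.0, 30.0)), 5.0),
            ),
            canvas_px=(200, 200),
        )
        arr = rasterize(spec)
        _, n = ndi.label(arr, structure=np.ones((3, 3)))
        assert n == 1
        bps = detect_branch_points(skeletonize(arr))
        assert len(bps) == 1

    def test_empty_spec_raises(self):
        with pytest.raises(InputError):
            rasterize(SyntheticNetworkSpec(strokes=(), canvas_px=(64, 64)))

    def test_deterministic(self):
        spec = make_ba_model(100.0, seed=5)
        assert (rasterize(spec) == rasterize(spec)).all()

    def test_off_canvas_clipped_with_warning(self):
        spec = SyntheticNetworkSpec(
            strokes=(Stroke(((-10.0, 5.0), (30.0, 90.0)), 4.0),), canvas_px=(64, 64)
        )
        with pytest.warns(UserWarning, match="clipped"):
            arr = rasterize(spec)
        assert arr.any()

    def test_narrow_stroke_rejected(self):
        with pytest.raises(InputError, match="width"):
            Stroke(((0.0, 0.0), (10.0, 10.0)), 1.0)


class TestBaModel:
    @pytest.mark.parametrize("preset", [120.0, 100.0, 80.0])
    def test_preset_mean_exact_at_spec_level(self, preset):
        spec = make_ba_model(preset, n_junctions=5, seed=1)
        angles = spec.ground_truth["per_junction_ba_deg"]
        assert np.mean(angles) == pytest.approx(preset, abs=1e-9)
        assert all(10 < a < 170 for a in angles)

    def test_identical_spec_on_rerun(self):
        a = make_ba_model(100.0, seed=7)
        b = make_ba_model(100.0, seed=7)
        assert a.ground_truth == b.ground_truth
        assert a.strokes == b.strokes

    def test_infeasible_preset_raises(self):
        with pytest.raises(InputError):
            make_ba_model(5.0)
        with pytest.raises(InputError):
            make_ba_model(175.0)


class TestMdModel:
    @pytest.mark.parametrize("preset", [0.2, 0.4, 0.6])
    def test_preset_mean_exact_at_spec_level(self, preset):
        spec = make_md_model(preset, n_junctions=4, seed=2)
        targets = spec.ground_truth["per_junction_md"]
        assert np.mean(targets) == pytest.approx(preset, abs=1e-9)

    def test_daughter_widths_solve_cube_relation(self):
        spec = make_md_model(0.4, n_junctions=4, seed=3)
        for j in spec.junctions:
            dm3 = j.mother_width_px**3
            dd3 = sum(w**3 for w in j.daughter_widths_px)
            assert abs(dm3 - dd3) / dm3 == pytest.approx(j.md, abs=1e-9)

    def test_murray_law_preset_zero(self):
        spec = make_md_model(0.0, n_junctions=3, seed=0)
        for j in spec.junctions:
            assert j.daughter_widths_px[0] == pytest.approx(10.0 / 2 ** (1 / 3), abs=1e-9)

    def test_too_low_resolution_raises(self):
        with pytest.raises(InputError, match="resolution"):
            make_md_model(0.6, mother_width_px=3.0)


class TestPatternModel:
    @pytest.mark.parametrize("pattern", ["central", "peripheral"])
    def test_vessels_land_in_designated_region(self, pattern):
        spec = make_pattern_model(pattern, seed=4)
        arr = rasterize(spec)
        mask = render_lesion_mask(spec)
        # independent region oracle from the lesion disk definition
        c = np.array(spec.lesion_mask_spec.center_rc)
        boundary = 0.5 * (spec.lesion_mask_spec.radius_px - 3.0)
        rr, cc = np.nonzero(arr)
        dist = np.hypot(rr - c[0], cc - c[1])
        frac_center = (dist <= boundary).mean()
        assert mask[rr, cc].all(), "all vessels lie inside the lesion"
        if pattern == "central":
            assert frac_center >= 0.9
        else:
            assert frac_center <= 0.1

    def test_mirrored_model_same_pattern(self):
        spec = make_pattern_model("central", seed=6)
        arr = rasterize(spec)[:, ::-1]
        mask = render_lesion_mask(spec)[:, ::-1]
        from vesselmorph import build_lesion_geometry, compute_vdr_svp

        geom = build_lesion_geometry(mask, erosion_radius_px=3)
        assert compute_vdr_svp(arr, geom).svp == 1


class TestCohort:
    def test_deterministic_and_well_formed(self):
        a = make_cohort(35, 25, seed=9)
        b = make_cohort(35, 25, seed=9)
        assert a.equals(b)
        assert len(a) == 60
        assert set(a.label) == {"benign", "malignant"}
        assert a.columns[0] == "id"

    def test_physical_bounds_respected(self):
        c = make_cohort(200, 200, seed=1)
        assert c.mvfd.between(1.0, 2.0).all()
        assert (c[["md_mean", "md_median", "md_max", "md_min"]] >= 0).all().all()
        assert c.ba_mean.between(0, 180).all()
        assert (c.vdr > 0).all()
        assert c.svp.isin([0, 1]).all()
        assert c.size_mm.between(5, 40).all()

    def test_order_statistics_consistent(self):
        c = make_cohort(100, 100, seed=2)
        for fam in ("md", "ba"):
            assert (c[f"{fam}_min"] <= c[f"{fam}_median"]).all()
            assert (c[f"{fam}_median"] <= c[f"{fam}_max"]).all()
            assert (c[f"{fam}_mean"] >= c[f"{fam}_min"]).all()
            assert (c[f"{fam}_mean"] <= c[f"{fam}_max"]).all()

    @pytest.mark.parametrize("param", ["mvfd", "vdr"])
    def test_group_means_match_truncated_normals(self, param):
        # only unclipped parameters: the order-statistic repair shifts md/ba marginals
        n = 4000
        c = make_cohort(n, n, seed=3)
        for label, (idx_mean, idx_sd) in (("benign", (0, 1)), ("malignant", (2, 3))):
            spec = COHORT_DISTRIBUTIONS[param]
            mean, sd, lo, hi = spec[idx_mean], spec[idx_sd], spec[4], spec[5]
            a = (lo - mean) / sd
            b = (hi - mean) / sd if np.isfinite(hi) else np.inf
            expected = truncnorm.mean(a, b, loc=mean, scale=sd)
            observed = c.loc[c.label == label, param]
            assert observed.mean() == pytest.approx(expected, abs=3.5 * sd / np.sqrt(n))

    def test_group_direction_matches_reported_effects(self):
        c = make_cohort(300, 300, seed=5)
        b = c[c.label == "benign"]
        m = c[c.label == "malignant"]
        assert m.md_mean.mean() > b.md_mean.mean()
        assert m.ba_mean.mean() < b.ba_mean.mean()
        assert m.mvfd.mean() > b.mvfd.mean()
        assert m.vdr.mean() > b.vdr.mean()

    def test_too_small_groups_raise(self):
        with pytest.raises(InputError):
            make_cohort(1, 25)
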