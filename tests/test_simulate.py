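import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coamap.calibration import Calibration, DEFAULT_CALIBRATION
from coamap.regions import PIAL_DISTANCE_FROM_FPS, PIAL_REGIONS, Region
from coamap.simulate import (
    GroundTruth,
    SimConfig,
    SimulationError,
    ground_truth_summaries,
    sample_truncated_lognormal,
    simulate_cohort,
    simulate_fov,
    simulate_section,
    stage_expected_counts,
)


def test_zero_intensity_yields_empty_fov(rng, calibration):
    cfg = SimConfig(hd_intensity=0.0)
    img, gt = simulate_fov(cfg, calibration, Region.FPS, rng)
    assert len(gt.objects) == 0
    assert gt.fovs["true_count"].iloc[0] == 0
    # nothing but background: all intensities near the background level
    assert img.pixels.max() < cfg.background_level + 6 * cfg.background_noise_sd


def test_identical_seed_is_bit_identical(small_calibration):
    cfg = SimConfig(hd_intensity=400.0)
    runs = []
    for _ in range(2):
        rng = np.random.default_rng(7)
        runs.append(simulate_fov(cfg, small_calibration, Region.PPS, rng))
    (img_a, gt_a), (img_b, gt_b) = runs
    assert np.array_equal(img_a.pixels, img_b.pixels)
    pd.testing.assert_frame_equal(gt_a.objects, gt_b.objects)


def test_hd_band_count_is_poisson_with_expected_mean(rng, calibration):
    """Mean HD count over 200 fields ~ intensity x band area (500 x 0.05164)."""
    cfg = SimConfig(hd_intensity=500.0, ld_ratio=0.0)
    expected = 500.0 * calibration.fov_width_um * 100.0 / 1e6
    counts = []
    for i in range(200):
        _, gt = simulate_fov(cfg, calibration, Region.FPS, rng, render=False)
        counts.append(len(gt.objects))
    counts = np.asarray(counts)
    assert expected == pytest.approx(25.8, abs=0.05)
    se = np.sqrt(expected / len(counts))
    assert abs(counts.mean() - expected) < 3 * se
    assert set(gt.objects["zone"]) <= {"HD"}


def test_hard_core_separation_is_enforced(rng, calibration):
    cfg = SimConfig(hd_intensity=2000.0, min_separation_um=15.0)
    _, gt = simulate_fov(cfg, calibration, Region.FPS, rng, render=False)
    xy = gt.objects[["centroid_x_um", "centroid_y_um"]].to_numpy()
    d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).T)
    np.fill_diagonal(d, np.inf)
    assert d.min() >= 15.0


def test_infeasible_packing_raises_with_context(rng):
    tiny = Calibration(DEFAULT_CALIBRATION.pixel_size_um, 64, 64)
    cfg = SimConfig(hd_intensity=5e6, min_separation_um=20.0, max_placement_attempts=50)
    with pytest.raises(SimulationError, match="FPS"):
        simulate_fov(cfg, tiny, Region.FPS, rng, render=False)


def test_diameters_respect_truncation_bounds(rng):
    d = sample_truncated_lognormal(rng, 5000, np.log(9.0), 0.3, (3.0, 30.0))
    assert d.min() >= 3.0 and d.max() <= 30.0
    # median near the location parameter
    assert np.median(d) == pytest.approx(9.0, rel=0.05)


def test_detectability_contract_validated():
    cfg = SimConfig(blob_peak_level=600.0, background_level=500.0, background_noise_sd=50.0)
    with pytest.raises(ValueError):
        cfg.validate()


def test_true_area_fraction_matches_object_areas(rng, calibration):
    cfg = SimConfig(hd_intensity=300.0)
    img, gt = simulate_fov(cfg, calibration, Region.FPS, rng)
    d = gt.objects["true_diameter_um"].to_numpy()
    analytic = 100.0 * np.sum(np.pi * (d / 2) ** 2) / calibration.fov_area_um2
    raster = gt.fovs["true_area_fraction_pct"].iloc[0]
    # raster discretisation error <= ~1 px per object perimeter
    per_object_tol = len(d) * np.pi * d.mean() * calibration.pixel_size_um
    assert abs(raster / 100 * calibration.fov_area_um2 - analytic / 100 * calibration.fov_area_um2) \
        <= per_object_tol


class TestSection:
    def test_stage0_is_empty(self, rng, calibration):
        cfg = SimConfig(stage=0)
        _, gt = simulate_section(cfg, calibration, rng, render=False)
        assert len(gt.objects) == 0
        assert gt.sections["true_stage"].iloc[0] == 0
        assert not gt.sections["deep_wm_lv"].iloc[0]

    def test_stage4_sets_deep_white_matter_flags(self, rng, calibration):
        cfg = SimConfig(stage=4)
        _, gt = simulate_section(cfg, calibration, rng, render=False,
                                 regions=[Region.FPS, Region.LV])
        assert bool(gt.sections["deep_wm_lv"].iloc[0])
        assert bool(gt.sections["deep_wm_phg_fusiform"].iloc[0])

    @pytest.mark.parametrize("stage", [2, 3, 4])
    def test_fps_expected_count_dominates(self, stage):
        counts = stage_expected_counts(stage)
        fps = counts[Region.FPS]
        assert all(fps >= counts[r] for r in PIAL_REGIONS)
        assert fps > counts[Region.APS]

    @pytest.mark.parametrize("stage", [2, 3, 4])
    def test_gradient_monotone_in_pial_distance(self, stage):
        """Expected intensity decays with ordinal pial distance from FPS."""
        counts = stage_expected_counts(stage)
        lateral = [Region.FPS, Region.PPS, Region.SPS, Region.MPS, Region.LPS, Region.CPS]
        vals = [counts[r] for r in lateral]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert counts[Region.FPS] > counts[Region.APS]

    def test_stage_bands_have_margin(self):
        """Expected FPS counts sit >= 1 count inside the half-open bands."""
        bands = {1: (0, 10), 2: (10, 50), 3: (50, 500), 4: (50, 500)}
        for stage, (lo, hi) in bands.items():
            fps = stage_expected_counts(stage)[Region.FPS]
            assert lo + 1 <= fps <= hi - 1

    def test_count_conservation(self, rng, calibration):
        cfg = SimConfig(stage=2, fovs_per_region=2)
        _, gt = simulate_section(cfg, calibration, rng, render=False)
        assert gt.fovs["true_count"].sum() == len(gt.objects)
        per_fov = gt.objects.groupby("fov_id").size()
        merged = gt.fovs.set_index("fov_id")["true_count"]
        for fov_id, n in per_fov.items():
            assert merged[fov_id] == n


class TestCohort:
    def test_covariates_and_balanced_stages(self, rng, calibration):
        cfg = SimConfig(subjects=10, fovs_per_region=1)
        _, gt, cov = simulate_cohort(cfg, calibration, rng, regions=[Region.FPS],
                                     render=False)
        assert len(cov) == 10
        assert set(cov.columns) == {"section_id", "age", "bmi", "sex"}
        assert cov["age"].between(*cfg.age_range).all()
        assert sorted(gt.sections["true_stage"].value_counts()) == [2, 2, 2, 2, 2]
        assert set(cov["sex"]) == {"M", "F"}

    def test_age_slope_creates_positive_diameter_correlation(self, rng, calibration):
        """slope 0.05 um/yr, 30 subjects, ages 42-89 -> positive rank corr."""
        cfg = SimConfig(subjects=30, fovs_per_region=2, age_diameter_slope=0.05,
                        stage=3)
        _, gt, cov = simulate_cohort(cfg, calibration, rng, regions=[Region.FPS],
                                     render=False, stages=[3] * 30)
        mean_d = gt.objects.groupby("section_id")["true_diameter_um"].mean()
        joined = cov.set_index("section_id").join(mean_d)
        r, _ = sps.spearmanr(joined["age"], joined["true_diameter_um"])
        assert r > 0.5

    def test_zero_slope_gives_null_correlation_on_average(self, calibration):
        """Age-diameter correlation centred on 0 when the slope is off."""
        rs = []
        for k in range(30):
            rng = np.random.default_rng(1000 + k)
            cfg = SimConfig(subjects=10, fovs_per_region=1, age_diameter_slope=0.0)
            _, gt, cov = simulate_cohort(cfg, calibration, rng, regions=[Region.FPS],
                                         render=False, stages=[3] * 10)
            mean_d = gt.objects.groupby("section_id")["true_diameter_um"].mean()
            joined = cov.set_index("section_id").join(mean_d)
            r, _ = sps.spearmanr(joined["age"], joined["true_diameter_um"])
            rs.append(r)
        assert abs(np.mean(rs)) < 0.2

    def test_ground_truth_summaries_shape(self, rng, calibration):
        cfg = SimConfig(subjects=2, fovs_per_region=2)
        _, gt, _ = simulate_cohort(cfg, calibration, rng,
                                   regions=[Region.FPS, Region.CA2], render=False)
        summ = ground_truth_summaries(gt, calibration)
        assert len(summ) == len(gt.fovs)
        empty = summ[summ["count"] == 0]
        assert empty["area_fraction_pct"].eq(0).all()
        assert empty["mean_diameter_um"].isna().all()
        full = summ[summ["count"] > 0]
        assert (full["min_diameter_um"] <= full["mean_diameter_um"]).all()
        assert (full["mean_diameter_um"] <= full["max_diameter_um"]).all()
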