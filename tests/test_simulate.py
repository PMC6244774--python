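"""Synthetic-cohort generator: determinism, geometry, spectra, survival and tier models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oscillomark.activity import band_power
from oscillomark.simulate import (
    SyntheticCohortConfig,
    assign_nlgn3_tiers,
    generate_atlas,
    generate_cohort_table,
    generate_imaging_cohort,
    generate_region_timeseries,
    generate_survival,
    generate_tumor_mask,
    score_imaging_cohort,
    tier_thresholds_from_prevalence,
)
from oscillomark.survival import SurvivalData, cox_fit

SMALL = SyntheticCohortConfig(
    n_patients=4, n_regions=12, grid_shape=(14, 14, 14), duration_s=8.0,
    sampling_rate_hz=250.0, seed=7,
)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(censor_rate=1.0)
        with pytest.raises(ValueError):
            SyntheticCohortConfig(nlgn3_thresholds=(1.0, 0.5))
        with pytest.raises(ValueError):
            SyntheticCohortConfig(duration_s=0.0)

    def test_identical_config_and_seed_reproduce_cohort(self):
        a = generate_cohort_table(SMALL)
        b = generate_cohort_table(SMALL)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_cohort_table(SMALL)
        b = generate_cohort_table(SyntheticCohortConfig(**{**SMALL.__dict__, "seed": 8}))
        assert not a["time_weeks"].equals(b["time_weeks"])


class TestAtlas:
    def test_regions_partition_foreground_and_are_contiguous(self):
        from scipy import ndimage

        atlas = generate_atlas(SMALL)
        sizes = atlas.region_sizes()
        assert atlas.n_regions == SMALL.n_regions
        assert (sizes > 0).all()
        assert sizes.sum() == (atlas.labels > 0).sum()
        structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        for r in range(1, atlas.n_regions + 1):
            _, n_components = ndimage.label(atlas.labels == r, structure=structure)
            assert n_components == 1

    def test_single_region_covers_all_foreground(self):
        cfg = SyntheticCohortConfig(n_regions=1, grid_shape=(10, 10, 10))
        atlas = generate_atlas(cfg)
        assert set(np.unique(atlas.labels)) == {0, 1}

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_atlas(SyntheticCohortConfig(n_regions=1000, grid_shape=(4, 4, 4)))


class TestTumorMask:
    def test_deterministic_under_fixed_seed(self):
        atlas = generate_atlas(SMALL)
        m1 = generate_tumor_mask(SMALL, atlas, np.random.default_rng(3))
        m2 = generate_tumor_mask(SMALL, atlas, np.random.default_rng(3))
        assert np.array_equal(m1.mask, m2.mask)

    def test_overlaps_at_least_one_region(self, rng):
        atlas = generate_atlas(SMALL)
        for _ in range(5):
            m = generate_tumor_mask(SMALL, atlas, rng)
            assert (m.mask & (atlas.labels > 0)).any()

    def test_unit_radii_mask_is_discrete_ball(self, rng):
        """Radii (1,1,1): only voxels with ||x - c|| <= 1, i.e. at most 7."""
        atlas = generate_atlas(SMALL)
        m = generate_tumor_mask(SMALL, atlas, rng, radii_voxels=(1.0, 1.0, 1.0))
        assert 1 <= m.n_voxels <= 7


class TestTimeseries:
    def test_doubling_scale_quadruples_band_power(self):
        cfg = SyntheticCohortConfig(
            n_regions=2, duration_s=30.0, sampling_rate_hz=250.0, seed=1
        )
        p1, p2 = [], []
        for seed in range(12):
            sig = generate_region_timeseries(
                cfg, [1.0, 2.0], np.random.default_rng(seed)
            )
            p1.append(band_power(sig[0], cfg.sampling_rate_hz, cfg.band_hz))
            p2.append(band_power(sig[1], cfg.sampling_rate_hz, cfg.band_hz))
        assert np.mean(p2) / np.mean(p1) == pytest.approx(4.0, rel=0.10)

    def test_higher_scale_higher_power_almost_surely(self):
        cfg = SyntheticCohortConfig(
            n_regions=2, duration_s=10.0, sampling_rate_hz=250.0
        )
        wins = 0
        for seed in range(40):
            sig = generate_region_timeseries(cfg, [1.0, 2.0], np.random.default_rng(seed))
            wins += band_power(sig[1], 250.0, cfg.band_hz) > band_power(
                sig[0], 250.0, cfg.band_hz
            )
        assert wins == 40

    def test_nonpositive_scale_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_region_timeseries(
                SyntheticCohortConfig(n_regions=2), [1.0, 0.0], rng
            )


class TestSurvivalGenerator:
    def test_null_effect_makes_times_independent_of_z(self):
        cfg = SyntheticCohortConfig(n_patients=400, log_hr_per_sd=0.0, censor_rate=0.0)
        ok = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            z = r.standard_normal(400)
            t, _ = generate_survival(cfg, z, r)
            p = sps.ks_2samp(t[z > 0], t[z <= 0]).pvalue
            ok += p > 0.01
        assert ok >= 18  # KS rejects at ~1% under the null

    def test_zero_censor_rate_observes_all_events(self, rng):
        cfg = SyntheticCohortConfig(n_patients=50, censor_rate=0.0)
        t, e = generate_survival(cfg, rng.standard_normal(50), rng)
        assert e.all() and (t > 0).all()

    def test_censor_rate_calibration(self):
        cfg = SyntheticCohortConfig(n_patients=4000, censor_rate=0.3)
        r = np.random.default_rng(0)
        z = r.standard_normal(4000)
        _, e = generate_survival(cfg, z, r)
        assert (~e).mean() == pytest.approx(0.3, abs=0.03)

    def test_cox_recovers_generating_hazard_ratio(self):
        """n=500 at log-HR ln 2.10, complete follow-up: the fitted HR lands in
        [1.9, 2.3] for most seeds (truncating follow-up widens the sampling
        distribution past this band; see the coverage test for the censored case)."""
        cfg = SyntheticCohortConfig(n_patients=500, censor_rate=0.0)
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            z = r.standard_normal(500)
            t, e = generate_survival(cfg, z, r)
            fit = cox_fit(SurvivalData.from_arrays(t, e, z, ("z",)))
            hits += 1.9 <= fit.hr[0] <= 2.3
        assert hits >= 0.9 * n_seeds


class TestTiers:
    def test_zero_noise_is_deterministic_step_function(self, rng):
        cfg = SyntheticCohortConfig(nlgn3_noise_sd=0.0, nlgn3_thresholds=(0.0, 1.0))
        z = np.array([-0.5, 0.5, 1.5])
        tiers = assign_nlgn3_tiers(cfg, z, rng)
        assert list(tiers) == ["low", "moderate", "high"]

    def test_quantile_thresholds_recover_cohort_prevalences(self):
        """Cut-points at the 12/21 and 18/21 latent quantiles give ~12/6/3 tiers."""
        noise_sd = 0.5
        thresholds = tier_thresholds_from_prevalence((12 / 21, 6 / 21, 3 / 21), noise_sd)
        cfg = SyntheticCohortConfig(
            nlgn3_thresholds=thresholds, nlgn3_noise_sd=noise_sd
        )
        counts = np.zeros(3)
        n_rep, n = 400, 21
        r = np.random.default_rng(0)
        for _ in range(n_rep):
            tiers = assign_nlgn3_tiers(cfg, r.standard_normal(n), r)
            counts += [(tiers == k).sum() for k in ("low", "moderate", "high")]
        assert np.allclose(counts / n_rep, [12, 6, 3], atol=0.5)

    def test_large_noise_erases_association(self):
        """With huge label noise the tier-activity association is null: the KW
        test rejects at 5% about 5% of the time."""
        from oscillomark.group_stats import kruskal_wallis

        cfg = SyntheticCohortConfig(nlgn3_noise_sd=100.0, nlgn3_thresholds=(-50.0, 50.0))
        ps = []
        r = np.random.default_rng(1)
        for _ in range(300):
            z = r.standard_normal(40)
            tiers = assign_nlgn3_tiers(cfg, z, r)
            groups = [z[tiers == k] for k in ("low", "moderate", "high")]
            groups = [g for g in groups if len(g) > 1]
            if len(groups) < 2:
                continue
            ps.append(kruskal_wallis(groups).p_value)
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 <= frac <= 0.10

    def test_monotone_in_z_on_average(self, rng):
        cfg = SyntheticCohortConfig()
        z = rng.standard_normal(3000)
        tiers = assign_nlgn3_tiers(cfg, z, rng)
        means = [z[tiers == k].mean() for k in ("low", "moderate", "high")]
        assert means[0] < means[1] < means[2]


class TestImagingCohort:
    def test_front_end_scores_track_latent_activity(self):
        """Full pipeline on volumes+signals: global z rank-correlates with latent z."""
        cfg = SyntheticCohortConfig(
            n_patients=6, n_regions=12, grid_shape=(14, 14, 14),
            duration_s=8.0, sampling_rate_hz=250.0, activity_gain=0.5, seed=11,
        )
        cohort = generate_imaging_cohort(cfg)
        oba = score_imaging_cohort(cohort)
        assert len(oba) == 6
        assert (oba["n_peritumor_regions"] >= 1).all()
        rho = sps.spearmanr(oba["global_z"], cohort.latent_z).statistic
        assert rho > 0.9
        # weighted-mean identity per patient
        r = cfg.n_regions
        k = oba["n_peritumor_regions"]
        lhs = r * oba["global_raw"]
        rhs = k * oba["peritumor_raw"] + (r - k) * oba["nontumor_raw"]
        assert np.allclose(lhs, rhs)
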