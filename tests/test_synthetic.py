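import dataclasses

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from pedct import (
    CalibrationError,
    CohortSpec,
    ParenchymaDistribution,
    PhantomSpec,
    calibrate_distribution,
    default_phantom_spec,
    generate_cohort,
    generate_phantom,
)
from pedct.synthetic import GAUSSIAN_TAIL


class TestCalibration:
    @pytest.mark.parametrize(
        "mean,sd,frac_low,frac_high",
        [
            (-803.0, 147.0, 0.0053, 0.1020),  # 10-year-old medians
            (-730.0, 142.3, 0.0146, 0.1247),  # 6-year-old medians
            (-832.5, 126.9, 0.0069, 0.0950),  # 15-year-old medians
            (-794.5, 150.0, 0.0100, 0.1100),  # whole-cohort-like targets
        ],
    )
    def test_hits_targets(self, mean, sd, frac_low, frac_high):
        d = calibrate_distribution(mean, sd, frac_low, frac_high)
        assert abs(d.achieved_mean - mean) <= 0.5
        assert abs(d.achieved_sd - sd) <= 0.5
        assert abs(d.achieved_frac_low - frac_low) <= 0.003
        assert abs(d.achieved_frac_high - frac_high) <= 0.003

    def test_calibration_roundtrip_analytic(self, dist10):
        # Recomputing moments/fractions from the returned parameters must
        # reproduce the achieved_* fields.
        assert dist10.mean() == pytest.approx(dist10.achieved_mean, abs=1e-9)
        assert dist10.sd() == pytest.approx(dist10.achieved_sd, abs=1e-9)
        assert dist10.frac_low() == pytest.approx(dist10.achieved_frac_low, abs=1e-12)
        assert dist10.frac_high() == pytest.approx(dist10.achieved_frac_high, abs=1e-12)

    def test_numerical_integration_roundtrip(self, dist10):
        # Independent oracle: integrate the mixture density numerically.
        mu, sig = dist10.bulk_mean, dist10.bulk_sd
        w, s = dist10.tail_weight, dist10.tail_scale
        def pdf(x):
            tail = np.exp(-(x - mu) / s) / s if x >= mu else 0.0
            return (1 - w) * stats.norm.pdf(x, mu, sig) + w * tail

        # Split at the density kink (the tail's support starts at mu) so
        # adaptive quadrature only ever sees smooth integrands.
        def integrate(f, lo, hi):
            total = 0.0
            for a, b in [(lo, min(mu, hi)), (max(mu, lo), hi)]:
                if a < b:
                    total += quad(lambda x: f(x) * pdf(x), a, b, limit=200)[0]
            return total

        lo, hi = mu - 12 * sig, mu + 80 * s
        m = integrate(lambda x: x, lo, hi)
        sd = np.sqrt(integrate(lambda x: (x - m) ** 2, lo, hi))
        fl = integrate(lambda x: 1.0, lo, m - sd)
        fh = integrate(lambda x: 1.0, m + sd, hi)
        assert m == pytest.approx(dist10.achieved_mean, abs=1e-3)
        assert sd == pytest.approx(dist10.achieved_sd, abs=1e-3)
        assert fl == pytest.approx(dist10.achieved_frac_low, abs=1e-4)
        assert fh == pytest.approx(dist10.achieved_frac_high, abs=1e-4)

    def test_gaussian_limit_symmetric_targets(self):
        d = calibrate_distribution(-800.0, 100.0, GAUSSIAN_TAIL, GAUSSIAN_TAIL)
        assert d.tail_weight == pytest.approx(0.0, abs=1e-6)
        assert d.achieved_frac_low == pytest.approx(GAUSSIAN_TAIL, abs=1e-3)
        assert d.achieved_frac_high == pytest.approx(GAUSSIAN_TAIL, abs=1e-3)
        # Collapses to the pure normal: moments are the targets exactly.
        assert d.bulk_mean == -800.0 and d.bulk_sd == 100.0

    def test_sampling_oracle(self, dist10, rng):
        # Brute-force sampling oracle, independent of the class's sampler:
        # draw the mixture directly and compare empirical statistics with
        # achieved_* within 3 Monte-Carlo standard errors.
        n = 1_000_000
        in_tail = rng.random(n) < dist10.tail_weight
        x = np.where(
            in_tail,
            dist10.bulk_mean + rng.exponential(dist10.tail_scale, n),
            rng.normal(dist10.bulk_mean, dist10.bulk_sd, n),
        )
        se_mean = dist10.achieved_sd / np.sqrt(n)
        assert abs(x.mean() - dist10.achieved_mean) <= 3 * se_mean
        # SE of the SD estimate ~ sd * sqrt((kurtosis-1)/(4n)); bound with a
        # generous factor instead of estimating kurtosis.
        assert abs(x.std() - dist10.achieved_sd) <= 10 * se_mean
        lo = dist10.achieved_mean - dist10.achieved_sd
        hi = dist10.achieved_mean + dist10.achieved_sd
        for frac, target in [
            ((x < lo).mean(), dist10.achieved_frac_low),
            ((x > hi).mean(), dist10.achieved_frac_high),
        ]:
            se = np.sqrt(target * (1 - target) / n)
            assert abs(frac - target) <= 3 * se

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(target_mean=-800, target_sd=-1, target_frac_low=0.01, target_frac_high=0.1),
            dict(target_mean=-800, target_sd=100, target_frac_low=0.1, target_frac_high=0.01),
            dict(target_mean=-800, target_sd=100, target_frac_low=0.0, target_frac_high=0.1),
            dict(target_mean=-800, target_sd=100, target_frac_low=0.1, target_frac_high=0.6),
        ],
    )
    def test_invalid_targets_raise(self, kwargs):
        with pytest.raises(ValueError):
            calibrate_distribution(**kwargs)

    def test_infeasible_targets_raise_calibration_error(self):
        # Both tails far heavier than any normal+right-tail mixture allows.
        with pytest.raises(CalibrationError, match="calibration infeasible"):
            calibrate_distribution(-800.0, 100.0, 0.30, 0.45)

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            ParenchymaDistribution(
                bulk_mean=-800, bulk_sd=50, tail_weight=0.7, tail_scale=100,
                achieved_mean=-800, achieved_sd=50,
                achieved_frac_low=0.01, achieved_frac_high=0.1,
            )


class TestPhantom:
    def test_ground_truth_volume_is_count_times_voxel_volume(self, default_phantom):
        volume, mask, gt_mL = default_phantom
        assert gt_mL == pytest.approx(mask.sum() * volume.voxel_volume_mm3 / 1000.0)

    def test_determinism(self, dist10):
        spec = default_phantom_spec(distribution=dist10)
        v1, m1, g1 = generate_phantom(spec, seed=11)
        v2, m2, g2 = generate_phantom(spec, seed=11)
        assert np.array_equal(v1.voxels, v2.voxels)
        assert np.array_equal(m1, m2)
        assert g1 == g2

    def test_different_seeds_differ(self, dist10):
        spec = default_phantom_spec(distribution=dist10)
        v1, _, _ = generate_phantom(spec, seed=11)
        v2, _, _ = generate_phantom(spec, seed=12)
        assert not np.array_equal(v1.voxels, v2.voxels)

    def test_structure_hu_assignment(self, default_phantom):
        volume, mask, _ = default_phantom
        spec_body = default_phantom_spec().body_mask()
        outside = ~spec_body
        assert np.all(volume.voxels[outside] == -1000)
        body_only = spec_body & ~mask
        assert np.all(volume.voxels[body_only] == 40)

    def test_large_phantom_mean_within_1_hu(self, dist10):
        # >= 5e5 lung voxels: sampled HU mean must sit within 1 HU of the
        # calibration target.
        spec = PhantomSpec(
            grid_shape=(128, 128, 128),
            spacing=(2.0, 2.0, 2.0),
            lung_ellipsoids=(((63.5, 63.5, 63.5), (60.0, 45.0, 45.0)),),
            distribution=dist10,
        )
        volume, mask, _ = generate_phantom(spec, seed=5)
        assert mask.sum() >= 500_000
        assert volume.voxels[mask].mean() == pytest.approx(-803.0, abs=1.0)

    def test_lung_outside_body_raises(self, dist10):
        spec = PhantomSpec(
            grid_shape=(48, 48, 48),
            lung_ellipsoids=(((24.0, 24.0, 2.0), (10.0, 10.0, 6.0)),),
            distribution=dist10,
        )
        with pytest.raises(ValueError, match="strictly inside the body"):
            generate_phantom(spec, seed=0)

    def test_pocket_intersecting_lung_raises(self, dist10):
        spec = default_phantom_spec(
            distribution=dist10,
            extra_air_pockets=(((47.5, 47.5, 30.0), (5.0, 5.0, 5.0)),),
        )
        with pytest.raises(ValueError, match="must not intersect"):
            generate_phantom(spec, seed=0)

    @pytest.mark.parametrize("bad", [dict(grid_shape=(4, 96, 96)), dict(spacing=(0, 2, 2))])
    def test_invalid_spec_raises(self, dist10, bad):
        with pytest.raises(ValueError):
            dataclasses.replace(default_phantom_spec(distribution=dist10), **bad)


class TestCohort:
    def test_noise_free_points_on_reference_curves(self):
        spec = CohortSpec(n_subjects=12, seed=1, age_min=6, age_max=17)
        for r in generate_cohort(spec):
            age = r.age_years
            assert r.tlc_ct_mL == pytest.approx(-541.7 + 319.7 * age, abs=1e-6)
            assert r.mean_hu == pytest.approx(-892.8 + 1160.4 / age, abs=1e-6)
            assert r.lat_hu == pytest.approx(-1018.5 + 1034.1 / age, abs=1e-6)
            assert r.hat_hu == pytest.approx(-767.2 + 1286.7 / age, abs=1e-6)
            assert r.pct_high == pytest.approx(8.147 + 26.931 / age, abs=1e-6)
            assert r.pct_low == pytest.approx(-0.561 + 5876.6 / r.tlc_ct_mL, abs=1e-6)

    def test_age6_noise_free_mean_attenuation(self):
        spec = CohortSpec(n_subjects=4, seed=2, age_min=6, age_max=6)
        recs = generate_cohort(spec)
        assert all(r.mean_hu == pytest.approx(-699.4, abs=1e-9) for r in recs)

    def test_identical_records_at_fixed_age_no_noise(self):
        spec = CohortSpec(n_subjects=2, seed=3, age_min=10, age_max=10)
        a, b = generate_cohort(spec)
        assert (a.age_years, a.tlc_ct_mL, a.mean_hu, a.pct_low, a.pct_high) == (
            b.age_years, b.tlc_ct_mL, b.mean_hu, b.pct_low, b.pct_high
        )

    def test_reproducible_given_seed(self):
        spec = CohortSpec(
            n_subjects=20, seed=42, noise_sd_attenuation=15.0,
            noise_sd_tlc=300.0, noise_sd_pct=0.5,
        )
        r1 = generate_cohort(spec)
        r2 = generate_cohort(spec)
        assert r1 == r2

    def test_ages_within_bounds(self):
        spec = CohortSpec(n_subjects=50, seed=9, age_min=8, age_max=12)
        ages = {r.age_years for r in generate_cohort(spec)}
        assert ages <= set(range(8, 13))

    def test_unknown_reference_set_raises(self):
        spec = CohortSpec(n_subjects=5, seed=1, reference_set="nope")
        with pytest.raises(KeyError):
            generate_cohort(spec)

    @pytest.mark.parametrize(
        "bad", [dict(n_subjects=1), dict(age_min=5), dict(age_min=12, age_max=8)]
    )
    def test_invalid_spec_raises(self, bad):
        kwargs = dict(n_subjects=10, seed=0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            CohortSpec(**kwargs)

    def test_threshold_ordering_held_under_noise(self):
        spec = CohortSpec(
            n_subjects=200, seed=17, noise_sd_attenuation=20.0, noise_sd_tlc=300.0
        )
        for r in generate_cohort(spec):
            assert r.lat_hu <= r.mean_hu <= r.hat_hu
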