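"""Generator contracts: determinism, configured marginals, dosing policy,
measurement process, and the kernel integral."""

import numpy as np
import pandas as pd
import pytest

from feverpghd.io_model import ACE, DEX, IBU
from feverpghd.synthetic_cohort import (
    DrugKernel,
    SimulationConfig,
    generate_cohort,
    kernel_integral,
    null_config,
    simulate_children,
    simulate_fever_course,
    simulate_measurements,
    weight_from_age,
)


class TestConfig:
    def test_invalid_probability_rejected(self):
        cfg = SimulationConfig(sex_male_prob=1.4)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError):
            DrugKernel(lag_h=3.0, nadir_h=2.0)

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "n_children: 7\nseed: 3\n"
            "drug_effect:\n  ACE: {nadir_drop_c: 0.5}\n"
            "  IBU: {nadir_drop_c: 0.5}\n  DEX: {nadir_drop_c: 0.5}\n",
            encoding="utf-8")
        cfg = SimulationConfig.from_yaml(p)
        assert cfg.n_children == 7
        assert cfg.drug_effect[ACE].nadir_drop_c == 0.5


class TestChildren:
    def test_single_child_is_deterministic(self):
        a = simulate_children(SimulationConfig(n_children=1),
                              np.random.default_rng(5))
        b = simulate_children(SimulationConfig(n_children=1),
                              np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 1

    def test_demographic_marginals_at_scale(self):
        cfg = SimulationConfig(n_children=10_000, seed=1)
        ch = simulate_children(cfg, np.random.default_rng(cfg.seed))
        male = (ch["sex"] == "male").mean()
        assert 0.49 <= male <= 0.52
        # configured target: mean 835.35 d, SD 529.80 d
        se = 529.80 / np.sqrt(len(ch))
        assert abs(ch["age_days"].mean() - 835.35) < 3 * se
        assert ch["age_days"].between(0, 7000).all()
        assert ch["weight_kg"].between(2, 50).all()

    def test_weight_map_is_monotone(self):
        ages = np.linspace(0, 7000, 200)
        w = weight_from_age(ages)
        assert np.all(np.diff(w) > 0)


class TestFeverCourse:
    def _course(self, seed=0, **cfg_kwargs):
        cfg = SimulationConfig(n_children=1, **cfg_kwargs)
        return simulate_fever_course("X", cfg, np.random.default_rng(seed)), cfg

    def test_zero_drop_kernels_leave_course_untreated(self):
        kern = {k: DrugKernel(nadir_drop_c=0.0) for k in (ACE, IBU, DEX)}
        course, _ = self._course(seed=2, drug_effect=kern)
        t = np.linspace(0, 96, 500)
        assert np.allclose(course.latent(t),
                           np.maximum(course.untreated(t), course.floor_c))

    def test_single_policy_uses_one_ingredient(self):
        for seed in range(30):
            course, _ = self._course(seed=seed)
            if course.policy == "single" and len(course.dose_times_h) > 1:
                assert len(set(course.dose_ingredients)) == 1
                gaps = np.diff(course.dose_times_h)
                assert np.all(gaps >= 4.0 - 1e-9)

    def test_combination_policy_alternates_at_4_to_6_hours(self):
        seen = 0
        for seed in range(120):
            course, _ = self._course(seed=seed)
            if course.policy == "combination" and len(course.dose_times_h) > 1:
                seen += 1
                ings = course.dose_ingredients
                assert any(a != b for a, b in zip(ings, ings[1:]))
                gaps = np.diff(course.dose_times_h)
                assert np.all(gaps >= 4.0 - 1e-9)
                # the scheduled alternating follow-up lands within the
                # configured interval (up to grid rounding)
                assert gaps[0] <= 6.0 + 0.1
        assert seen >= 5

    def test_doses_only_fire_at_or_above_threshold_modulo_delay(self):
        course, cfg = self._course(seed=11)
        for td in course.dose_times_h[:1]:
            # at the triggering crossing (dose time minus delay <= cap) the
            # latent course must have reached the caregiver threshold
            window = np.arange(max(td - cfg.dose_delay_cap_h, 0.0), td + 1e-9,
                               cfg.step_h)
            assert course.latent(window).max() >= course.threshold_c - 1e-6


class TestMeasurements:
    def test_noise_free_samples_lie_on_latent_curve(self):
        cfg = SimulationConfig(n_children=1, measurement_noise_sd_c=0.0)
        rng = np.random.default_rng(4)
        course = simulate_fever_course("X", cfg, rng)
        times, temps = simulate_measurements(course, cfg, rng)
        assert len(times) > 0
        assert np.allclose(temps, np.round(course.latent(times), 1),
                           atol=0.051)

    def test_observations_are_tenth_degree_multiples(self):
        cfg = SimulationConfig(n_children=1)
        rng = np.random.default_rng(4)
        course = simulate_fever_course("X", cfg, rng)
        _, temps = simulate_measurements(course, cfg, rng)
        assert np.allclose(np.round(temps * 10) / 10, temps, atol=1e-9)

    def test_febrile_segments_sampled_more_densely(self):
        cfg = SimulationConfig(n_children=1)
        rng = np.random.default_rng(0)
        counts = {"hot": 0, "cool": 0}
        for _ in range(300):
            course = simulate_fever_course("X", cfg, rng)
            times, _ = simulate_measurements(course, cfg, rng)
            if not len(times):
                continue
            latent = course.latent(times)
            hot_span = (course.latent(
                np.arange(0, cfg.sim_window_h, 0.25)) >= 38.5).mean()
            if hot_span in (0.0, 1.0):
                continue
            counts["hot"] += int((latent >= 38.5).sum())
            counts["cool"] += int((latent < 38.5).sum())
        # febrile time is a small fraction of the window yet collects a
        # disproportionate share of readings
        assert counts["hot"] > 0.1 * counts["cool"]


class TestGenerateCohort:
    def test_same_seed_is_byte_identical(self):
        cfg = SimulationConfig(n_children=40, seed=9)
        c1, g1 = generate_cohort(cfg)
        c2, g2 = generate_cohort(SimulationConfig(n_children=40, seed=9))
        pd.testing.assert_frame_equal(c1.temperatures, c2.temperatures)
        pd.testing.assert_frame_equal(c1.antipyretics, c2.antipyretics)
        pd.testing.assert_frame_equal(g1, g2)

    def test_zero_combination_probability_gives_all_single(self):
        cfg = SimulationConfig(
            n_children=150, seed=3,
            combination_prob_by_band={k: 0.0 for k in
                                      ("<37", "[37,38)", "[38,39)",
                                       "[39,40)", ">=40")})
        _, gt = generate_cohort(cfg)
        assert len(gt) and (gt["true_group"] == "single").all()

    def test_exchangeable_null_config_balances_groups(self):
        cfg = null_config(300, seed=5)
        _, gt = generate_cohort(cfg)
        share = (gt[gt.case_index == 0]["policy"] == "combination").mean()
        assert 0.35 < share < 0.65

    def test_underthreshold_dosing_share_matches_configuration(self):
        cfg = SimulationConfig(n_children=3000, seed=21)
        _, gt = generate_cohort(cfg)
        first = gt[gt.case_index == 0]
        share = (first["true_baseline_c"] < 38.0).mean()
        assert abs(share - cfg.underthreshold_dosing_prob) < 0.02

    def test_combination_gradient_matches_configuration(self):
        cfg = SimulationConfig(n_children=3000, seed=22)
        _, gt = generate_cohort(cfg)
        first = gt[gt.case_index == 0]
        shares = {}
        for band, grp in first.groupby("true_band"):
            p = cfg.combination_prob_by_band[band]
            share = (grp["policy"] == "combination").mean()
            n = len(grp)
            # binomial 4-sigma envelope, floored at 2 percentage points
            tol = max(0.02, 4 * np.sqrt(p * (1 - p) / n))
            assert abs(share - p) < tol, (band, share, p, n)
            shares[band] = share
        ordered = [b for b in ("[38,39)", "[39,40)") if b in shares]
        assert shares[ordered[0]] < shares[ordered[-1]]


class TestKernelIntegral:
    @pytest.mark.parametrize("horizon", [0.5, 1.0, 1.7, 2.0, 3.5, 6.0, 9.0])
    def test_closed_form_matches_fine_quadrature(self, horizon):
        kern = DrugKernel(lag_h=1.0, nadir_h=2.0, nadir_drop_c=1.3,
                          duration_h=6.0)
        t = np.linspace(0, horizon, 200_001)
        numeric = np.trapezoid(kern(t), t)
        assert kernel_integral(kern, horizon) == pytest.approx(
            numeric, abs=1e-6)

    def test_full_support_area_is_triangle(self):
        kern = DrugKernel(lag_h=1.0, nadir_h=2.0, nadir_drop_c=2.0,
                          duration_h=6.0)
        assert kernel_integral(kern, 100.0) == pytest.approx(
            -0.5 * 2.0 * (6.0 - 1.0))
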