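import numpy as np
import pytest

from ergocal.calorimetry import analyze_bmr
from ergocal.graded import GradedResult, analyze_graded, detect_vo2peak
from ergocal.prescription import design_comb_session, design_mict_session
from ergocal.session import summarize_session
from ergocal.synthetic import (
    PRESETS,
    NoiseModel,
    fat_curve,
    make_subject,
    simulate_bmr_recording,
    simulate_cohort,
    simulate_graded_test,
    simulate_submax_session,
)


class TestFatCurve:
    def test_landmarks(self):
        assert fat_curve(50.0, 0.32, 50.0, 74.0) == pytest.approx(0.32)
        assert fat_curve(74.0, 0.32, 50.0, 74.0) == 0.0
        assert fat_curve(0.0, 0.32, 50.0, 74.0) == 0.0
        assert fat_curve(90.0, 0.32, 50.0, 74.0) == 0.0

    def test_unimodal_with_peak_at_fatmax(self):
        grid = np.linspace(1.0, 73.9, 500)
        vals = fat_curve(grid, 0.41, 46.0, 74.0)
        assert np.max(vals) <= 0.41 + 1e-12
        assert grid[np.argmax(vals)] == pytest.approx(46.0, abs=0.2)


class TestMakeSubject:
    def test_same_seed_gives_identical_subject(self):
        a = make_subject(PRESETS["COMB_W0"], seed=42)
        b = make_subject(PRESETS["COMB_W0"], seed=42)
        assert a == b

    def test_zero_sd_preset_returns_exact_means(self):
        s = make_subject(PRESETS["MICT_W0"].zero_noise(), seed=0)
        assert (s.body_mass, s.ffm, s.bmr) == (111.5, 69.2, 8.66)
        assert (s.true_vo2peak, s.true_mfo, s.true_fatmax) == (3.60, 0.41, 46.0)

    def test_population_mean_recovered_over_many_draws(self):
        rng = np.random.default_rng(1)
        bms = np.array([make_subject(PRESETS["COMB_W0"], seed=rng).body_mass
                        for _ in range(10000)])
        se = bms.std(ddof=1) / 100.0
        assert abs(bms.mean() - 117.7) <= 2 * se + 1e-9

    def test_invariants_hold_under_extreme_draws(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            s = make_subject(PRESETS["COMB_W0"], seed=rng)
            assert 0 < s.ffm <= s.body_mass
            assert s.true_fatmax < s.true_crossover <= 100.0


class TestBmrRecording:
    def test_noiseless_round_trip_to_1e6(self, comb_subject, noiseless):
        rec = simulate_bmr_recording(comb_subject, noiseless, seed=0)
        assert analyze_bmr(rec, discard_s=600.0).bmr_mj_day == pytest.approx(
            comb_subject.bmr, abs=1e-6
        )

    def test_skipping_the_discard_biases_high(self, comb_subject, noiseless):
        rec = simulate_bmr_recording(comb_subject, noiseless, seed=0)
        assert analyze_bmr(rec, discard_s=0.0).bmr_mj_day > comb_subject.bmr

    def test_noisy_recovery_within_3pct_in_95pct_of_seeds(self, comb_subject):
        noise = NoiseModel()
        ok = 0
        for seed in range(200):
            rec = simulate_bmr_recording(comb_subject, noise, seed=seed)
            est = analyze_bmr(rec, discard_s=600.0).bmr_mj_day
            ok += abs(est - comb_subject.bmr) / comb_subject.bmr <= 0.03
        assert ok >= 190


class TestGradedTest:
    def test_noiseless_peak_round_trip(self, comb_subject, noiseless):
        g = simulate_graded_test(comb_subject, noiseless, seed=0)
        vo2peak, hrpeak = detect_vo2peak(g)
        assert vo2peak == pytest.approx(comb_subject.true_vo2peak, abs=1e-3)
        assert hrpeak == pytest.approx(comb_subject.hr_peak, abs=0.1)

    def test_noiseless_pipeline_recovers_curve_landmarks(self, comb_subject, noiseless):
        g = simulate_graded_test(comb_subject, noiseless, seed=0)
        res = analyze_graded(g, pox=comb_subject.resting_pox, subject=comb_subject)
        assert res.mfo.fatmax == pytest.approx(comb_subject.true_fatmax, abs=0.5)
        assert res.mfo.mfo == pytest.approx(comb_subject.true_mfo, abs=1e-3)
        assert res.crossover.intensity >= res.mfo.fatmax

    def test_hr_stop_truncates_the_protocol(self, noiseless):
        hot = make_subject(PRESETS["COMB_W0"].zero_noise(), seed=0)
        hot.hr_peak = 200.0  # crosses 180 bpm mid-protocol
        g = simulate_graded_test(hot, noiseless, seed=0)
        full = simulate_graded_test(make_subject(PRESETS["COMB_W0"].zero_noise(), seed=0),
                                    noiseless, seed=0)
        assert g.t[-1] < full.t[-1]
        assert g.hr[-1] >= 179.0

    def test_rer_never_exceeds_ceiling(self, comb_subject):
        g = simulate_graded_test(comb_subject, NoiseModel(), seed=3)
        mask = g.vo2 > 0
        assert np.all(g.vco2[mask] <= 1.1 * g.vo2[mask] + 1e-12)

    def test_same_seed_is_bit_reproducible(self, comb_subject):
        a = simulate_graded_test(comb_subject, NoiseModel(), seed=9)
        b = simulate_graded_test(comb_subject, NoiseModel(), seed=9)
        np.testing.assert_array_equal(a.vo2, b.vo2)
        np.testing.assert_array_equal(a.hr, b.hr)


class TestSubmaxSession:
    def test_noiseless_mict_session_meets_energy_budget(self, mict_subject, noiseless):
        result = GradedResult(vo2peak=mict_subject.true_vo2peak,
                              hrpeak=mict_subject.hr_peak, o2pulse=None)
        plan = design_mict_session(result, mict_subject.ffm, intensity=40.0)
        sess = simulate_submax_session(mict_subject, plan, noiseless, seed=0)
        summ = summarize_session(sess, subject=mict_subject)
        assert summ.total_ee == pytest.approx(plan.energy_target, rel=0.02)

    def test_same_seed_is_bit_reproducible(self, mict_subject):
        result = GradedResult(vo2peak=mict_subject.true_vo2peak,
                              hrpeak=mict_subject.hr_peak, o2pulse=None)
        plan = design_mict_session(result, mict_subject.ffm)
        a = simulate_submax_session(mict_subject, plan, NoiseModel(), seed=5)
        b = simulate_submax_session(mict_subject, plan, NoiseModel(), seed=5)
        np.testing.assert_array_equal(a.vco2, b.vco2)

    @pytest.mark.parametrize("preset_name, mode", [("MICT_W0", "mict"), ("COMB_W0", "comb")])
    def test_mean_session_grams_land_on_calibration_cells(self, preset_name, mode):
        """Over 200 seeded sessions the mean substrate grams fall within
        2 printed SDs of the group's session table cells."""
        preset = PRESETS[preset_name]
        noise = NoiseModel()
        rng = np.random.default_rng(7)
        grams = {"fat": [], "cho": [], "protein": []}
        for _ in range(200):
            subj = make_subject(preset, seed=rng)
            result = GradedResult(vo2peak=subj.true_vo2peak, hrpeak=subj.hr_peak, o2pulse=None)
            try:
                plan = (design_mict_session(result, subj.ffm, intensity=40.0)
                        if mode == "mict" else design_comb_session(result, subj.ffm))
            except Exception:
                continue  # rare infeasible tail draw
            sess = simulate_submax_session(subj, plan, noise, seed=rng)
            summ = summarize_session(sess, subject=subj)
            for k in grams:
                grams[k].append(summ.grams_by_substrate[k])
        targets = preset.session_targets
        for key, cell in (("fat", targets["fat_g"]), ("cho", targets["cho_g"]),
                          ("protein", targets["protein_g"])):
            mean = np.mean(grams[key])
            assert abs(mean - cell.mean) <= 2 * cell.sd, (key, mean, cell)


class TestCohort:
    def test_change_scores_match_preset_implied_deltas(self):
        bundle = simulate_cohort(1000, seed=3)
        w = bundle.table.wide("VO2peak")
        d = (w.loc[w.group == "COMB", "W3"] - w.loc[w.group == "COMB", "W0"]).to_numpy()
        implied = PRESETS["COMB_W3"].vo2peak.mean - PRESETS["COMB_W0"].vo2peak.mean
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean() - implied) <= 2 * se
        # the preset-implied change matches the reported mean gain to rounding
        assert implied == pytest.approx(0.28, abs=0.015)

    def test_interaction_power_at_trial_sample_size(self):
        """With the trial's n (10 vs 11) and the preset deltas, the
        oxygen-uptake interaction is detected in a majority of seeds."""
        from ergocal.stats import mixed_anova_2x2

        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            bundle = simulate_cohort({"COMB": 10, "MICT": 11}, seed=seed)
            res = mixed_anova_2x2(bundle.table, "VO2peak")
            hits += res.effects["GxT"].p < 0.05
        assert hits > n_seeds / 2

    def test_null_presets_reject_at_alpha(self):
        """Zero-delta generation keeps the interaction's type-I error near 5%."""
        from dataclasses import replace
        from ergocal.stats import mixed_anova_2x2

        null_presets = dict(PRESETS)
        for g in ("COMB", "MICT"):
            null_presets[f"{g}_W3"] = replace(
                PRESETS[f"{g}_W0"], name=f"{g}_W3", timepoint="W3"
            )
        rej = 0
        n_rep = 200
        for seed in range(n_rep):
            bundle = simulate_cohort(20, presets=null_presets, seed=10_000 + seed)
            res = mixed_anova_2x2(bundle.table, "VO2peak")
            rej += res.effects["GxT"].p < 0.05
        assert 0.01 <= rej / n_rep <= 0.10

    def test_cohort_is_reproducible(self):
        a = simulate_cohort(5, seed=8).table.data
        b = simulate_cohort(5, seed=8).table.data
        import pandas as pd

        pd.testing.assert_frame_equal(a, b)
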