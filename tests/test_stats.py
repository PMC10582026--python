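import numpy as np
import pandas as pd
import pytest

from ergocal.errors import DataError, DomainError
from ergocal.stats import (
    build_table1,
    check_normality,
    greenhouse_geisser_epsilon,
    hedges_g,
    mixed_anova_2x2,
)
from ergocal.types import TrialTable


def table_from_arrays(y_by_group, outcome="y", unit="au"):
    rows = []
    for g, y in y_by_group.items():
        for i, pair in enumerate(np.asarray(y)):
            for tp, val in zip(("W0", "W3"), pair):
                rows.append(
                    {"subject_id": f"{g}{i}", "group": g, "timepoint": tp, outcome: val}
                )
    return TrialTable(pd.DataFrame(rows), units={outcome: unit})


def anova_oracle(y, glab):
    """Brute-force mixed-design F statistics via explicit design matrices.

    Between level: regression of subject means on group dummies.  Within
    level: long regression with subject dummies, a time dummy and the
    group x time interaction, F from sums-of-squared-residual differences.
    Valid for balanced or unbalanced two-group, two-timepoint data.
    """
    y = np.asarray(y, float)
    n, k = y.shape
    groups = sorted(set(glab))
    a = len(groups)
    gcode = np.array([groups.index(g) for g in glab])

    def sse(X, yy):
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        r = yy - X @ beta
        return float(r @ r)

    m = y.mean(axis=1)
    ones = np.ones((n, 1))
    Xg = np.column_stack([(gcode == j).astype(float) for j in range(a)])
    ss_g = k * (sse(ones, m) - sse(Xg, m))
    ss_err_b = k * sse(Xg, m)
    F_G = (ss_g / (a - 1)) / (ss_err_b / (n - a))

    yl = y.reshape(-1)
    subj = np.kron(np.eye(n), np.ones((k, 1)))
    tdum = np.tile(np.arange(k) == 1, n).astype(float)[:, None]
    gt = (np.repeat(gcode, k) == 1).astype(float)[:, None] * tdum
    X_s = subj
    X_st = np.hstack([subj, tdum])
    X_full = np.hstack([subj, tdum, gt])
    sse_full = sse(X_full, yl)
    df_err_w = (n - a) * (k - 1)
    ms_err = sse_full / df_err_w
    F_T = ((sse(X_s, yl) - sse(X_st, yl)) / (k - 1)) / ms_err
    F_GT = ((sse(X_st, yl) - sse_full) / ((a - 1) * (k - 1))) / ms_err
    return F_G, F_T, F_GT


class TestNormality:
    def test_gaussian_samples_rarely_rejected(self):
        rng = np.random.default_rng(11)
        passes = sum(check_normality(rng.normal(0, 1, 50))[1] > 0.05 for _ in range(100))
        assert passes >= 90

    def test_heavy_skew_usually_rejected(self):
        rng = np.random.default_rng(12)
        rejects = sum(
            check_normality(rng.lognormal(0, 1, 50))[1] < 0.05 for _ in range(100)
        )
        assert rejects >= 90

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DomainError):
            check_normality([1.0, 2.0])
        with pytest.raises(DataError):
            check_normality([3.0, 3.0, 3.0, 3.0])


class TestMixedAnova:
    def test_agrees_with_design_matrix_oracle(self):
        rng = np.random.default_rng(100)
        for rep in range(50):
            na = int(rng.integers(4, 9))
            ya = rng.normal(0, 1, (na, 2)) + rng.normal(0, 1, (na, 1))
            yb = rng.normal(rng.uniform(-1, 1), 1, (na, 2)) + rng.normal(0, 1, (na, 1))
            yb[:, 1] += rng.uniform(-1, 1)
            t = table_from_arrays({"COMB": ya, "MICT": yb})
            res = mixed_anova_2x2(t, "y")
            F_G, F_T, F_GT = anova_oracle(
                np.vstack([ya, yb]), ["COMB"] * na + ["MICT"] * na
            )
            assert res.effects["G"].F == pytest.approx(F_G, abs=1e-8)
            assert res.effects["T"].F == pytest.approx(F_T, abs=1e-8)
            assert res.effects["GxT"].F == pytest.approx(F_GT, abs=1e-8)

    def test_agrees_with_pingouin_including_unbalanced(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        for na, nb in [(8, 8), (10, 11)]:
            ya = rng.normal(0, 1, (na, 2))
            yb = rng.normal(0.5, 1, (nb, 2))
            yb[:, 1] += 0.7
            t = table_from_arrays({"COMB": ya, "MICT": yb})
            res = mixed_anova_2x2(t, "y")
            df = t.data.rename(columns={"y": "dv"})
            ref = pg.mixed_anova(
                data=df, dv="dv", within="timepoint", between="group", subject="subject_id"
            ).set_index("Source")
            assert res.effects["G"].F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
            assert res.effects["T"].F == pytest.approx(ref.loc["timepoint", "F"], rel=1e-9)
            assert res.effects["GxT"].F == pytest.approx(ref.loc["Interaction", "F"], rel=1e-9)

    def test_pure_time_shift_detected_as_time_effect_only(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, (400, 1))
        noise = rng.normal(0, 0.2, (400, 2))
        y = base + noise
        y[:, 1] += 1.0
        t = table_from_arrays({"COMB": y[:200], "MICT": y[200:]})
        res = mixed_anova_2x2(t, "y")
        assert res.effects["T"].p < 1e-6
        assert res.effects["G"].p > 0.01
        assert res.effects["GxT"].p > 0.01

    def test_crossed_cells_detected_as_interaction_only(self):
        rng = np.random.default_rng(3)
        na = 300
        ya = rng.normal(0, 0.3, (na, 2)) + np.array([[-0.5, 0.5]])
        yb = rng.normal(0, 0.3, (na, 2)) + np.array([[0.5, -0.5]])
        t = table_from_arrays({"COMB": ya, "MICT": yb})
        res = mixed_anova_2x2(t, "y")
        assert res.effects["GxT"].p < 1e-6
        assert res.effects["G"].p > 0.01
        assert res.effects["T"].p > 0.01
        assert len(res.posthoc) == 4
        assert all(p.p_adj >= p.p_raw for p in res.posthoc)

    def test_epsilon_is_exactly_one_for_two_timepoints(self):
        rng = np.random.default_rng(4)
        t = table_from_arrays({"COMB": rng.normal(0, 1, (6, 2)), "MICT": rng.normal(0, 1, (6, 2))})
        res = mixed_anova_2x2(t, "y")
        assert res.effects["T"].epsilon == 1.0

    def test_subject_missing_a_timepoint_is_excluded(self, caplog):
        t = table_from_arrays({"COMB": np.random.default_rng(0).normal(0, 1, (5, 2)),
                               "MICT": np.random.default_rng(1).normal(0, 1, (5, 2))})
        t.data = t.data.drop(index=1)  # drop COMB0's W3 row
        with caplog.at_level("WARNING"):
            res = mixed_anova_2x2(t, "y")
        assert res.n_per_group == {"COMB": 4, "MICT": 5}

    def test_tiny_groups_rejected(self):
        t = table_from_arrays({"COMB": [[1.0, 2.0]], "MICT": [[1.0, 2.0], [2.0, 1.0]]})
        with pytest.raises(DataError):
            mixed_anova_2x2(t, "y")


class TestGreenhouseGeisser:
    def test_generic_epsilon_bounds_for_three_levels(self):
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, (30, 3))
        y[:, 2] *= 4.0  # break sphericity
        eps = greenhouse_geisser_epsilon(y)
        assert 0.5 <= eps < 1.0
        spherical = rng.normal(0, 1, (2000, 3))
        assert greenhouse_geisser_epsilon(spherical) > 0.95


class TestHedgesG:
    def test_identical_samples_are_a_null_effect(self):
        es = hedges_g([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert es.g == 0.0 and es.label == "small"

    def test_small_sample_correction_closed_form(self):
        a = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        b = a - np.sqrt(a.var(ddof=1))  # raw d exactly 1
        es = hedges_g(a, b)
        assert es.g == pytest.approx(1.0 - 3.0 / 31.0, abs=1e-12)

    def test_large_sample_recovers_true_effect_with_large_label(self):
        rng = np.random.default_rng(21)
        a = rng.normal(0.7, 1.0, 10000)
        b = rng.normal(0.0, 1.0, 10000)
        es = hedges_g(a, b)
        assert es.g == pytest.approx(0.70, abs=0.04)
        assert es.label == "large"

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(22)
        a, b = rng.normal(0, 1, 30), rng.normal(0.4, 1.2, 25)
        assert hedges_g(a, b).g == pytest.approx(-hedges_g(b, a).g, abs=1e-12)

    def test_zero_pooled_sd_flagged_undefined(self):
        es = hedges_g([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])
        assert not es.defined and es.g is None

    @pytest.mark.parametrize("g_val, label", [(0.1, "small"), (0.35, "medium"), (0.8, "large")])
    def test_threshold_labels(self, g_val, label):
        # construct two samples with a known standardized difference
        rng = np.random.default_rng(23)
        a = rng.normal(g_val, 1.0, 200000)
        b = rng.normal(0.0, 1.0, 200000)
        assert hedges_g(a, b).label == label


class TestBuildTable1:
    def test_two_subject_mean_sd_by_hand(self):
        t = table_from_arrays({"COMB": [[1.0, 2.0], [3.0, 4.0]],
                               "MICT": [[5.0, 6.0], [7.0, 8.0]]}, outcome="BM", unit="kg")
        out = build_table1(t, decimals=2)
        assert out.loc["BM", "COMB W0"] == "2.00 ± 1.41"
        assert out.loc["BM", "MICT W3"] == "7.00 ± 1.41"
        assert {"P(G)", "P(T)", "P(GxT)"} <= set(out.columns)

    def test_simulated_cohort_means_near_preset_targets(self):
        from ergocal.synthetic import simulate_cohort

        bundle = simulate_cohort(1000, seed=17)
        data = bundle.table.data
        sel = (data["group"] == "COMB") & (data["timepoint"] == "W0")
        bm = data.loc[sel, "BM"]
        se = bm.std(ddof=1) / np.sqrt(len(bm))
        assert abs(bm.mean() - 117.7) <= 2 * se + 1e-9

    def test_single_group_cohort_rejected_naming_missing_group(self):
        t = table_from_arrays({"COMB": [[1.0, 2.0], [3.0, 4.0]]})
        with pytest.raises(DataError, match="MICT"):
            build_table1(t)
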