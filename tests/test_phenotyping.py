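"""Bioassay phenotyping: averaging rules, GLM/Cox fits and label decision rules."""

import math

import numpy as np
import pandas as pd
import pytest

from trichoselect.phenotyping import (
    MissingDataError,
    classify_thrips,
    classify_whitefly,
    fit_cox,
    fit_whitefly_glm,
    kaplan_meier,
    mean_survival,
    phenotype_thrips,
)
from trichoselect.simulate import SimConfig, simulate_thrips_assay
from conftest import exponential_cox_oracle


def wf_records(rows):
    return pd.DataFrame(
        rows, columns=["accession", "plant_id", "cage_id", "n_alive", "n_dead"]
    )


class TestMeanSurvival:
    def test_cage_then_plant_averaging_order(self):
        rec = wf_records([("A", "P1", "C1", 10, 5), ("A", "P1", "C2", 12, 3)])
        out = mean_survival(rec)
        assert out.loc["A", "mean_survival"] == pytest.approx((10 / 15 + 12 / 15) / 2)

    def test_all_dead_gives_zero(self):
        rec = wf_records([("A", "P1", "C1", 0, 15), ("A", "P2", "C1", 0, 15)])
        assert mean_survival(rec).loc["A", "mean_survival"] == 0.0

    def test_accession_mean_and_se_across_plants(self):
        rec = wf_records([("A", "P1", "C1", 2, 8), ("A", "P2", "C1", 6, 4)])
        out = mean_survival(rec)
        assert out.loc["A", "mean_survival"] == pytest.approx(0.4)
        assert out.loc["A", "se"] == pytest.approx(0.2)

    def test_empty_input_raises(self):
        with pytest.raises(MissingDataError):
            mean_survival(wf_records([]))


class TestWhiteflyGLM:
    def test_two_group_coefficient_matches_logit_oracle(self, whitefly_two_group):
        res = fit_whitefly_glm(whitefly_two_group, "BASE")
        expected = math.log(0.2 / 0.8) - math.log(0.8 / 0.2)  # -2.7726
        assert res.loc["TEST", "coefficient"] == pytest.approx(expected, abs=1e-6)
        assert res.loc["BASE", "note"] == "baseline"

    def test_identical_counts_give_null_coefficients(self):
        rows = []
        for acc in ("A", "B", "C"):
            for p in (1, 2, 3):
                rows.append((acc, f"{acc}P{p}", f"{acc}C{p}", 10, 5))
        res = fit_whitefly_glm(wf_records(rows), "A")
        other = res.drop("A")
        assert np.allclose(other["coefficient"], 0, atol=1e-8)
        assert (other["p_value"] > 0.9).all()

    def test_zero_survival_accession_excluded_and_resistant(self):
        rows = [("BASE", "P1", "C1", 12, 3), ("BASE", "P2", "C1", 11, 4),
                ("DEAD", "P1", "C1", 0, 15), ("DEAD", "P2", "C1", 0, 15),
                ("MID", "P1", "C1", 8, 7), ("MID", "P2", "C1", 7, 8)]
        res = fit_whitefly_glm(wf_records(rows), "BASE")
        assert res.loc["DEAD", "note"] == "excluded from GLM: zero survival"
        assert np.isneginf(res.loc["DEAD", "coefficient"])
        labels = classify_whitefly(res).set_index("accession")
        assert labels.loc["DEAD", "class"] == "resistant"

    def test_missing_baseline_raises(self, whitefly_two_group):
        with pytest.raises(MissingDataError):
            fit_whitefly_glm(whitefly_two_group, "NOPE")

    def test_recovers_known_logit_differences_within_3_se(self):
        # simulated binomial survival with known probabilities
        from trichoselect.simulate import simulate_whitefly_assay

        cfg = SimConfig(
            n_accessions=6, n_resistant=2, plants_per_accession=30,
            survival_prob_resistant=0.3, survival_prob_susceptible=0.7, seed=17,
        )
        rec, truth = simulate_whitefly_assay(cfg)
        res = fit_whitefly_glm(rec, cfg.baseline_accession)
        logit = lambda p: math.log(p / (1 - p))
        base_p = truth.true_survival_prob[cfg.baseline_accession]
        for acc, p in truth.true_survival_prob.items():
            if acc == cfg.baseline_accession:
                continue
            true_coef = logit(p) - logit(base_p)
            r = res.loc[acc]
            assert abs(r["coefficient"] - true_coef) <= 3 * r["se"]


class TestClassifyWhitefly:
    @pytest.mark.parametrize(
        "coef,p,expected",
        [(-3.1, 0.001, "resistant"),
         (1.2, 0.001, "susceptible"),   # significant but higher survival
         (-0.4, 0.3, "susceptible")],   # right sign but not significant
    )
    def test_sign_and_significance_rule(self, coef, p, expected):
        res = pd.DataFrame(
            {"coefficient": [coef], "se": [0.5], "p_value": [p], "note": [""]},
            index=pd.Index(["X"], name="accession"),
        )
        out = classify_whitefly(res).set_index("accession")
        assert out.loc["X", "class"] == expected


def thrips_records(days_status, acc="A"):
    return pd.DataFrame(
        [(acc, f"{acc}-{i}", d, s) for i, (d, s) in enumerate(days_status)],
        columns=["accession", "individual_id", "day", "status"],
    )


class TestKaplanMeier:
    def test_all_die_day_one(self):
        km = kaplan_meier(thrips_records([(1, 1)] * 10))
        assert km.loc["A", "median_survival"] == 1

    def test_no_deaths_median_beyond_horizon(self):
        km = kaplan_meier(thrips_records([(19, 0)] * 10))
        assert np.isinf(km.loc["A", "median_survival"])

    def test_without_censoring_equals_empirical_survival(self):
        days = [1, 1, 2, 3, 3, 3, 5, 8]
        km = kaplan_meier(thrips_records([(d, 1) for d in days]))
        curves = km.attrs["curves"]
        emp = lambda t: np.mean([d > t for d in days])
        for _, row in curves[curves["day"] > 0].iterrows():
            assert row["survival"] == pytest.approx(emp(row["day"]))

    def test_simulated_exponential_median_on_daily_grid(self):
        cfg = SimConfig(
            n_accessions=2, n_resistant=1, n_larvae=2500,
            baseline_daily_hazard=0.2, log_hr_resistant=0.0, seed=23,
        )
        df, _ = simulate_thrips_assay(cfg)
        km = kaplan_meier(df)
        assert (km["median_survival"] == 4).all()

    def test_interpolated_median_falls_between_grid_days(self):
        # S(1) = 0.6, S(2) = 0.2: the 0.5 crossing interpolates inside (1, 2)
        rec = thrips_records([(1, 1)] * 4 + [(2, 1)] * 4 + [(3, 1)] * 2)
        km_grid = kaplan_meier(rec)
        km_int = kaplan_meier(rec, interpolate=True)
        assert km_grid.loc["A", "median_survival"] == 2
        assert 1 < km_int.loc["A", "median_survival"] < 2
        assert km_int.loc["A", "median_survival"] == pytest.approx(1.25)


class TestCox:
    def test_identical_groups_hazard_ratio_near_one(self):
        rec = pd.concat(
            [thrips_records([(d, 1) for d in (2, 3, 3, 5, 7, 9)], acc=a)
             for a in ("A", "B")],
            ignore_index=True,
        )
        res = fit_cox(rec, "A")
        assert res.loc["B", "exp_coefficient"] == pytest.approx(1.0, abs=1e-6)
        assert res.loc["B", "p_value"] > 0.99

    def test_two_group_exponential_recovery_vs_closed_form(self):
        cfg = SimConfig(
            n_accessions=2, n_resistant=1, n_larvae=200,
            baseline_daily_hazard=0.04, log_hr_resistant=math.log(5), seed=31,
        )
        df, truth = simulate_thrips_assay(cfg)
        base = cfg.baseline_accession
        other = [a for a in df["accession"].unique() if a != base][0]
        res = fit_cox(df, base)
        df2 = df.rename(columns={"accession": "arm"})
        df2["arm"] = (df2["arm"] == other).astype(int)
        oracle, se = exponential_cox_oracle(df2)
        assert abs(res.loc[other, "coefficient"] - oracle) <= 3 * se

    def test_zero_death_accession_flagged_not_crashed(self):
        rec = pd.concat(
            [thrips_records([(d, 1) for d in (1, 2, 2, 3)], acc="A"),
             thrips_records([(19, 0)] * 4, acc="B")],
            ignore_index=True,
        )
        res = fit_cox(rec, "A")
        assert res.loc["B", "note"] == "non-estimable: zero deaths"
        labels = classify_thrips(res).set_index("accession")
        assert labels.loc["B", "class"] == "susceptible"

    def test_breslow_option_close_to_efron_with_few_ties(self):
        rng = np.random.default_rng(0)
        days = rng.integers(1, 50, size=60)
        rec = pd.concat(
            [thrips_records([(d, 1) for d in days[:30]], acc="A"),
             thrips_records([(max(1, d // 3), 1) for d in days[30:]], acc="B")],
            ignore_index=True,
        )
        efron = fit_cox(rec, "A", ties="efron")
        breslow = fit_cox(rec, "A", ties="breslow")
        assert efron.loc["B", "coefficient"] == pytest.approx(
            breslow.loc["B", "coefficient"], rel=0.15
        )


class TestClassifyThrips:
    @pytest.mark.parametrize(
        "hr,p,expected",
        [(215.0, 1e-4, "resistant"),
         (0.5, 1e-4, "susceptible"),   # significant but protective-for-insect
         (3.0, 0.05, "susceptible")],  # above 1 but not significant at 0.01
    )
    def test_direction_and_threshold_rule(self, hr, p, expected):
        res = pd.DataFrame(
            {"coefficient": [math.log(hr)], "exp_coefficient": [hr],
             "se": [0.5], "p_value": [p], "note": [""]},
            index=pd.Index(["X"], name="accession"),
        )
        out = classify_thrips(res).set_index("accession")
        assert out.loc["X", "class"] == expected


def test_label_determinism_end_to_end(small_config):
    df, _ = simulate_thrips_assay(small_config)
    l1 = phenotype_thrips(df, small_config.baseline_accession)
    l2 = phenotype_thrips(df, small_config.baseline_accession)
    pd.testing.assert_frame_equal(l1, l2)
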