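import math

import numpy as np
import pandas as pd
import pytest

from promscan import study_analytics as sa
from promscan import synthetic_corpus as sc


def corpus_table(n=2000, seed=0, **config_kwargs):
    config = sc.SyntheticConfig(n_studies=n, seed=seed, **config_kwargs)
    studies, gt = sc.generate_corpus(config)
    flags = {sid: t.uses_prompem for sid, t in gt.studies.items()}
    sites = {sid: t.site_label for sid, t in gt.studies.items()}
    return sa.build_table(studies, flags, sites), studies, gt


class TestAggregation:
    def test_any_semantics(self):
        flags = sa.aggregate_study_flags(
            {("S1", 1): False, ("S1", 2): True, ("S1", 3): False}
        )
        assert flags == {"S1": True}

    def test_all_negative(self):
        assert sa.aggregate_study_flags({("S1", 1): False}) == {"S1": False}

    def test_adding_positive_never_flips(self):
        base = {("S1", 1): True, ("S1", 2): False}
        more = dict(base)
        more[("S1", 3)] = True
        assert sa.aggregate_study_flags(base)["S1"]
        assert sa.aggregate_study_flags(more)["S1"]

    def test_matches_brute_force_any(self, small_corpus):
        studies, gt = small_corpus
        detections = {
            key: t.contains_named_instrument for key, t in gt.outcomes.items()
        }
        flags = sa.aggregate_study_flags(detections)
        for study in studies:
            expected = any(
                gt.outcomes[o.key].contains_named_instrument for o in study.outcomes
            )
            assert flags[study.study_id] == expected

    def test_empty(self):
        assert sa.aggregate_study_flags({}) == {}

    def test_flagless_study_errors(self, small_corpus):
        studies, gt = small_corpus
        with pytest.raises(sa.AnalyticsError):
            sa.build_table(studies, {})


class TestTrend:
    def test_flat_prevalence_null(self):
        # constant 50% prevalence, n=200/year: trend test should not reject
        rng = np.random.default_rng(11)
        rows = []
        for year in range(2012, 2022):
            for i in range(200):
                rows.append({"year": year, "uses_prompem": int(rng.random() < 0.5)})
        out = sa.yearly_trend(pd.DataFrame(rows))
        assert out["p_value"] > 0.05

    def test_linear_increase_detected(self):
        # 0.25 -> 0.40 over 10 years, 500 studies/year
        rng = np.random.default_rng(13)
        rows = []
        for j, year in enumerate(range(2012, 2022)):
            p = 0.25 + 0.15 * j / 9
            for i in range(500):
                rows.append({"year": year, "uses_prompem": int(rng.random() < p)})
        table = pd.DataFrame(rows)
        out = sa.yearly_trend(table)
        assert out["p_value"] < 0.001
        series = out["series"]
        # estimates roughly monotone: fitted slope positive
        assert np.polyfit(series["year"], series["proportion"], 1)[0] > 0

    def test_single_year_no_test(self):
        table = pd.DataFrame({"year": [2015] * 10, "uses_prompem": [1, 0] * 5})
        out = sa.yearly_trend(table)
        assert out["p_value"] is None
        assert len(out["series"]) == 1

    def test_empty_table(self):
        out = sa.yearly_trend(pd.DataFrame(columns=["year", "uses_prompem"]))
        assert out["series"].empty
        assert out["p_value"] is None


class TestBivariate:
    def test_type_i_error_rate(self):
        # independence generator: ~5% rejections over replicates
        rng = np.random.default_rng(21)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            table = pd.DataFrame({
                "covariate": rng.choice(["a", "b"], size=120).tolist(),
                "uses_prompem": rng.integers(0, 2, size=120).tolist(),
            })
            out = sa.bivariate_chisq(table, "covariate")
            rejections += out["p_value"] < 0.05
        assert abs(rejections / reps - 0.05) < 0.02

    def test_perfect_association_statistic_n(self):
        # 2x2 with phi=1 gives statistic n
        table = pd.DataFrame({
            "covariate": ["a"] * 20 + ["b"] * 20,
            "uses_prompem": [1] * 20 + [0] * 20,
        })
        out = sa.bivariate_chisq(table, "covariate")
        assert out["statistic"] == pytest.approx(40.0)

    def test_single_level_errors(self):
        table = pd.DataFrame({"covariate": ["a"] * 10, "uses_prompem": [0, 1] * 5})
        with pytest.raises(sa.AnalyticsError):
            sa.bivariate_chisq(table, "covariate")

    def test_missing_level_excluded(self):
        table = pd.DataFrame({
            "covariate": ["a", "b", "missing"] * 20,
            "uses_prompem": [0, 1] * 30,
        })
        out = sa.bivariate_chisq(table, "covariate")
        assert math.isfinite(out["statistic"])


def irls_logistic(x, y, tol=1e-10, max_iter=100):
    """Independent iteratively-reweighted least-squares reference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        eta = x @ beta
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        wx = x * w[:, None]
        beta_new = np.linalg.solve(x.T @ wx, x.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


class TestRegression:
    def test_or_recovery(self):
        table, _, _ = corpus_table(
            n=5000, seed=101, prevalence=0.3,
            covariate_effects={"allocation=randomized": math.log(2.0)},
        )
        results, info = sa.fit_use_model(table, "interventional", ["allocation"])
        randomized = next(r for r in results if r.level == "randomized")
        assert randomized.ci95[0] <= 2.0 <= randomized.ci95[1]
        assert info["n_dropped_missing"] > 0

    def test_reference_level_or_exactly_one(self):
        table, _, _ = corpus_table(n=1500, seed=5)
        results, _ = sa.fit_use_model(
            table, "interventional", ["allocation", "primary_purpose"]
        )
        for r in results:
            if r.is_reference:
                assert r.odds_ratio == 1.0
                assert r.ci95 == (1.0, 1.0)
                assert r.wald_p is None

    def test_matches_irls_reference(self):
        table, _, _ = corpus_table(n=3000, seed=33, prevalence=0.35,
                                   covariate_effects={"allocation=randomized": 0.5})
        results, info = sa.fit_use_model(table, "interventional", ["allocation"])
        sub = table[(table.study_type == "interventional")
                    & (table.allocation != "missing")]
        x = np.column_stack([
            np.ones(len(sub)),
            (sub["allocation"] == "randomized").to_numpy(float),
        ])
        beta = irls_logistic(x, sub["uses_prompem"].to_numpy())
        randomized = next(r for r in results if r.level == "randomized")
        assert math.log(randomized.odds_ratio) == pytest.approx(beta[1], abs=1e-6)

    def test_null_coverage(self):
        """Under a null generator, the 95% CI covers OR=1 ~95% of the time."""
        rng = np.random.default_rng(55)
        covered = 0
        reps = 200
        for _ in range(reps):
            n = 400
            table = pd.DataFrame({
                "study_type": ["interventional"] * n,
                "allocation": rng.choice(["randomized", "nonrandomized"], n).tolist(),
                "uses_prompem": rng.integers(0, 2, n).tolist(),
            })
            results, _ = sa.fit_use_model(table, "interventional", ["allocation"])
            r = next(x for x in results if x.level == "randomized")
            covered += r.ci95[0] <= 1.0 <= r.ci95[1]
        assert abs(covered / reps - 0.95) < 0.05

    def test_constant_predictor_errors(self):
        table = pd.DataFrame({
            "study_type": ["interventional"] * 40,
            "allocation": ["randomized"] * 40,
            "uses_prompem": [0, 1] * 20,
        })
        with pytest.raises(sa.SeparationError):
            sa.fit_use_model(table, "interventional", ["allocation"])

    def test_perfect_separation_errors(self):
        table = pd.DataFrame({
            "study_type": ["interventional"] * 40,
            "allocation": ["randomized"] * 20 + ["nonrandomized"] * 20,
            "uses_prompem": [1] * 20 + [0] * 20,
        })
        with pytest.raises(sa.SeparationError, match="allocation"):
            sa.fit_use_model(table, "interventional", ["allocation"])

    def test_empty_stratum_errors(self):
        table = pd.DataFrame({
            "study_type": ["interventional"] * 4,
            "allocation": ["randomized", "nonrandomized"] * 2,
            "uses_prompem": [0, 1, 1, 0],
        })
        with pytest.raises(sa.AnalyticsError):
            sa.fit_use_model(table, "observational", ["allocation"])


class TestMissingness:
    def test_null_rejection_rate(self):
        rng = np.random.default_rng(88)
        rejections = 0
        reps = 200
        for _ in range(reps):
            n = 300
            table = pd.DataFrame({
                "year": rng.integers(2012, 2022, n),
                "phase": np.where(rng.random(n) < 0.3, "missing", "phase2"),
            })
            out = sa.missingness_check(table, "phase", covariates=["year"])
            rejections += out["test_p"] < 0.05
        assert abs(rejections / reps - 0.05) < 0.04

    def test_year_dependent_missingness_detected(self):
        rng = np.random.default_rng(99)
        n = 2000
        years = rng.integers(2012, 2022, n)
        p_missing = 1 / (1 + np.exp(-(years - 2017) * 0.5))
        table = pd.DataFrame({
            "year": years,
            "phase": np.where(rng.random(n) < p_missing, "missing", "phase2"),
        })
        out = sa.missingness_check(table, "phase", covariates=["year"])
        assert out["verdict"] == "not consistent with MCAR"
        assert out["test_p"] < 0.05

    def test_fully_observed(self):
        table = pd.DataFrame({"year": [2015, 2016], "phase": ["phase2", "phase3"]})
        out = sa.missingness_check(table, "phase", covariates=["year"])
        assert out == {"test_p": None, "verdict": "nothing to test"}


def test_format_p():
    assert sa.format_p(0.0004) == "<.001"
    assert sa.format_p(0.0312) == ".03"
    assert sa.format_p(0.5) == ".50"
    assert sa.format_p(None) == "NA"
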