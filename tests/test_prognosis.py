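"""Survival branch: Cox fits, penalised selection, risk scoring, cohort
splitting, KM/log-rank and time-dependent AUC."""

import numpy as np
import pandas as pd
import pytest

from cernamut.exceptions import ConfigError, InestimableError, ValidationError
from cernamut.prognosis import (
    RiskModel,
    _breslow_loglik,
    km_estimate,
    lasso_cox_select,
    load_published_model,
    logrank_test,
    median_risk_groups,
    multivariate_cox,
    risk_score,
    score_samples,
    split_cohort,
    time_dependent_auc,
    univariate_cox,
)
from cernamut.simulate import simulate_survival


def _clinical(times, events):
    return pd.DataFrame(
        {"os_days": np.asarray(times, dtype=float), "event": list(events)},
        index=[f"S{i}" for i in range(len(times))],
    )


class TestUnivariateCox:
    def test_constant_covariate_inestimable(self):
        clin = _clinical([5, 6, 7, 8], [1, 1, 1, 0])
        with pytest.raises(InestimableError):
            univariate_cox(np.ones(4), clin)

    def test_too_few_events_inestimable(self):
        clin = _clinical([5, 6, 7, 8], [1, 0, 0, 0])
        with pytest.raises(InestimableError):
            univariate_cox(np.array([1.0, 2.0, 3.0, 4.0]), clin)

    def test_matches_grid_search_of_partial_likelihood(self):
        # 6 records, no ties: maximize the written-out partial likelihood
        # by brute-force grid search and compare
        times = [3.0, 5.0, 7.0, 11.0, 13.0, 17.0]
        events = [1, 1, 0, 1, 1, 1]
        x = np.array([0.5, -0.2, 1.0, 0.3, -0.8, 0.1])
        clin = _clinical(times, events)

        def pl(beta):
            total = 0.0
            for i in range(6):
                if events[i]:
                    risk = [j for j in range(6) if times[j] >= times[i]]
                    total += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return total

        grid = np.arange(-3.0, 3.0, 1e-3)
        beta_grid = grid[int(np.argmax([pl(b) for b in grid]))]
        res = univariate_cox(x, clin)
        assert res.beta == pytest.approx(beta_grid, abs=5e-3)
        assert res.hr == pytest.approx(np.exp(res.beta), rel=1e-12)

    def test_parameter_recovery_from_simulated_hazard(self, rng):
        # hazard exp(1 * x) at n=500: beta-hat within +/-0.15 of 1
        expr = pd.DataFrame(
            {f"S{i}": [v] for i, v in enumerate(rng.lognormal(2, 0.8, 500))},
            index=["GX"],
        )
        clin = simulate_survival(expr, {"GX": 1.0}, 1 / 300, 0.2, seed=8)
        x = np.log2(expr.loc["GX"].values + 1)
        res = univariate_cox(x, clin.loc[expr.columns])
        assert abs(res.beta - 1.0) < 0.15

    def test_recovery_bias_and_se_consistency(self, rng):
        # repeated simulation at n=1000: small bias, model SE close to the
        # empirical spread of the estimates
        betas, ses = [], []
        for rep in range(25):
            expr = pd.DataFrame(
                {f"S{i}": [v] for i, v in enumerate(rng.lognormal(1.5, 1.0, 1000))},
                index=["GX"],
            )
            clin = simulate_survival(expr, {"GX": 0.8}, 1 / 300, 0.0, seed=100 + rep)
            res = univariate_cox(np.log2(expr.loc["GX"].values + 1), clin)
            betas.append(res.beta)
            ses.append(res.se)
        assert abs(np.mean(betas) - 0.8) < 0.05
        assert abs(np.mean(ses) / np.std(betas, ddof=1) - 1) < 0.35


class TestBreslowLoglik:
    def test_matches_hand_computation_without_ties(self):
        X = np.array([[0.5], [-1.0], [0.0], [2.0]])
        time = np.array([2.0, 4.0, 6.0, 8.0])
        event = np.array([1, 0, 1, 1])
        beta = np.array([0.3])
        lp = X @ beta
        expected = 0.0
        for i in range(4):
            if event[i]:
                risk = lp[time >= time[i]]
                expected += lp[i] - np.log(np.sum(np.exp(risk)))
        assert _breslow_loglik(beta, X, time, event) == pytest.approx(expected, rel=1e-12)


class TestLassoCoxSelect:
    def test_single_strong_candidate_selected(self, rng):
        expr = pd.DataFrame(
            rng.lognormal(2, 0.8, size=(1, 200)),
            index=["GX"], columns=[f"S{i}" for i in range(200)],
        )
        clin = simulate_survival(expr, {"GX": 1.2}, 1 / 300, 0.1, seed=4)
        selected, path = lasso_cox_select(expr, clin, n_folds=5, seed=0)
        assert selected == ["GX"]

    def test_path_starts_fully_shrunk(self, rng):
        # the largest lambda on the path shrinks (almost) everything to zero
        expr = pd.DataFrame(
            rng.lognormal(2, 0.6, size=(8, 150)),
            index=[f"G{i}" for i in range(8)], columns=[f"S{i}" for i in range(150)],
        )
        clin = simulate_survival(expr, {"G0": 1.0}, 1 / 300, 0.1, seed=6)
        _, path = lasso_cox_select(expr, clin, n_folds=5, seed=0)
        first = path.iloc[:, 0]  # largest lambda
        assert (first != 0).sum() <= 1

    def test_support_recovery_with_noise_genes(self, rng):
        # 5 planted signal genes among 50 independent noise genes, n=400
        genes = [f"SIG{i}" for i in range(5)] + [f"NOI{i}" for i in range(50)]
        expr = pd.DataFrame(
            rng.lognormal(2, 0.8, size=(55, 400)),
            index=genes, columns=[f"S{i}" for i in range(400)],
        )
        coeffs = {f"SIG{i}": (1.0 if i % 2 == 0 else -1.0) for i in range(5)}
        clin = simulate_survival(expr, coeffs, 1 / 300, 0.2, seed=12)
        selected, _ = lasso_cox_select(expr, clin, n_folds=10, seed=0)
        assert set(f"SIG{i}" for i in range(5)) <= set(selected)
        assert sum(1 for g in selected if g.startswith("NOI")) <= 5


class TestMultivariateCox:
    def test_single_gene_matches_univariate(self, rng):
        expr = pd.DataFrame(
            rng.lognormal(2, 0.8, size=(1, 120)),
            index=["GX"], columns=[f"S{i}" for i in range(120)],
        )
        clin = simulate_survival(expr, {"GX": 0.9}, 1 / 300, 0.2, seed=3)
        logged = np.log2(expr + 1)
        model, table = multivariate_cox(logged, clin)
        uni = univariate_cox(logged.loc["GX"].values, clin)
        assert model.coefficients[0] == pytest.approx(uni.beta, rel=1e-6)
        assert table.loc[0, "p_value"] == pytest.approx(uni.p_value, rel=1e-6)

    def test_two_independent_effects_recovered(self, rng):
        expr = pd.DataFrame(
            rng.lognormal(2, 0.8, size=(2, 500)),
            index=["GP", "GN"], columns=[f"S{i}" for i in range(500)],
        )
        clin = simulate_survival(expr, {"GP": 1.0, "GN": -1.0}, 1 / 300, 0.2, seed=9)
        model, _ = multivariate_cox(np.log2(expr + 1), clin)
        coefs = dict(zip(model.genes, model.coefficients))
        assert abs(coefs["GP"] - 1.0) < 0.2
        assert abs(coefs["GN"] + 1.0) < 0.2

    def test_more_genes_than_samples_rejected(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(10, 8)),
            index=[f"G{i}" for i in range(10)], columns=[f"S{i}" for i in range(8)],
        )
        clin = _clinical(np.arange(1.0, 9.0), [1] * 8)
        clin.index = expr.columns
        with pytest.raises(ValidationError):
            multivariate_cox(expr, clin)


class TestRiskScore:
    def test_null_vector_scores_zero(self):
        model = RiskModel(("A", "B"), (0.5, -0.3))
        assert risk_score({"A": 0.0, "B": 0.0}, model) == 0.0

    def test_published_model_leading_coefficient(self):
        model = load_published_model()
        assert len(model.genes) == 8
        row = {g: 0.0 for g in model.genes}
        row["SLC30A1"] = 1.0
        assert risk_score(row, model) == pytest.approx(0.65)

    def test_linearity(self, rng):
        model = load_published_model()
        x = {g: float(v) for g, v in zip(model.genes, rng.normal(size=8))}
        y = {g: float(v) for g, v in zip(model.genes, rng.normal(size=8))}
        combo = {g: 2 * x[g] + 3 * y[g] for g in model.genes}
        assert risk_score(combo, model) == pytest.approx(
            2 * risk_score(x, model) + 3 * risk_score(y, model), rel=1e-12
        )

    def test_missing_gene_named_in_error(self):
        model = RiskModel(("A", "B"), (1.0, 1.0))
        with pytest.raises(ValidationError, match="B"):
            risk_score({"A": 1.0}, model)

    def test_score_samples_matches_rowwise(self, rng):
        model = RiskModel(("A", "B"), (0.5, -0.25))
        expr = pd.DataFrame(
            rng.normal(size=(2, 5)), index=["A", "B"], columns=list("vwxyz")
        )
        scores = score_samples(expr, model)
        for s in expr.columns:
            assert scores[s] == pytest.approx(
                risk_score(expr[s].to_dict(), model), rel=1e-12
            )

    def test_tsv_roundtrip(self, tmp_path):
        model = load_published_model()
        path = tmp_path / "model.tsv"
        model.to_tsv(path)
        back = RiskModel.from_tsv(path)
        assert back.genes == model.genes
        assert back.coefficients == model.coefficients


class TestSplitAndGroups:
    def test_seventy_thirty_split(self):
        train, test = split_cohort([f"S{i}" for i in range(10)], 0.7, seed=1)
        assert len(train) == 7 and len(test) == 3

    def test_partition_property(self):
        samples = [f"S{i}" for i in range(23)]
        train, test = split_cohort(samples, 0.7, seed=5)
        assert sorted(train + test) == sorted(samples)
        assert not set(train) & set(test)

    def test_deterministic_under_seed(self):
        samples = [f"S{i}" for i in range(40)]
        assert split_cohort(samples, 0.7, 9) == split_cohort(samples, 0.7, 9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            split_cohort(["S1"], 0.7, 0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigError):
            split_cohort(["S1", "S2"], 1.5, 0)

    def test_median_split_even(self):
        scores = pd.Series(np.arange(1.0, 11.0), index=[f"S{i}" for i in range(10)])
        groups = median_risk_groups(scores)
        assert (groups == "high").sum() == 5 and (groups == "low").sum() == 5

    def test_median_sample_goes_low_on_odd_n(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        groups = median_risk_groups(scores)
        assert groups["b"] == "low"

    def test_invariant_under_monotone_transform(self, rng):
        scores = pd.Series(rng.normal(size=21), index=[f"S{i}" for i in range(21)])
        g1 = median_risk_groups(scores)
        g2 = median_risk_groups(np.exp(scores) * 3 + 7)
        pd.testing.assert_series_equal(g1, g2)


class TestKmAndLogrank:
    def test_no_events_flat_curve(self):
        clin = _clinical([5, 6, 7], [0, 0, 0])
        groups = pd.Series(["g"] * 3, index=clin.index)
        curve = km_estimate(clin, groups)["g"]
        assert (curve["survival"] == 1.0).all()

    def test_all_events_closed_form(self):
        clin = _clinical([1, 2, 3, 4], [1, 1, 1, 1])
        groups = pd.Series(["g"] * 4, index=clin.index)
        curve = km_estimate(clin, groups)["g"].set_index("time")["survival"]
        np.testing.assert_allclose(
            curve.loc[[1.0, 2.0, 3.0, 4.0]].values, [0.75, 0.5, 0.25, 0.0]
        )

    def test_matches_hand_product_limit_with_censoring(self):
        # classic 6-record toy: events at 6, 13, 31; censored at 10, 16, 40
        clin = _clinical([6, 10, 13, 16, 31, 40], [1, 0, 1, 0, 1, 0])
        groups = pd.Series(["g"] * 6, index=clin.index)
        curve = km_estimate(clin, groups)["g"].set_index("time")["survival"]
        assert curve.loc[6.0] == pytest.approx(5 / 6)
        assert curve.loc[13.0] == pytest.approx(5 / 6 * 3 / 4)
        assert curve.loc[31.0] == pytest.approx(5 / 6 * 3 / 4 * 1 / 2)
        # censored times do not drop the curve
        assert curve.loc[10.0] == pytest.approx(5 / 6)

    def test_curves_non_increasing_in_unit_interval(self, demo_cohort):
        clin = demo_cohort.clinical
        groups = pd.Series(
            np.where(np.arange(len(clin)) % 2 == 0, "a", "b"), index=clin.index
        )
        for curve in km_estimate(clin, groups).values():
            s = curve["survival"].values
            assert ((s >= -1e-12) & (s <= 1 + 1e-12)).all()
            assert (np.diff(s) <= 1e-12).all()

    def test_identical_groups_logrank_null(self):
        times = [3.0, 5.0, 8.0, 11.0, 14.0, 20.0]
        clin = _clinical(times + times, [1, 1, 0, 1, 1, 0] * 2)
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=clin.index)
        chi2, p = logrank_test(clin, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_logrank_formula(self):
        # hand summation of (O - E) and hypergeometric variance per event time
        times = np.array([2.0, 4.0, 5.0, 7.0, 9.0, 12.0, 15.0, 18.0])
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        labels = np.array(list("aabbaabb"))
        clin = _clinical(times, events)
        groups = pd.Series(labels, index=clin.index)
        o_minus_e = 0.0
        var = 0.0
        for t in sorted(set(times[events == 1])):
            at_risk = times >= t
            n = at_risk.sum()
            n_a = (at_risk & (labels == "a")).sum()
            d = ((times == t) & (events == 1)).sum()
            d_a = ((times == t) & (events == 1) & (labels == "a")).sum()
            o_minus_e += d_a - d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / var
        chi2, _ = logrank_test(clin, groups)
        assert chi2 == pytest.approx(expected_chi2, rel=1e-9)

    def test_single_group_rejected(self):
        clin = _clinical([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValidationError):
            logrank_test(clin, pd.Series(["g"] * 3, index=clin.index))


class TestTimeDependentAuc:
    def test_perfect_model_auc_one(self):
        clin = _clinical([10, 20, 30, 40, 50, 60], [1, 1, 1, 0, 0, 0])
        scores = pd.Series([6.0, 5.0, 4.0, 3.0, 2.0, 1.0], index=clin.index)
        assert time_dependent_auc(scores, clin, 35.0) == pytest.approx(1.0)

    def test_random_scores_near_half(self, rng):
        n = 4000
        clin = _clinical(rng.exponential(100, n), np.ones(n, dtype=int))
        scores = pd.Series(rng.normal(size=n), index=clin.index)
        assert abs(time_dependent_auc(scores, clin, 80.0) - 0.5) < 0.05

    def test_matches_pair_enumeration_on_toy(self):
        clin = _clinical([5, 8, 12, 20, 25, 30, 35, 40],
                         [1, 1, 0, 1, 0, 1, 1, 0])
        scores = pd.Series([3.1, 0.4, 2.2, 1.5, 0.9, 2.8, 1.1, 0.2],
                           index=clin.index)
        t = 22.0
        cases = [i for i in range(8) if clin["event"].iloc[i] and clin["os_days"].iloc[i] <= t]
        controls = [i for i in range(8) if clin["os_days"].iloc[i] > t]
        wins = 0.0
        for i in cases:
            for j in controls:
                si, sj = scores.iloc[i], scores.iloc[j]
                wins += 1.0 if si > sj else 0.5 if si == sj else 0.0
        expected = wins / (len(cases) * len(controls))
        assert time_dependent_auc(scores, clin, t) == pytest.approx(expected, rel=1e-12)

    def test_no_cases_rejected(self):
        clin = _clinical([50, 60, 70], [1, 1, 1])
        scores = pd.Series([1.0, 2.0, 3.0], index=clin.index)
        with pytest.raises(InestimableError):
            time_dependent_auc(scores, clin, 10.0)
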