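import numpy as np
import pandas as pd
import pytest

from dysreg.containers import ExpressionMatrix
from dysreg.coxmodel import fit_cox
from dysreg.signature import (GreedyConfig, benefit_transfer,
                              cross_validate_signature, greedy_build,
                              km_logrank_hr, risk_score, time_dependent_auc)


class TestGreedyBuild:
    def test_single_candidate_history_length_one(self, survival_cohort):
        expr, clin = survival_cohort
        model = greedy_build([("g0", "g1")], expr, clin,
                             GreedyConfig(n_reps=10, seed=0))
        assert model.dysregulations == [("g0", "g1")]
        assert len(model.c_index_history) == 1
        assert model.genes == ["g0", "g1"]

    def test_huge_delta_keeps_primary_only(self, survival_cohort):
        expr, clin = survival_cohort
        cands = [("g0", "g1"), ("g2", "g3"), ("g4", "g5")]
        model = greedy_build(cands, expr, clin,
                             GreedyConfig(n_reps=10, seed=0, delta_c_stop=1e9))
        assert len(model.dysregulations) == 1

    def test_history_strictly_increasing_by_delta(self, survival_cohort):
        expr, clin = survival_cohort
        cands = [(f"g{2 * i}", f"g{2 * i + 1}") for i in range(6)]
        cfg = GreedyConfig(n_reps=10, seed=1, delta_c_stop=0.001)
        model = greedy_build(cands, expr, clin, cfg)
        h = model.c_index_history
        assert all(h[i + 1] >= h[i] + cfg.delta_c_stop for i in range(len(h) - 1))
        assert len(model.genes) <= 2 * len(model.dysregulations)

    def test_prognostic_candidate_chosen_primary(self, survival_cohort):
        expr, clin = survival_cohort
        # g0 carries the hazard; pair it against noise candidates
        cands = [("g0", "g1")] + [(f"g{10 + 2 * i}", f"g{11 + 2 * i}")
                                  for i in range(8)]
        model = greedy_build(cands, expr, clin, GreedyConfig(n_reps=10, seed=3))
        assert model.dysregulations[0] == ("g0", "g1")

    def test_restriction_filters_candidates(self, survival_cohort):
        expr, clin = survival_cohort
        cands = [("g0", "g1"), ("g2", "g3")]
        model = greedy_build(cands, expr, clin,
                             GreedyConfig(n_reps=5, seed=0,
                                          restrict_genes={"g2", "g3"}))
        assert model.dysregulations == [("g2", "g3")]


class TestRiskScore:
    def test_median_split_halves_cohort(self, survival_cohort):
        expr, clin = survival_cohort
        genes = ["g0", "g1"]
        Z = np.column_stack([expr.values.loc[g] for g in genes] +
                            [clin[c] for c in ("age", "gender", "stage")])
        fit = fit_cox(Z, clin["os_time"].to_numpy(),
                      clin["os_event"].to_numpy().astype(int),
                      covariates=genes + ["age", "gender", "stage"])
        rs = risk_score(fit, genes, ["age", "gender", "stage"], expr, clin)
        n_high = (rs.groups == "high").sum()
        n_low = (rs.groups == "low").sum()
        assert abs(n_high - n_low) <= 1
        assert set(rs.groups.index) == set(rs.scores.index)

    def test_missing_gene_listed_in_error(self, survival_cohort):
        expr, clin = survival_cohort
        fit = fit_cox(expr.values.loc[["g0"]].to_numpy().T,
                      clin["os_time"].to_numpy(),
                      clin["os_event"].to_numpy().astype(int))
        with pytest.raises(ValueError, match="absent_gene"):
            risk_score(fit, ["absent_gene"], [], expr, clin)

    def test_sign_grouping_invariant_to_global_shift(self, survival_cohort):
        expr, clin = survival_cohort
        genes = ["g0", "g1"]
        untx = clin.copy()
        untx["adjc"] = ([0, 1] * len(untx))[:len(untx)]
        km1, auc1, rs1 = benefit_transfer(genes, expr, untx)
        shifted = ExpressionMatrix(expr.values + 7.5, expr.condition)
        km2, auc2, rs2 = benefit_transfer(genes, shifted, untx)
        assert (rs1.groups == rs2.groups).all()
        assert np.allclose(rs1.scores, rs2.scores, atol=1e-8)


class TestKMLogrank:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1, 40)
        e = np.ones(40, int)
        g = pd.Series(["A"] * 20 + ["B"] * 20)
        res = km_logrank_hr(g, pd.Series(np.concatenate([t[:20], t[:20]])),
                            pd.Series(np.concatenate([e[:20], e[:20]])))
        assert res.logrank_p > 0.9
        assert res.hazard_ratio == pytest.approx(1.0, abs=0.05)

    def test_dominated_group_detected(self):
        tA = np.linspace(0.1, 2.0, 20)
        tB = np.linspace(5.0, 9.0, 20)
        g = pd.Series(["A"] * 20 + ["B"] * 20)
        res = km_logrank_hr(g, pd.Series(np.concatenate([tA, tB])),
                            pd.Series(np.ones(40, int)), numerator="A")
        assert res.logrank_p < 0.01
        assert res.hazard_ratio > 1

    def test_statistic_matches_textbook_formula(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        events = np.array([1, 1, 0, 1, 1, 0, 1, 0])
        groups = np.array(["A", "B", "A", "B", "A", "B", "A", "B"])
        res = km_logrank_hr(pd.Series(groups), pd.Series(times), pd.Series(events))
        # observed-minus-expected oracle
        O = E = V = 0.0
        for u in np.unique(times[events == 1]):
            at_risk = times >= u
            d = float(((times == u) & (events == 1)).sum())
            n = float(at_risk.sum())
            n_a = float((at_risk & (groups == "A")).sum())
            d_a = float(((times == u) & (events == 1) & (groups == "A")).sum())
            O += d_a
            E += d * n_a / n
            if n > 1:
                V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        chi2 = (O - E) ** 2 / V
        assert res.logrank_chi2 == pytest.approx(chi2, abs=1e-10)

    def test_zero_event_group_flagged(self):
        t = pd.Series([1.0, 2.0, 3.0, 4.0])
        e = pd.Series([1, 1, 0, 0])
        g = pd.Series(["A", "A", "B", "B"])
        with pytest.warns(UserWarning, match="zero events"):
            res = km_logrank_hr(g, t, e)
        assert res.hazard_ratio is None


class TestTimeAUC:
    def test_no_censoring_equals_empirical_auc(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = 80
            s = rng.standard_normal(n)
            t = rng.exponential(2, n)
            e = np.ones(n, int)
            for tau in np.quantile(t, [0.3, 0.5, 0.7]):
                auc = time_dependent_auc(s, t, e, [tau]).auc[0]
                ref = sklearn_metrics.roc_auc_score((t <= tau).astype(int), s)
                assert auc == pytest.approx(ref, abs=1e-12)

    def test_perfect_score_every_time(self):
        t = np.linspace(0.5, 10, 40)
        auc = time_dependent_auc(-t, t, np.ones(40, int), [2.0, 5.0, 8.0])
        assert all(a == 1.0 for a in auc.auc)

    def test_close_to_sksurv_reference(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(9)
        n = 150
        s = rng.standard_normal(n)
        T = rng.exponential(np.exp(-0.8 * s)) * 3
        C = rng.uniform(0, 8, n)
        t = np.minimum(T, C)
        e = (T <= C).astype(int)
        y = np.array([(bool(ev), tt) for ev, tt in zip(e, t)],
                     dtype=[("event", bool), ("time", float)])
        taus = [1.0, 2.0]
        ref, _ = sksurv_metrics.cumulative_dynamic_auc(y, y, s, taus)
        ours = time_dependent_auc(s, t, e, taus).auc
        assert np.allclose(ours, ref, atol=0.02)

    def test_missing_when_no_cases(self):
        t = np.array([5.0, 6.0, 7.0])
        with pytest.warns(UserWarning):
            auc = time_dependent_auc(np.zeros(3), t, np.ones(3, int), [1.0])
        assert np.isnan(auc.auc[0])


class TestCrossValidationAndBenefit:
    def test_cv_reproducible_and_informative(self, survival_cohort):
        expr, clin = survival_cohort
        cfg = GreedyConfig(n_reps=8, seed=12)
        a = cross_validate_signature(["g0", "g1"], expr, clin, cfg)
        b = cross_validate_signature(["g0", "g1"], expr, clin, cfg)
        pd.testing.assert_frame_equal(a, b)
        assert a["c_index_test"].median() > 0.6    # g0 carries real signal

    def test_noise_signature_near_half(self, survival_cohort):
        expr, clin = survival_cohort
        cfg = GreedyConfig(n_reps=10, seed=13)
        cv = cross_validate_signature(["g20", "g21"], expr, clin, cfg,
                                      clinical_cols=[])
        assert 0.4 <= cv["c_index_test"].median() <= 0.6

    def test_benefit_requires_untreated(self, survival_cohort):
        expr, clin = survival_cohort
        allt = clin.copy()
        allt["adjc"] = 1
        with pytest.raises(ValueError, match="untreated"):
            benefit_transfer(["g0"], expr, allt)

    def test_benefit_null_genes_hr_near_one(self, survival_cohort):
        expr, clin = survival_cohort
        hrs = []
        rng = np.random.default_rng(21)
        for _ in range(5):
            c = clin.copy()
            c["adjc"] = rng.integers(0, 2, len(c))
            km, auc, rs = benefit_transfer(["g30", "g31"], expr, c)
            if km.hazard_ratio is not None:
                hrs.append(km.hazard_ratio)
        assert 0.5 <= np.median(hrs) <= 2.0
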