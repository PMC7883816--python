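import filecmp
import json

import numpy as np
import pandas as pd
import pytest

from dysreg import io as dio
from dysreg.containers import ConditionalGRN
from dysreg.coxmodel import fit_cox
from dysreg.dyscall import identify_dysregulations, moderated_t_test
from dysreg.intensity import estimate_intensities
from dysreg.simdata import (build_dataset, generate_grn, make_fixture,
                            simulate_expression, simulate_survival,
                            simulate_tumor_cohort)


class TestGenerateGrn:
    def test_no_dysregulation_means_equal_betas(self, rng):
        truth = generate_grn(5, 10, 2, 0.0, 1.0, rng)
        assert (truth.links["beta_normal"] == truth.links["beta_tumor"]).all()

    def test_link_count(self, rng):
        truth = generate_grn(8, 10, 3, 0.1, 1.0, rng)
        assert len(truth.links) == 30

    def test_sign_invariant_over_draws(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            truth = generate_grn(6, 12, 2, 0.25, 1.0, rng)
            inter = truth.intercepts.set_index("target")
            dys = truth.links[truth.links["dysregulated"]]
            for _, row in dys.iterrows():
                delta = row["beta_tumor"] - row["beta_normal"]
                shift = inter.loc[row["target"], "tumor"] - \
                    inter.loc[row["target"], "normal"]
                assert np.sign(delta) == np.sign(shift)
                assert truth.deg_flags[row["target"]]
            stable = truth.links[~truth.links["dysregulated"]]
            assert (stable["beta_normal"] == stable["beta_tumor"]).all()

    def test_too_many_links_raises(self, rng):
        with pytest.raises(ValueError):
            generate_grn(3, 5, 4, 0.0, 1.0, rng)


class TestSimulateExpression:
    def test_noiseless_single_link_exact(self):
        rng = np.random.default_rng(1)
        truth = generate_grn(1, 1, 1, 0.0, 1.0, rng)
        em = simulate_expression(truth, 10, 0.0, np.random.default_rng(2))
        beta = truth.links["beta_normal"].iloc[0]
        inter = truth.intercepts.set_index("target").loc[truth.targets[0], "normal"]
        norm = em.subset_condition("normal").values
        resid = norm.loc[truth.targets[0]] - inter - beta * norm.loc[truth.tfs[0]]
        assert np.allclose(resid, 0.0, atol=1e-12)

    def test_regression_recovers_planted_betas(self):
        rng = np.random.default_rng(3)
        truth = generate_grn(6, 10, 2, 0.0, 1.0, rng)
        em = simulate_expression(truth, 500, 0.3, np.random.default_rng(4))
        tum = em.subset_condition("tumor").values
        for tg in truth.targets[:5]:
            tfs = truth.links.loc[truth.links["target"] == tg, "tf"].tolist()
            X = np.column_stack([tum.loc[tf] for tf in tfs])
            X = np.column_stack([np.ones(len(tum.columns)), X])
            y = tum.loc[tg].to_numpy()
            coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
            planted = truth.links.set_index(["target", "tf"])
            for j, tf in enumerate(tfs):
                assert abs(coefs[j + 1] - planted.loc[(tg, tf), "beta_tumor"]) < 0.05

    def test_pairing_and_conditions(self, rng):
        truth = generate_grn(3, 4, 1, 0.0, 1.0, rng)
        em = simulate_expression(truth, 8, 0.2, np.random.default_rng(5))
        assert len(em.pairing) == 8
        for t, n in em.pairing.items():
            assert em.condition[t] == "tumor" and em.condition[n] == "normal"


class TestSimulateSurvival:
    def cohort(self, coef, n=300, censor=0.3, seed=6):
        rng = np.random.default_rng(seed)
        truth = generate_grn(4, 6, 1, 0.0, 1.0, rng)
        truth.hazard_coefs = {truth.targets[0]: coef}
        truth.censor_rate = censor
        em = simulate_tumor_cohort(truth, n, 0.3, rng)
        clin = simulate_survival(em, truth, rng=rng)
        return truth, em, clin

    def test_null_hazard_c_half(self):
        truth, em, clin = self.cohort(0.0)
        c = fit_cox(em.values.loc[[truth.targets[1]]].to_numpy().T,
                    clin["os_time"].to_numpy(),
                    clin["os_event"].to_numpy().astype(int)).c_index
        assert abs(c - 0.5) < 0.06

    def test_single_gene_coefficient_recovered(self):
        errs = []
        for seed in range(8):
            truth, em, clin = self.cohort(1.0, seed=seed)
            g = truth.targets[0]
            fit = fit_cox(em.values.loc[[g]].to_numpy().T,
                          clin["os_time"].to_numpy(),
                          clin["os_event"].to_numpy().astype(int))
            errs.append(abs(fit.coef[0] - 1.0))
        assert np.median(errs) < 0.15

    def test_censoring_rate_calibrated(self):
        for target_rate in (0.2, 0.3, 0.5):
            truth, em, clin = self.cohort(0.5, censor=target_rate, seed=9)
            realized = 1.0 - clin["os_event"].mean()
            assert abs(realized - target_rate) < 0.05

    def test_bad_censor_rate_raises(self):
        truth, em, _ = self.cohort(0.0)
        with pytest.raises(ValueError):
            simulate_survival(em, truth, censor_rate=1.5)


class TestFixtures:
    def test_fixture_files_validate_against_io_schemas(self, tmp_path):
        ds = make_fixture("tiny", 11, tmp_path)
        em = dio.read_expression_matrix(tmp_path / "expr.tsv",
                                        tmp_path / "labels.tsv")
        assert em.values.shape == ds.expr.values.shape
        assert em.pairing == ds.expr.pairing
        clin = dio.read_clinical_tsv(tmp_path / "clinical.tsv")
        assert list(clin.columns) == ["os_time", "os_event", "rfs_time",
                                      "rfs_event", "age", "gender", "stage",
                                      "adjc", "adjc_type"]
        ref = dio.read_edges_tsv(tmp_path / "refgrn.tsv")
        assert len(ref) == len(ds.truth.links)
        with open(tmp_path / "truth.json") as fh:
            truth = json.load(fh)
        assert truth["tfs"] == ds.truth.tfs

    def test_same_seed_byte_identical(self, tmp_path):
        make_fixture("tiny", 17, tmp_path / "a")
        make_fixture("tiny", 17, tmp_path / "b")
        for name in ("expr.tsv", "labels.tsv", "clinical.tsv", "refgrn.tsv",
                     "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_planted_calls_recovered_in_large_sample_limit(self):
        # near-infinite-n check: with n=1000 pairs every planted
        # dysregulation should satisfy all three criteria
        ds_truth = None
        rng = np.random.default_rng(23)
        truth = generate_grn(10, 40, 2, 8 / 80, 1.0, rng)
        em = simulate_expression(truth, 1000, 0.5, rng)
        edges = {}
        for _, r in truth.links.iterrows():
            edges.setdefault(r["target"], set()).add(r["tf"])
        gn = ConditionalGRN("normal", edges)
        gt = ConditionalGRN("tumor", {k: set(v) for k, v in edges.items()})
        intens = estimate_intensities(em, gn, gt, seed=0)
        degs = moderated_t_test(em)
        calls = {(z.tf, z.target)
                 for z in identify_dysregulations(intens, degs)}
        planted = truth.dysregulated_pairs()
        recall = len(calls & planted) / len(planted)
        assert recall >= 0.95
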