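import numpy as np
import pandas as pd
import pytest

from dysreg.containers import PrepConfig, RawExpressionTable
from dysreg.prep import (collapse_probes, impute_knn, log2_transform,
                         mask_and_filter, quantile_normalize)


def table(values, platform="rnaseq_tpm", index=None, columns=None):
    df = pd.DataFrame(values, index=index, columns=columns)
    df.index = [f"g{i}" for i in range(len(df))] if index is None else index
    df.columns = [f"s{i}" for i in range(df.shape[1])] if columns is None else columns
    return RawExpressionTable(df.astype(float), platform=platform)


class TestMaskAndFilter:
    def test_gene_dropped_when_missing_fraction_exceeds_cutoff(self):
        t = table([[5, 0.2, 8], [5, 6, 8]])
        out = mask_and_filter(t, PrepConfig())
        assert list(out.values.index) == ["g1"]
        assert out.n_genes_removed == 1
        assert not out.values.isna().any().any()

    def test_boundary_fraction_is_strict(self):
        # 2 missing out of 10 samples is exactly 20%: kept
        row = [5.0] * 8 + [0.5, 0.5]
        out = mask_and_filter(table([row]), PrepConfig())
        assert list(out.values.index) == ["g0"]
        assert int(out.values.isna().sum().sum()) == 2

    def test_all_removed_raises(self):
        with pytest.raises(ValueError, match="no genes survive"):
            mask_and_filter(table([[0.1, 0.2, 0.3]]), PrepConfig())

    def test_never_increases_genes_and_respects_fraction(self, rng):
        vals = rng.uniform(0, 10, size=(40, 12))
        out = mask_and_filter(table(vals), PrepConfig())
        assert out.values.shape[0] <= 40
        assert (out.values.isna().mean(axis=1) <= 0.2 + 1e-12).all()


class TestImputeKnn:
    def test_identity_on_complete(self):
        t = table([[1, 2, 3], [4, 5, 6], [9, 9, 9], [2, 1, 5]])
        out = impute_knn(t, k=2)
        assert out.values.equals(t.values)

    def test_k_equals_all_donors(self):
        vals = pd.DataFrame([[1.0, 2.0, np.nan],
                             [1.1, 2.1, 3.0],
                             [0.9, 1.9, 5.0]],
                            index=["A", "B", "C"], columns=["s0", "s1", "s2"])
        out = impute_knn(RawExpressionTable(vals), k=2)
        assert out.values.loc["A", "s2"] == pytest.approx(4.0)

    def test_matches_bruteforce_oracle(self, rng):
        n_genes, n_samp, k = 20, 10, 5
        vals = rng.uniform(1, 10, (n_genes, n_samp))
        mask = rng.uniform(size=vals.shape) < 0.05
        mask[:, 0] = False          # keep every gene observed somewhere
        masked = np.where(mask, np.nan, vals)
        t = table(masked)
        out = impute_knn(t, k=k).values.to_numpy()

        # independent loop-based oracle with the same donor rules
        ref = masked.copy()
        for gi in range(n_genes):
            for si in range(n_samp):
                if not np.isnan(masked[gi, si]):
                    continue
                dists = []
                for gj in range(n_genes):
                    if gj == gi or np.isnan(masked[gj, si]):
                        continue
                    shared = ~np.isnan(masked[gi]) & ~np.isnan(masked[gj])
                    if shared.sum() < 3:
                        continue
                    d = np.sqrt(np.mean((masked[gi, shared] - masked[gj, shared]) ** 2))
                    dists.append((d, gj))
                dists.sort(key=lambda x: x[0])
                donors = [gj for _, gj in dists[:k]]
                ref[gi, si] = np.mean([masked[gj, si] for gj in donors])
        assert np.allclose(out, ref, atol=1e-12, equal_nan=False)

    def test_preserves_observed_bit_for_bit(self, rng):
        vals = rng.uniform(1, 10, (15, 8))
        mask = np.zeros_like(vals, dtype=bool)
        mask[3, 4] = mask[7, 1] = True
        masked = np.where(mask, np.nan, vals)
        out = impute_knn(table(masked), k=4).values.to_numpy()
        assert np.array_equal(out[~mask], masked[~mask])

    def test_all_missing_gene_raises(self):
        with pytest.raises(ValueError, match="zero observed"):
            impute_knn(table([[np.nan, np.nan], [1, 2], [3, 4]]), k=1)


class TestLog2Transform:
    def test_values(self):
        out = log2_transform(table([[1, 8], [2, 4]]))
        assert np.allclose(out.to_numpy(), [[0, 3], [1, 2]])

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError, match="non-positive"):
            log2_transform(table([[0.0, 1.0]], platform="microarray"))


class TestCollapseProbes:
    def test_multigene_probe_removed_and_highest_mean_kept(self):
        t = table([[7.0, 7.4], [9.0, 9.0], [5.0, 5.2]], platform="microarray",
                  index=["P1", "P2", "P3"])
        pm = {"P1": {"A"}, "P2": {"A", "B"}, "P3": {"A"}}
        out = collapse_probes(t, pm)
        assert list(out.values.index) == ["A"]
        assert out.values.loc["A", "s0"] == 7.0       # P1 mean 7.2 beats P3 5.1

    def test_one_probe_per_gene_is_relabel(self):
        t = table([[1.0, 2.0], [3.0, 4.0]], platform="microarray",
                  index=["P1", "P2"])
        out = collapse_probes(t, {"P1": {"B"}, "P2": {"A"}})
        assert list(out.values.index) == ["A", "B"]
        assert out.values.loc["B"].tolist() == [1.0, 2.0]

    def test_output_gene_set_is_single_gene_probes(self, rng):
        probes = [f"P{i}" for i in range(10)]
        pm = {p: ({f"G{i}"} if i % 3 else {f"G{i}", "X"}) for i, p in enumerate(probes)}
        t = table(rng.uniform(1, 10, (10, 4)), platform="microarray", index=probes)
        out = collapse_probes(t, pm)
        expected = {f"G{i}" for i in range(10) if i % 3}
        assert set(out.values.index) == expected

    def test_empty_map_raises(self):
        t = table([[1.0, 2.0]], platform="microarray", index=["P1"])
        with pytest.raises(ValueError, match="empty probe map"):
            collapse_probes(t, {})


class TestQuantileNormalize:
    def test_mean_of_order_statistics(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [3.0, 4.0, 5.0]})
        out = quantile_normalize(df)
        assert np.allclose(np.sort(out["a"]), [2, 3, 4])
        assert np.allclose(np.sort(out["b"]), [2, 3, 4])
        # rank order preserved per column
        assert out["a"].tolist() == sorted(out["a"])

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        assert np.allclose(quantile_normalize(df).to_numpy(), df.to_numpy())

    def test_columns_share_sorted_values(self, rng):
        df = pd.DataFrame(rng.uniform(0, 10, (50, 4)))
        out = quantile_normalize(df).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            assert np.allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.uniform(0, 10, (30, 3)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_single_sample_warns(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = quantile_normalize(df)
        assert out.equals(df)
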