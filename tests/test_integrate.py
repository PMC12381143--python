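import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stratomics.containers import ReferenceTables
from stratomics.integrate import (
    co_enrichment_map,
    compartment_means,
    halflife_group_test,
    kruskal_dunn,
    population_correlation,
    profile_correlation_classify,
    zscore_fold_changes,
)


def strata_meta(n_reps=2):
    rows = []
    for c in ("SO", "SP", "SR", "SLM"):
        for r in range(1, n_reps + 1):
            rows.append((f"{c}_r{r}", c, r, "tissue"))
    return pd.DataFrame(rows, columns=["sample_id", "compartment", "replicate",
                                       "fraction"]).set_index("sample_id")


class TestPopulationCorrelation:
    def test_shifted_copy_gives_r_one(self):
        meta = strata_meta()
        rng = np.random.default_rng(0)
        rna = pd.DataFrame(rng.normal(10, 2, size=(30, 8)),
                           columns=meta.index)
        prot = rna + 5.0
        out = population_correlation(rna, prot, meta).set_index("scope")
        np.testing.assert_allclose(out["r"], 1.0, atol=1e-12)

    def test_negated_copy_gives_r_minus_one(self):
        meta = strata_meta()
        rng = np.random.default_rng(1)
        rna = pd.DataFrame(rng.normal(10, 2, size=(30, 8)),
                           columns=meta.index)
        out = population_correlation(rna, -rna, meta).set_index("scope")
        np.testing.assert_allclose(out["r"], -1.0, atol=1e-12)

    def test_hand_computed_four_pairs(self):
        # r = 6.5 / sqrt(5 * 8.75) = 0.98270762982399...
        meta = strata_meta(n_reps=1)
        rna = pd.DataFrame([[1.0], [2.0], [3.0], [4.0]],
                           columns=["SO_r1"]).reindex(
            columns=meta.index)
        prot = pd.DataFrame([[1.0], [2.0], [3.0], [5.0]],
                            columns=["SO_r1"]).reindex(columns=meta.index)
        out = population_correlation(rna, prot, meta).set_index("scope")
        np.testing.assert_allclose(out.loc["SO", "r"],
                                   6.5 / np.sqrt(5 * 8.75), atol=1e-12)

    def test_too_few_pairs_flagged(self):
        meta = strata_meta(n_reps=1)
        rna = pd.DataFrame(np.ones((2, 4)), columns=meta.index)
        out = population_correlation(rna, rna, meta)
        assert not out["defined"].any()


class TestProfileClassification:
    def test_identical_profiles_positive(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"],
                         columns=list("abcd"))
        rec = profile_correlation_classify(m, m.copy())
        assert rec.loc[0, "class"] == "positive"
        np.testing.assert_allclose(rec.loc[0, "r"], 1.0)

    def test_reversed_monotone_profile_negative(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"],
                         columns=list("abcd"))
        rev = pd.DataFrame([[4.0, 3.0, 2.0, 1.0]], index=["g"],
                           columns=list("abcd"))
        rec = profile_correlation_classify(m, rev)
        assert rec.loc[0, "class"] == "negative"

    def test_flat_profile_is_neither_and_flagged(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["g"],
                         columns=list("abcd"))
        other = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"],
                             columns=list("abcd"))
        rec = profile_correlation_classify(m, other)
        assert rec.loc[0, "class"] == "neither"
        assert not rec.loc[0, "defined"]
        assert np.isnan(rec.loc[0, "r"])

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        rm = pd.DataFrame(rng.normal(size=(200, 4)))
        pm = pd.DataFrame(rng.normal(size=(200, 4)))
        loose = profile_correlation_classify(rm, pm, r_pos=0.7, r_neg=-0.7)
        strict = profile_correlation_classify(rm, pm, r_pos=0.9, r_neg=-0.9)
        assert (loose["class"] == "positive").sum() >= \
            (strict["class"] == "positive").sum()

    def test_gene_absent_from_one_side_skipped(self):
        rm = pd.DataFrame(np.random.default_rng(3).normal(size=(3, 4)),
                          index=["a", "b", "c"])
        pm = rm.loc[["a", "b"]]
        rec = profile_correlation_classify(rm, pm)
        assert set(rec["gene"]) == {"a", "b"}


class TestZScores:
    def test_hand_computed_row(self):
        z, _ = zscore_fold_changes(pd.DataFrame([[1.0, 2.0, 3.0, 4.0]],
                                                columns=list("abcd")))
        np.testing.assert_allclose(
            z[list("abcd")].to_numpy().ravel(),
            [-1.161895, -0.387298, 0.387298, 1.161895], atol=1e-6)

    def test_constant_row_zeroed_and_flagged(self):
        z, _ = zscore_fold_changes(pd.DataFrame([[2.0, 2.0, 2.0]],
                                                columns=list("abc")))
        np.testing.assert_allclose(z[list("abc")].to_numpy(), 0.0)
        assert z["flat_profile"].iloc[0]

    def test_rows_standardized(self):
        rng = np.random.default_rng(4)
        lfc = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        z, _ = zscore_fold_changes(lfc)
        vals = z[list("abcd")].to_numpy()
        np.testing.assert_allclose(vals.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(vals.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_single_stratum_rejected(self):
        with pytest.raises(ValueError):
            zscore_fold_changes(pd.DataFrame([[1.0]]))


class TestKruskalDunn:
    def test_identical_groups_zero(self):
        g = {"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}
        res = kruskal_dunn(g)
        np.testing.assert_allclose(res.H, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.dunn["Z"], 0.0, atol=1e-12)

    def test_hand_computed_example(self):
        # ranks 1..6, group mean ranks 1.5 / 3.5 / 5.5 -> H = 32/7
        res = kruskal_dunn({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        np.testing.assert_allclose(res.H, 32.0 / 7.0, atol=1e-10)
        np.testing.assert_allclose(res.pvalue, np.exp(-res.H / 2), atol=1e-10)
        assert res.df == 2

    def test_matches_scipy_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            sizes = rng.integers(2, 12, size=rng.integers(2, 5))
            data = [np.round(rng.normal(size=n), 1) for n in sizes]  # ties
            res = kruskal_dunn({f"g{i}": d for i, d in enumerate(data)})
            H, p = stats.kruskal(*data)
            np.testing.assert_allclose(res.H, H, rtol=1e-10)
            np.testing.assert_allclose(res.pvalue, p, rtol=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn({"a": [1.0], "b": [2.0, 3.0]})

    def test_bonferroni_capped_at_one(self):
        res = kruskal_dunn({"a": [1, 2, 4], "b": [2, 3, 1], "c": [3, 1, 2]})
        assert (res.dunn["p_adjusted"] <= 1.0).all()
        assert (res.dunn["p_adjusted"] >= res.dunn["pvalue"] - 1e-12).all()


class TestHalfLifeTest:
    def _records(self, classes):
        return pd.DataFrame({"gene": [f"g{i}" for i in range(len(classes))],
                             "class": classes,
                             "r": 0.0, "n_profile_points": 4})

    def test_directional_difference_detected(self):
        rng = np.random.default_rng(6)
        classes = ["positive"] * 30 + ["negative"] * 30 + ["neither"] * 30
        rec = self._records(classes)
        hl = np.concatenate([np.exp(rng.normal(3.5, 0.3, 30)),
                             np.exp(rng.normal(5.0, 0.3, 30)),
                             np.exp(rng.normal(4.2, 0.3, 30))])
        ref = ReferenceTables(half_life=pd.Series(hl, index=rec["gene"]))
        res = halflife_group_test(rec, ref)
        assert res.pvalue < 1e-6
        pv = res.dunn.set_index(["group_a", "group_b"])
        assert pv.loc[("positive", "negative"), "Z"] < 0  # shorter half-lives

    def test_join_count_reported(self):
        rec = self._records(["positive"] * 3 + ["negative"] * 3)
        hl = pd.Series([1.0, 2, 3, 4], index=["g0", "g1", "g3", "g4"])
        ref = ReferenceTables(half_life=hl)
        res = halflife_group_test(rec, ref)
        assert res.n_joined == 4


class TestCoEnrichment:
    def _calls(self, rows, molecule):
        return pd.DataFrame(rows, columns=["feature", "compartment",
                                           "direction"]).assign(
            molecule=molecule)

    def test_single_gene_cell(self):
        m = self._calls([("g", "SP", "enriched")], "mrna")
        p = self._calls([("g", "SLM", "enriched")], "protein")
        table = co_enrichment_map(m, p)
        assert table.counts.loc["SP", "SLM"] == 1
        assert table.counts.to_numpy().sum() == 1

    def test_translatome_proportions(self):
        genes = [f"g{i}" for i in range(10)]
        m = self._calls([(g, "SLM", "enriched") for g in genes], "mrna")
        p = self._calls([(g, "SLM", "enriched") for g in genes], "protein")
        labels = pd.Series(["neuropil"] * 4 + ["soma"] + ["unbiased"] * 5,
                           index=genes)
        table = co_enrichment_map(m, p, labels)
        cell = table.cells.iloc[0]
        np.testing.assert_allclose(
            [cell["prop_neuropil"], cell["prop_soma"], cell["prop_unbiased"]],
            [0.4, 0.1, 0.5])
        np.testing.assert_allclose(
            cell[["prop_soma", "prop_neuropil", "prop_unbiased"]].sum(), 1.0,
            atol=1e-10)

    def test_multi_compartment_fanout_matches_hand_enumeration(self):
        # 12 planted genes; g0 is mRNA-enriched in SP and SR and its protein
        # in SLM -> contributes to both (SP, SLM) and (SR, SLM)
        m_rows = [("g0", "SP", "enriched"), ("g0", "SR", "enriched")]
        p_rows = [("g0", "SLM", "enriched")]
        for i in range(1, 6):
            m_rows.append((f"g{i}", "SP", "enriched"))
            p_rows.append((f"g{i}", "SP", "enriched"))
        for i in range(6, 10):
            m_rows.append((f"g{i}", "SLM", "enriched"))
            p_rows.append((f"g{i}", "SLM", "enriched"))
        for i in range(10, 12):  # depleted records must not count
            m_rows.append((f"g{i}", "SO", "depleted"))
            p_rows.append((f"g{i}", "SO", "depleted"))
        table = co_enrichment_map(self._calls(m_rows, "mrna"),
                                  self._calls(p_rows, "protein"))
        assert table.counts.loc["SP", "SLM"] == 1
        assert table.counts.loc["SR", "SLM"] == 1
        assert table.counts.loc["SP", "SP"] == 5
        assert table.counts.loc["SLM", "SLM"] == 4
        assert table.counts.loc["SO", "SO"] == 0
        assert table.counts.to_numpy().sum() == 11
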