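import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from stratomics.containers import DesignError
from stratomics.differential import (
    DispersionFit,
    bh_adjust,
    call_enrichment,
    estimate_dispersions,
    filter_valid_values,
    fit_variance_prior,
    moderated_lm_de,
    nb_wald_de,
    trigamma_inverse,
)

from conftest import make_matrix


class TestBH:
    def test_hand_example_all_tied(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_hand_example_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.005, 0.04, 0.05]),
                                   [0.015, 0.05, 0.05])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_nan_propagated(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    def test_q_at_least_p_and_permutation_invariant(self, ps):
        p = np.array(ps)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        p = rng.random(200)
        np.testing.assert_allclose(bh_adjust(p),
                                   multipletests(p, method="fdr_bh")[1],
                                   rtol=1e-12)


class TestValidValueFilter:
    def test_no_missing_identity(self):
        mat = make_matrix(np.ones((4, 6)))
        groups = {"a": mat.sample_ids[:3], "b": mat.sample_ids[3:]}
        assert filter_valid_values(mat, groups).feature_ids == mat.feature_ids

    def test_fully_missing_group_excludes_feature(self):
        vals = np.ones((2, 6))
        vals[0, 3:] = np.nan
        mat = make_matrix(vals)
        groups = {"a": mat.sample_ids[:3], "b": mat.sample_ids[3:]}
        assert filter_valid_values(mat, groups).feature_ids == ["g1"]

    def test_crafted_missingness_hand_enumeration(self):
        vals = np.ones((5, 6))
        vals[0, :] = np.nan                    # missing everywhere -> drop
        vals[1, [0, 1, 2]] = np.nan            # group a empty -> drop
        vals[2, [0, 1, 3, 4]] = np.nan         # 1 left in each group -> keep
        vals[3, [5]] = np.nan                  # keep
        mat = make_matrix(vals)
        groups = {"a": mat.sample_ids[:3], "b": mat.sample_ids[3:]}
        assert filter_valid_values(mat, groups, min_quant=1).feature_ids == \
            ["g2", "g3", "g4"]
        # across all samples instead: row 1 has 3 values -> kept
        assert filter_valid_values(mat, groups, min_quant=2,
                                   by_contrast=False).feature_ids == \
            ["g1", "g2", "g3", "g4"]

    def test_empty_group_rejected(self):
        mat = make_matrix(np.ones((2, 4)))
        with pytest.raises(DesignError):
            filter_valid_values(mat, {"a": [], "b": mat.sample_ids})


def _counts_matrix(counts, compartments, replicates):
    return make_matrix(counts, kind="rna_counts", compartments=compartments,
                       replicates=replicates)


class TestNBWald:
    def test_identical_groups_give_null_result(self):
        row = [40, 50, 60, 40, 50, 60]
        counts = np.array([row, [c * 2 for c in row]])
        mat = _counts_matrix(counts, ["SO"] * 3 + ["SP"] * 3, [1, 2, 3, 1, 2, 3])
        de = nb_wald_de(mat, scheme="one_vs_rest")
        one = de[de["contrast"] == "SO_vs_rest"]
        np.testing.assert_allclose(one["log2fc"], 0.0, atol=1e-6)
        np.testing.assert_allclose(one["pvalue"], 1.0, atol=1e-6)

    def test_large_count_limit_matches_poisson_z(self):
        # single informative gene at huge counts and vanishing dispersion:
        # the NB Wald z converges to the two-sample Poisson z statistic
        y1 = np.array([5000, 5100, 4900])
        y2 = np.array([6000, 6100, 5900])
        counts = np.vstack([np.concatenate([y1, y2]),
                            np.full(6, 5000)])
        mat = _counts_matrix(counts, ["SO"] * 3 + ["SP"] * 3,
                             [1, 2, 3, 1, 2, 3])
        sf = pd.Series(1.0, index=mat.sample_ids)
        disp = DispersionFit(
            alpha=pd.Series(1e-8, index=mat.feature_ids),
            alpha_genewise=pd.Series(1e-8, index=mat.feature_ids),
            trend_coef=(1e-8, 0.0),
            base_mean=pd.Series(counts.mean(axis=1), index=mat.feature_ids))
        de = nb_wald_de(mat, scheme="one_vs_rest", size_factors=sf,
                        include_replicate=False, dispersions=disp)
        z = de[(de["feature"] == "g0")
               & (de["contrast"] == "SO_vs_rest")]["stat"].iloc[0]
        beta_pois = np.log(y1.mean() / y2.mean())
        se_pois = np.sqrt(1 / y1.sum() + 1 / y2.sum())
        assert abs(z - beta_pois / se_pois) / abs(beta_pois / se_pois) < 0.02

    def test_all_zero_gene_flagged_untestable(self):
        counts = np.vstack([np.zeros(6, dtype=int), np.full(6, 50)])
        mat = _counts_matrix(counts, ["SO"] * 3 + ["SP"] * 3, [1, 2, 3, 1, 2, 3])
        de = nb_wald_de(mat)
        g0 = de[de["feature"] == "g0"]
        assert (~g0["tested"]).all()
        assert g0["pvalue"].isna().all()

    def test_dispersion_recovery_order_of_magnitude(self):
        rng = np.random.default_rng(9)
        alpha = 0.1
        mu = 200.0
        counts = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu),
                                       size=(400, 8)).astype(float)
        norm = pd.DataFrame(counts, columns=[f"s{i}" for i in range(8)])
        fit = estimate_dispersions(norm, pd.Series(
            ["a"] * 4 + ["b"] * 4, index=norm.columns))
        assert 0.05 < fit.alpha.median() < 0.2


class TestModeratedLM:
    def test_identical_group_values_null(self):
        vals = np.tile([[10.0, 11.0, 12.0, 10.0, 11.0, 12.0]], (5, 1))
        vals = vals + np.arange(5)[:, None]
        mat = make_matrix(vals, compartments=["SO"] * 3 + ["SP"] * 3,
                          replicates=[1, 2, 3, 1, 2, 3])
        de = moderated_lm_de(mat, scheme="one_vs_rest",
                             include_replicate=False)
        one = de[de["contrast"] == "SO_vs_rest"]
        np.testing.assert_allclose(one["log2fc"], 0.0, atol=1e-10)
        np.testing.assert_allclose(one["pvalue"], 1.0, atol=1e-10)

    def test_equal_variances_collapse_to_z_test(self):
        # identical residual patterns across proteins -> d0 = inf and the
        # moderated t becomes a z-test with the common variance
        base = np.array([0.0, 1.0, 0.0, 1.0, 2.0, 3.0])
        vals = np.vstack([base + i for i in range(6)])
        vals[3:, 2:] += 1.0  # some true effects, same residuals
        mat = make_matrix(vals, compartments=["SO"] * 2 + ["SP"] * 4,
                          replicates=[1, 2, 1, 2, 3, 4])
        de = moderated_lm_de(mat, scheme="one_vs_rest",
                             include_replicate=False)
        assert np.isinf(de["prior_df"]).all()
        one = de[de["contrast"] == "SO_vs_rest"]
        z = one["log2fc"] / one["se"]
        np.testing.assert_allclose(one["pvalue"],
                                   2 * stats.norm.sf(np.abs(z)), rtol=1e-10)

    def test_prior_recovery_within_20_percent(self):
        rng = np.random.default_rng(10)
        d0, s0 = 4.0, 0.05
        n, d = 5000, 6
        sigma2 = d0 * s0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        d0_hat, s0_hat = fit_variance_prior(s2, np.full(n, d))
        assert abs(d0_hat - d0) / d0 < 0.2
        assert abs(s0_hat - s0) / s0 < 0.2

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma
        for y in (0.1, 1.0, 5.0, 40.0):
            x = float(polygamma(1, y))
            assert abs(trigamma_inverse(x) - y) / y < 1e-6


class TestEnrichmentCalls:
    def _de(self, rows):
        return pd.DataFrame(rows, columns=["feature", "contrast", "log2fc",
                                           "padj"])

    def test_single_significant_pairwise_contrast_is_no_call(self):
        de = self._de([("g", "CA1_vs_CA23", 0.5, 0.001),
                       ("g", "CA1_vs_DG", 0.5, 0.5),
                       ("g", "CA23_vs_CA1", -0.5, 0.001),
                       ("g", "CA23_vs_DG", 0.0, 0.9),
                       ("g", "DG_vs_CA1", -0.5, 0.5),
                       ("g", "DG_vs_CA23", 0.0, 0.9)])
        calls = call_enrichment(de, "pairwise_intersection", "mrna",
                                alpha=0.01)
        assert len(calls) == 0

    def test_both_contrasts_significant_gives_enriched_call(self):
        de = self._de([("g", "CA1_vs_CA23", 0.5, 0.005),
                       ("g", "CA1_vs_DG", 0.5, 0.005),
                       ("g", "CA23_vs_CA1", -0.5, 0.005),
                       ("g", "CA23_vs_DG", 0.1, 0.9),
                       ("g", "DG_vs_CA1", -0.5, 0.005),
                       ("g", "DG_vs_CA23", -0.1, 0.9)])
        calls = call_enrichment(de, "pairwise_intersection", "mrna",
                                alpha=0.01)
        assert calls.to_dict("records") == [{
            "feature": "g", "molecule": "mrna", "compartment": "CA1",
            "direction": "enriched",
            "contrasts": "CA1_vs_CA23;CA1_vs_DG"}]

    def test_one_vs_rest_depletion_direction(self):
        de = self._de([("g", "SO_vs_rest", -0.5, 0.001),
                       ("g", "SP_vs_rest", 0.05, 0.001),
                       ("g", "SR_vs_rest", 0.2, 0.2),
                       ("g", "SLM_vs_rest", 0.5, 0.001)])
        calls = call_enrichment(de, "one_vs_rest", "protein", alpha=0.01)
        got = {(r.compartment, r.direction) for r in calls.itertuples()}
        # SP fails lfc_min, SR fails alpha
        assert got == {("SO", "depleted"), ("SLM", "enriched")}

    def test_antisymmetry(self, tissue_bundle):
        rna, _prot, _truth = tissue_bundle
        de = nb_wald_de(rna, scheme="one_vs_rest")
        calls = call_enrichment(de, "one_vs_rest", "mrna", alpha=0.05)
        dup = calls.groupby(["feature", "compartment"])["direction"].nunique()
        assert (dup <= 1).all()

    def test_missing_contrast_rejected(self):
        de = self._de([("g", "SO_vs_rest", 0.5, 0.001)])
        de2 = pd.concat([de, self._de([("g", "SP_vs_SO", 0.1, 0.5)])])
        with pytest.raises(DesignError):
            call_enrichment(de2, "one_vs_rest", "mrna")


def test_null_pvalues_roughly_uniform(tissue_bundle):
    """On simulated null genes the Wald p-value distribution is flat."""
    rna, _prot, truth = tissue_bundle
    de = nb_wald_de(rna, scheme="one_vs_rest")
    null_genes = truth.genes.index[truth.genes["mrna_compartment"] == ""]
    p = de[de["feature"].isin(null_genes)
           & (de["contrast"] == "SO_vs_rest")]["pvalue"].dropna()
    assert stats.kstest(p, "uniform").pvalue > 0.01
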