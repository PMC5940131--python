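"""Moderated-t differential expression: OLS stage, variance moderation,
BH adjustment, DEG calling and interaction scans."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

import crstrains as cs
from crstrains.diffexpr import fit_gene_linear_models

from _oracles import bh_step_up


def _two_group(n_per=8, genes=50, seed=0, shift=0.0, sd=0.5):
    rng = np.random.default_rng(seed)
    ctl = rng.normal(8.0, sd, (genes, n_per))
    cr = rng.normal(8.0 + shift, sd, (genes, n_per))
    mat = pd.DataFrame(np.hstack([ctl, cr]),
                       index=[f"g{i:03d}" for i in range(genes)],
                       columns=[f"s{j}" for j in range(2 * n_per)])
    diets = ["CTL"] * n_per + ["CR"] * n_per
    return mat, diets


class TestLinearFit:
    def test_group_mean_difference_recovered_exactly(self):
        # CTL mean 8.0, CR mean 9.0 per gene, nonzero residuals
        rng = np.random.default_rng(0)
        eps = rng.normal(0, 0.1, (12, 2))
        rows = np.hstack([8.0 + eps, 8.0 - eps, 9.0 + eps, 9.0 - eps])
        mat = pd.DataFrame(rows, index=[f"g{i}" for i in range(12)],
                           columns=[f"s{j}" for j in range(8)])
        fit = cs.cr_contrast(mat, ["CTL"] * 4 + ["CR"] * 4)
        np.testing.assert_allclose(fit["log2fc"], 1.0, atol=1e-12)
        np.testing.assert_allclose(fit["fc"], 2.0, atol=1e-12)

    def test_sigma2_matches_direct_residual_oracle(self):
        mat, diets = _two_group(genes=30, seed=1)
        design = pd.DataFrame({"intercept": 1.0,
                               "diet": [0.0] * 8 + [1.0] * 8},
                              index=mat.columns)
        fit = fit_gene_linear_models(mat, design)
        assert fit.df_residual == 14
        for g in ["g000", "g017"]:
            y = mat.loc[g].to_numpy()
            rss = ((y[:8] - y[:8].mean()) ** 2).sum() + \
                ((y[8:] - y[8:].mean()) ** 2).sum()
            assert fit.sigma2[g] == pytest.approx(rss / 14)

    def test_zero_residuals_flagged_degenerate(self):
        mat = pd.DataFrame(np.tile([8.0, 8.0, 9.0, 9.0, 9.0, 8.0], (15, 1)),
                           index=[f"g{i}" for i in range(15)],
                           columns=[f"s{j}" for j in range(6)])
        design = pd.DataFrame({"intercept": 1.0,
                               "diet": [0, 0, 1, 1, 1, 0]},
                              index=mat.columns, dtype=float)
        fit = fit_gene_linear_models(mat, design)
        np.testing.assert_allclose(fit.sigma2, 0.0, atol=1e-20)

    def test_rank_deficient_design_rejected_naming_columns(self):
        mat, _ = _two_group(genes=12)
        design = pd.DataFrame({"intercept": 1.0,
                               "diet": [0.0] * 8 + [1.0] * 8},
                              index=mat.columns)
        design["copy"] = design["diet"]
        with pytest.raises(ValueError, match="copy"):
            fit_gene_linear_models(mat, design)


class TestModeration:
    def test_identical_variances_give_infinite_prior(self):
        prior, post = cs.moderate_variances(np.full(100, 0.3), 14)
        assert np.isinf(prior.df_prior)
        assert (post == prior.s2_prior).all()
        # equality with the common value holds up to the documented
        # log-scale bias factor exp(psi(d/2) - log(d/2))
        factor = np.exp(special.digamma(7.0) - np.log(7.0))
        assert prior.s2_prior == pytest.approx(0.3 / factor, rel=1e-10)
        assert prior.s2_prior == pytest.approx(0.3, rel=0.10)

    def test_known_prior_recovered_from_simulation(self):
        rng = np.random.default_rng(11)
        true_var = 0.25 * 4.0 / rng.chisquare(4.0, 5000)
        s2 = true_var * rng.chisquare(14, 5000) / 14
        prior, _ = cs.moderate_variances(s2, 14)
        assert prior.df_prior == pytest.approx(4.0, rel=0.20)
        assert prior.s2_prior == pytest.approx(0.25, rel=0.05)

    def test_posterior_interpolates_prior_and_sample(self):
        rng = np.random.default_rng(12)
        true_var = 0.25 * 4.0 / rng.chisquare(4.0, 200)
        s2 = true_var * rng.chisquare(10, 200) / 10
        prior, post = cs.moderate_variances(s2, 10)
        assert np.isfinite(prior.df_prior)
        expected = (prior.df_prior * prior.s2_prior + 10 * s2) / (prior.df_prior + 10)
        np.testing.assert_allclose(post, expected, rtol=1e-12)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            cs.moderate_variances(np.full(5, 0.2), 10)


class TestModeratedT:
    def test_no_moderation_limit_equals_classical_t(self):
        mat, diets = _two_group(genes=40, seed=2, shift=0.3)
        design = pd.DataFrame({"intercept": 1.0,
                               "diet": [0.0] * 8 + [1.0] * 8},
                              index=mat.columns)
        fit = fit_gene_linear_models(mat, design)
        t, p = cs.moderated_t_test(fit.coefficients["diet"],
                                   fit.stdev_unscaled["diet"], fit.sigma2,
                                   fit.df_residual, df_prior=0.0)
        classical = stats.ttest_ind(mat.iloc[:, 8:], mat.iloc[:, :8], axis=1)
        np.testing.assert_allclose(t, classical.statistic, atol=1e-10)
        np.testing.assert_allclose(p, classical.pvalue, atol=1e-10)

    def test_infinite_prior_limit_equals_z_test(self):
        beta = pd.Series([0.5, -0.2], index=["a", "b"])
        t, p = cs.moderated_t_test(beta, 0.5, 0.04, 10, np.inf)
        z = beta / (0.5 * 0.2)
        np.testing.assert_allclose(t, z, atol=1e-10)
        np.testing.assert_allclose(p, 2 * stats.norm.sf(np.abs(z)), atol=1e-10)

    def test_zero_effect_gives_p_one(self):
        t, p = cs.moderated_t_test(pd.Series([0.0]), 0.5, 0.1, 10, 4.0)
        assert t.iloc[0] == 0.0 and p.iloc[0] == 1.0

    def test_matches_limma_on_shared_fixture(self, tmp_path):
        """Independent cross-check against the R reference implementation."""
        rng = np.random.default_rng(3)
        G = 150
        Y = rng.normal(8, 1, (G, 10)) * np.sqrt(
            0.25 * 4 / rng.chisquare(4, G))[:, None]
        Y[:, 5:] += rng.normal(0, 0.5, G)[:, None]
        mat = pd.DataFrame(Y, index=[f"g{i}" for i in range(G)],
                           columns=[f"s{i}" for i in range(10)])
        fit = cs.cr_contrast(mat, ["CTL"] * 5 + ["CR"] * 5)
        mat.to_csv(tmp_path / "m.tsv", sep="\t")
        script = f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.delim("{tmp_path}/m.tsv", row.names=1))
        f <- eBayes(lmFit(m, cbind(Intercept=1, diet=c(rep(0,5), rep(1,5)))))
        write.table(data.frame(t=f$t[,"diet"], p=f$p.value[,"diet"]),
                    "{tmp_path}/out.tsv", sep="\t", quote=FALSE)
        cat(f$df.prior, f$s2.prior, "\\n")
        """
        res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        d0, s02 = map(float, res.stdout.split())
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        from crstrains.diffexpr import moderate_variances
        prior, _ = moderate_variances(fit["s2"], 8)
        assert prior.df_prior == pytest.approx(d0, rel=1e-5)
        assert prior.s2_prior == pytest.approx(s02, rel=1e-5)
        np.testing.assert_allclose(fit["t"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(fit["p"], ref["p"], atol=1e-8)

    def test_null_type_one_error_near_nominal(self):
        mat, diets = _two_group(genes=2000, seed=4)
        fit = cs.cr_contrast(mat, diets)
        assert 0.03 < (fit["p"] < 0.05).mean() < 0.07


class TestBH:
    def test_step_up_example(self):
        q = cs.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate_vectors(self):
        assert cs.bh_adjust([0.2]).iloc[0] == pytest.approx(0.2)
        np.testing.assert_allclose(cs.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_literal_step_up_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = rng.uniform(size=rng.integers(2, 30))
            np.testing.assert_allclose(cs.bh_adjust(p), bh_step_up(p),
                                       atol=1e-12)

    def test_repeated_invocation_is_stable_and_pure(self):
        p = pd.Series([0.3, 0.01, 0.7, 0.04])
        snapshot = p.copy()
        q1 = cs.bh_adjust(p)
        q2 = cs.bh_adjust(p)
        pd.testing.assert_series_equal(q1, q2)
        pd.testing.assert_series_equal(p, snapshot)  # input not mutated

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = cs.bh_adjust(p).to_numpy()
        q_perm = cs.bh_adjust([p[i] for i in perm]).to_numpy()
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            cs.bh_adjust([0.5, np.nan])


@pytest.mark.parametrize("q,fc,is_deg,direction", [
    (0.05, 1.6, True, "up"),
    (0.05, 1.2, False, None),
    (0.20, 2.0, False, None),
    (0.05, 0.5, True, "down"),
])
def test_deg_rule(q, fc, is_deg, direction):
    fit = pd.DataFrame({"fdr": [q], "fc": [fc]}, index=["g0"])
    degs = cs.call_degs(fit)
    assert ("g0" in degs.index) is is_deg
    if is_deg:
        assert degs.loc["g0", "direction"] == direction


def test_deg_calls_invariant_to_gene_order(fit_tables):
    fit = fit_tables["A"]
    shuffled = fit.sample(frac=1.0, random_state=0)
    a = set(cs.call_degs(fit).index)
    b = set(cs.call_degs(shuffled).index)
    assert a == b


class TestInteractionScan:
    @staticmethod
    def _study(seed=0, planted=1.0, n_genes=300, n_planted=30, n_strains=7):
        rng = np.random.default_rng(seed)
        labels = [chr(ord("A") + i) for i in range(n_strains)]
        strains = np.repeat(labels, 16)
        diets = np.tile(["CTL"] * 8 + ["CR"] * 8, n_strains)
        mat = rng.normal(8, 0.5, (n_genes, 16 * n_strains))
        # common CR effect everywhere; extra planted interaction in strain A
        mat[:, diets == "CR"] += 0.2
        focal_cr = (strains == "A") & (diets == "CR")
        mat[:n_planted][:, focal_cr] += planted
        mat = pd.DataFrame(mat, index=[f"g{i:03d}" for i in range(n_genes)],
                           columns=[f"s{j}" for j in range(16 * n_strains)])
        return mat, strains, diets

    def test_planted_interaction_detected_with_power(self):
        mat, strains, diets = self._study(seed=1, planted=1.0,
                                          n_genes=1000, n_planted=100)
        fit = cs.interaction_scan(mat, strains, diets, "A")
        planted = fit.iloc[:100]
        assert planted["log2fc"].mean() == pytest.approx(1.0, abs=0.1)
        assert (planted["fdr"] < 0.10).mean() > 0.8

    def test_equal_cr_effect_everywhere_is_null(self):
        mat, strains, diets = self._study(planted=0.0)
        fit = cs.interaction_scan(mat, strains, diets, "A")
        assert 0.02 < (fit["p"] < 0.05).mean() < 0.09
        assert (fit["fdr"] < 0.10).sum() <= 2

    def test_single_strain_rejected(self):
        mat, strains, diets = self._study()
        with pytest.raises(ValueError):
            cs.interaction_scan(mat.iloc[:, :16], strains[:16], diets[:16], "A")

    def test_missing_diet_arm_rejected(self):
        mat, strains, diets = self._study()
        keep = ~((strains == "A") & (diets == "CR"))
        with pytest.raises(ValueError):
            cs.interaction_scan(mat.loc[:, keep], strains[keep], diets[keep], "A")

    def test_deterministic(self):
        mat, strains, diets = self._study()
        a = cs.interaction_scan(mat, strains, diets, "B")
        b = cs.interaction_scan(mat, strains, diets, "B")
        pd.testing.assert_frame_equal(a, b)
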