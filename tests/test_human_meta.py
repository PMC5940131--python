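"""Paired human experiments and the DerSimonian-Laird meta-signature."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crstrains as cs
from crstrains.containers import PairedExperiment
from crstrains.human_meta import ExperimentSummary

from _oracles import dl_formulas


def _experiment(eid="E1", set_id="B1", n_genes=30, n_subj=6, effect=0.0,
                seed=0, sd=0.3):
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i:03d}" for i in range(n_genes)], name="gene")
    cols = [f"s{j}" for j in range(n_subj)]
    base = pd.DataFrame(rng.normal(8, 1, (n_genes, 1))
                        + rng.normal(0, sd, (n_genes, n_subj)),
                        index=genes, columns=cols)
    post = base + effect + rng.normal(0, sd, (n_genes, n_subj))
    return PairedExperiment(eid, base, post, set_id)


class TestPairedDifferences:
    def test_basic_difference_signs(self):
        genes = pd.Index(["g1"], name="gene")
        base = pd.DataFrame([[8.0, 8.0]], index=genes, columns=["a", "b"])
        post = pd.DataFrame([[9.0, 8.0]], index=genes, columns=["a", "b"])
        d = cs.paired_log2_differences(PairedExperiment("e", base, post, "b1"))
        assert d.loc["g1", "a"] == 1.0 and d.loc["g1", "b"] == 0.0

    def test_identical_matrices_give_zero(self):
        exp = _experiment(effect=0.0)
        d = cs.paired_log2_differences(
            PairedExperiment("e", exp.baseline, exp.baseline.copy(), "b"))
        assert (d == 0).all().all()

    def test_planted_effect_recovered(self):
        exp = _experiment(n_genes=200, n_subj=10, effect=0.5, sd=0.2, seed=1)
        d = cs.paired_log2_differences(exp)
        se = 0.2 * np.sqrt(2.0) / np.sqrt(10)
        assert abs(d.mean(axis=1).mean() - 0.5) < 3 * se / np.sqrt(200) * 10
        assert d.mean(axis=1).mean() == pytest.approx(0.5, abs=3 * se)


class TestLowExpressionFilter:
    def test_fifteen_percent_of_hundred(self):
        exp = _experiment(n_genes=100)
        kept = cs.low_expression_filter(exp)
        assert len(kept) == 85

    def test_floor_convention_small_n(self):
        exp = _experiment(n_genes=10)
        kept = cs.low_expression_filter(exp, 0.15)
        assert len(kept) == 9  # floor(1.5) = 1 removed

    def test_tie_break_removes_lexicographically_smallest(self):
        genes = pd.Index(["gB", "gA", "gC"], name="gene")
        base = pd.DataFrame(np.full((3, 2), 8.0), index=genes, columns=["a", "b"])
        exp = PairedExperiment("e", base, base.copy(), "b1")
        kept = cs.low_expression_filter(exp, fraction=0.34)
        assert "gA" not in kept and len(kept) == 2

    def test_lowest_expressed_genes_removed(self):
        exp = _experiment(n_genes=40, seed=3)
        means = pd.concat([exp.baseline, exp.post], axis=1).mean(axis=1)
        kept = cs.low_expression_filter(exp)
        dropped = exp.genes.difference(kept)
        assert means[dropped].max() <= means[kept].min() + 1e-12


class TestExperimentSummary:
    def test_two_point_case(self):
        diffs = pd.DataFrame(np.vstack([[1.0, -1.0]] * 12),
                             index=[f"g{i}" for i in range(12)],
                             columns=["a", "b"])
        diffs.iloc[1:] += np.random.default_rng(0).normal(0, 0.2, (11, 2))
        s = cs.experiment_summary(diffs, "e", "b")
        assert s.table.loc["g0", "mean"] == pytest.approx(0.0)
        assert s.table.loc["g0", "se"] == pytest.approx(1.0)
        assert s.n_subjects == 2

    def test_constant_differences_flagged_degenerate(self):
        rng = np.random.default_rng(1)
        diffs = pd.DataFrame(rng.normal(0, 0.3, (20, 5)),
                             index=[f"g{i}" for i in range(20)],
                             columns=list("abcde"))
        diffs.iloc[0] = 0.7
        s = cs.experiment_summary(diffs)
        assert s.table["degenerate"].iloc[0]
        assert not s.table["degenerate"].iloc[1:].any()

    def test_single_subject_rejected(self):
        diffs = pd.DataFrame({"a": np.zeros(15)})
        with pytest.raises(ValueError):
            cs.experiment_summary(diffs)

    def test_null_moderated_p_roughly_uniform(self):
        rng = np.random.default_rng(2)
        diffs = pd.DataFrame(rng.normal(0, 0.4, (2000, 8)))
        diffs.index = [f"g{i}" for i in range(2000)]
        s = cs.experiment_summary(diffs)
        assert 0.03 < (s.table["p"] < 0.05).mean() < 0.07


def _summary(eid, set_id, avg_se):
    return ExperimentSummary(eid, set_id, 5, pd.DataFrame(), avg_se)


class TestIndependenceFilter:
    def test_lowest_average_se_retained_per_set(self):
        kept = cs.independence_filter([
            _summary("E1", "A", 0.3), _summary("E2", "A", 0.2),
            _summary("E3", "B", 0.5)])
        assert [s.experiment_id for s in kept] == ["E2", "E3"]

    def test_all_distinct_sets_all_retained(self):
        ss = [_summary(f"E{i}", f"B{i}", 0.1 * i) for i in range(1, 6)]
        assert len(cs.independence_filter(ss)) == 5

    def test_tie_breaks_to_lexicographic_experiment_id(self):
        kept = cs.independence_filter([
            _summary("E2", "A", 0.3), _summary("E1", "A", 0.3)])
        assert [s.experiment_id for s in kept] == ["E1"]

    def test_output_size_equals_distinct_baseline_sets(self, small_sim):
        _, _, _, truth = small_sim
        cfg = cs.HumanMetaConfig(n_experiments=12, n_baseline_sets=7,
                                 subjects_range=(3, 6))
        exps = cs.simulate_human_experiments(cfg, truth, seed=4)
        summaries = []
        for e in exps:
            keep = cs.low_expression_filter(e)
            diffs = cs.paired_log2_differences(e).loc[keep]
            summaries.append(cs.experiment_summary(diffs, e.experiment_id,
                                                   e.baseline_set_id))
        assert len(cs.independence_filter(summaries)) == 7


class TestGeneInclusion:
    def test_boundary_six_of_eighteen(self):
        presence = pd.DataFrame(False, index=["g6", "g5"],
                                columns=[f"e{i}" for i in range(18)])
        presence.loc["g6", presence.columns[:6]] = True
        presence.loc["g5", presence.columns[:5]] = True
        kept = cs.gene_inclusion_filter(presence, 6)
        assert list(kept) == ["g6"]

    def test_counts_on_constructed_matrix(self):
        rng = np.random.default_rng(5)
        n_genes, n_exp = 500, 18
        counts = rng.integers(0, n_exp + 1, n_genes)
        presence = pd.DataFrame(
            [np.arange(n_exp) < c for c in counts],
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"e{j}" for j in range(n_exp)])
        kept = cs.gene_inclusion_filter(presence, 6)
        assert len(kept) == int((counts >= 6).sum())


class TestDerSimonianLaird:
    def test_equal_weights_force_midpoint(self):
        res = cs.dersimonian_laird([0.2, 0.6], [0.1, 0.1])
        assert res.mu == pytest.approx(0.4)

    def test_hand_evaluated_formula_oracle(self):
        # frozen by hand: w=(100,100,25); Q = 10 exactly; tau2 = 8/(400/3);
        # random weights (100/7, 100/7, 10); mu = 87/270; se = sqrt(7/270)
        res = cs.dersimonian_laird([0.2, 0.6, 0.1], [0.1, 0.1, 0.2])
        assert res.q_cochran == pytest.approx(10.0, abs=1e-10)
        assert res.tau2 == pytest.approx(0.06, abs=1e-12)
        assert res.mu == pytest.approx(87.0 / 270.0, abs=1e-12)
        assert res.se == pytest.approx(np.sqrt(7.0 / 270.0), abs=1e-12)

    def test_matches_formula_oracle_on_random_inputs(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            k = int(rng.integers(2, 12))
            y = rng.normal(0, 0.5, k)
            se = rng.uniform(0.05, 0.4, k)
            res = cs.dersimonian_laird(y, se)
            mu, se_mu, tau2, q = dl_formulas(y, se)
            assert res.mu == pytest.approx(mu, abs=1e-12)
            assert res.se == pytest.approx(se_mu, abs=1e-12)
            assert res.tau2 == pytest.approx(tau2, abs=1e-12)
            assert res.q_cochran == pytest.approx(q, abs=1e-10)

    def test_matches_metafor_reference(self):
        rng = np.random.default_rng(7)
        y = np.round(rng.normal(0.2, 0.4, 6), 4)
        se = np.round(rng.uniform(0.05, 0.3, 6), 4)
        res = cs.dersimonian_laird(y, se)
        script = (
            'suppressMessages(library(metafor));'
            f'r <- rma(yi=c({",".join(map(str, y))}), '
            f'sei=c({",".join(map(str, se))}), method="DL");'
            'cat(r$b, r$se, r$tau2, r$QE, r$pval, "\\n")')
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        mu, se_mu, tau2, q, p = map(float, out.stdout.split())
        assert res.mu == pytest.approx(mu, abs=1e-6)
        assert res.se == pytest.approx(se_mu, abs=1e-6)
        assert res.tau2 == pytest.approx(tau2, abs=1e-6)
        assert res.p == pytest.approx(p, abs=1e-6)

    def test_homogeneous_effects_give_zero_tau2(self):
        res = cs.dersimonian_laird([0.3, 0.3, 0.3], [0.1, 0.2, 0.3])
        assert res.tau2 == 0.0
        assert res.mu == pytest.approx(0.3)

    def test_tau2_zero_whenever_q_below_df(self):
        rng = np.random.default_rng(8)
        seen = 0
        for _ in range(50):
            k = int(rng.integers(2, 8))
            y = rng.normal(0, 0.1, k)
            se = rng.uniform(0.2, 0.5, k)
            res = cs.dersimonian_laird(y, se)
            if res.q_cochran <= k - 1:
                assert res.tau2 == 0.0
                seen += 1
        assert seen > 5

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-2, 2), min_size=2, max_size=10),
           st.integers(0, 10 ** 6))
    def test_mu_within_effect_range(self, y, seed):
        se = np.random.default_rng(seed).uniform(0.05, 0.5, len(y))
        res = cs.dersimonian_laird(y, se)
        assert min(y) - 1e-9 <= res.mu <= max(y) + 1e-9
        assert res.tau2 >= 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cs.dersimonian_laird([0.1], [0.1])
        with pytest.raises(ValueError):
            cs.dersimonian_laird([0.1, 0.2], [0.0, 0.1])


class TestMetaSignature:
    @staticmethod
    def _experiments(n_exp=6, n_sets=6, effect=0.5, n_genes=300, sd=0.3,
                     seed=0, n_subj=10):
        rng = np.random.default_rng(seed)
        genes = pd.Index([f"g{i:03d}" for i in range(n_genes)], name="gene")
        exps = []
        for i in range(n_exp):
            cols = [f"s{j}" for j in range(n_subj)]
            base = pd.DataFrame(rng.normal(8, 1, (n_genes, 1))
                                + rng.normal(0, sd, (n_genes, n_subj)),
                                index=genes, columns=cols)
            post = base + effect + rng.normal(0, sd, (n_genes, n_subj))
            exps.append(PairedExperiment(f"E{i:02d}", base, post,
                                         f"B{i % n_sets:02d}"))
        return exps

    def test_common_effect_recovered(self):
        sig = cs.meta_signature(self._experiments(effect=0.5), min_experiments=4)
        se_mean = sig.table["se"].mean() / np.sqrt(len(sig.table))
        assert sig.table["meta_log2fc"].mean() == pytest.approx(
            0.5, abs=max(3 * se_mean, 0.02))

    def test_null_experiments_yield_no_discoveries(self):
        sig = cs.meta_signature(self._experiments(effect=0.0, seed=1),
                                min_experiments=4)
        assert (sig.table["fdr"] < 0.10).mean() < 0.01

    def test_single_baseline_set_rejected(self):
        exps = self._experiments(n_exp=3, n_sets=1)
        with pytest.raises(ValueError):
            cs.meta_signature(exps, min_experiments=2)

    def test_fc_consistent_with_log2fc(self):
        sig = cs.meta_signature(self._experiments(seed=2), min_experiments=4)
        np.testing.assert_allclose(sig.table["meta_fc"],
                                   np.exp2(sig.table["meta_log2fc"]),
                                   rtol=1e-10)
        assert (sig.table["fdr"] >= sig.table["p"] - 1e-12).all()
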