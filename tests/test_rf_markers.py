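import numpy as np
import pandas as pd
import pytest

from editscan.errors import ValidationError
from editscan.pileup_io import ExpressionMatrix, GenePanel
from editscan.rf_markers import (
    RFConfig,
    iterative_rf_select,
    lda_validate,
    pca_project,
    preprocess,
    restrict_to_panel,
    run_marker_pipeline,
)
from editscan.synthetic_data import simulate_expression


def matrix_from(values: dict, groups, sexes=None):
    samples = list(next(iter(values.values())).keys()) if values else []
    df = pd.DataFrame(values).T
    sexes = sexes or ["M"] * len(df.columns)
    meta = pd.DataFrame(
        {"group": groups, "sex": sexes}, index=list(df.columns)
    )
    return ExpressionMatrix(values=df, sample_meta=meta)


class TestPreprocess:
    def base(self, values):
        df = pd.DataFrame(
            values, index=[f"G{i}" for i in range(len(values))],
            columns=["s1", "s2", "s3"],
        )
        meta = pd.DataFrame(
            {"group": ["WT", "WT", "AS"], "sex": ["M", "M", "M"]},
            index=["s1", "s2", "s3"],
        )
        return ExpressionMatrix(values=df, sample_meta=meta)

    def test_all_below_one_removed(self):
        expr = self.base([[0.2, 0.5, 0.9], [2.0, 3.0, 4.0]])
        out = preprocess(expr)
        assert out.genes == ["G1"]

    def test_not_all_below_one_retained(self):
        expr = self.base([[0.2, 3.0, 0.9]])
        assert preprocess(expr).genes == ["G0"]

    def test_zero_maps_to_zero(self):
        expr = self.base([[0.0, 3.0, 8.0]])
        out = preprocess(expr)
        assert out.values.loc["G0", "s1"] == 0.0
        assert out.values.loc["G0", "s2"] == pytest.approx(np.log(4.0))

    def test_female_samples_removed(self):
        expr, _ = simulate_expression(
            n_genes=10, n_informative=0, samples_per_group=4,
            n_female_per_group=2, seed=0,
        )
        out = preprocess(expr)
        assert len(out.samples) == 4
        assert (out.sample_meta["sex"] == "M").all()

    def test_no_males_errors(self):
        expr = self.base([[1.0, 2.0, 3.0]])
        expr.sample_meta["sex"] = "F"
        with pytest.raises(ValidationError, match="male"):
            preprocess(expr)

    def test_group_lost_errors(self):
        expr = self.base([[1.0, 2.0, 3.0]])
        expr.sample_meta.loc["s3", "sex"] = "F"  # only AS sample
        with pytest.raises(ValidationError, match="group"):
            preprocess(expr)


class TestRestrictToPanel:
    def test_intersection(self):
        expr, _ = simulate_expression(n_genes=20, n_informative=0, seed=1)
        panel = GenePanel("p", tuple(expr.genes[:5]) + ("NOT_PRESENT",))
        out = restrict_to_panel(expr, panel)
        assert len(out.genes) == 5

    def test_disjoint_errors(self):
        expr, _ = simulate_expression(n_genes=5, n_informative=0, seed=1)
        panel = GenePanel("p", ("Xiap", "Bax"))
        with pytest.raises(ValidationError):
            restrict_to_panel(expr, panel)

    def test_case_mismatch_still_intersects(self):
        expr, _ = simulate_expression(n_genes=5, n_informative=0, seed=1)
        panel = GenePanel("p", tuple(g.lower() for g in expr.genes[:3]))
        assert len(restrict_to_panel(expr, panel).genes) == 3


@pytest.fixture(scope="module")
def informative():
    expr, truth = simulate_expression(
        n_genes=30, n_informative=5, shift_sd_units=4.0,
        samples_per_group=6, seed=21,
    )
    return preprocess(expr), truth


class TestIterativeRFSelect:
    CFG = RFConfig(
        n_iterations=50, trees_per_forest=30, top_k_per_iteration=5,
        n_select=5, seed=42,
    )

    def test_informative_genes_top_frequencies(self, informative):
        expr, truth = informative
        sel = iterative_rf_select(expr, config=self.CFG)
        true_genes = set(truth.loc[~truth.is_null, "gene"])
        assert set(sel.selected) == true_genes

    def test_determinism(self, informative):
        expr, _ = informative
        a = iterative_rf_select(expr, config=self.CFG)
        b = iterative_rf_select(expr, config=self.CFG)
        pd.testing.assert_series_equal(a.selection_freq, b.selection_freq)
        assert a.selected == b.selected

    def test_selection_freq_sum_invariant(self, informative):
        expr, _ = informative
        sel = iterative_rf_select(expr, config=self.CFG)
        total = sel.selection_freq.sum() * self.CFG.n_iterations
        expected = self.CFG.n_iterations * min(
            self.CFG.top_k_per_iteration, len(expr.genes)
        )
        assert total == pytest.approx(expected)

    def test_single_iteration_freqs_binary(self, informative):
        expr, _ = informative
        cfg = RFConfig(n_iterations=1, trees_per_forest=10,
                       top_k_per_iteration=5, n_select=5, seed=1)
        sel = iterative_rf_select(expr, config=cfg)
        assert set(sel.selection_freq.unique()) <= {0.0, 1.0}

    def test_top_k_exceeding_genes_warns(self, informative):
        expr, _ = informative
        cfg = RFConfig(n_iterations=2, trees_per_forest=10,
                       top_k_per_iteration=100, n_select=5, seed=1)
        with pytest.warns(UserWarning, match="top_k"):
            sel = iterative_rf_select(expr, config=cfg)
        assert (sel.selection_freq == 1.0).all()

    def test_null_labels_no_dominant_gene(self):
        # permutation reference: with no signal, the real-label max selection
        # frequency should sit inside the permutation distribution
        expr, _ = simulate_expression(
            n_genes=30, n_informative=0, samples_per_group=5, seed=33,
        )
        pre = preprocess(expr)
        labels = pre.sample_meta.loc[pre.samples, "group"].to_numpy()
        cfg = RFConfig(n_iterations=30, trees_per_forest=15,
                       top_k_per_iteration=3, n_select=3, seed=8)
        observed = iterative_rf_select(pre, labels, cfg).selection_freq.max()
        rng = np.random.default_rng(99)
        perm_freqs = []
        for i in range(8):
            shuffled = rng.permutation(labels)
            cfg_i = RFConfig(n_iterations=30, trees_per_forest=15,
                             top_k_per_iteration=3, n_select=3, seed=100 + i)
            perm_freqs.extend(
                iterative_rf_select(pre, shuffled, cfg_i).selection_freq.values
            )
        assert observed <= np.quantile(perm_freqs, 0.99)


class TestLDAValidate:
    def test_perfect_separation(self):
        expr, _ = simulate_expression(
            n_genes=10, n_informative=10, shift_sd_units=6.0,
            samples_per_group=4, seed=3,
        )
        assert lda_validate(preprocess(expr)) == 1.0

    def test_random_labels_near_chance(self):
        accs = []
        for seed in range(6):
            expr, _ = simulate_expression(
                n_genes=50, n_informative=0, samples_per_group=3, seed=seed,
            )
            pre = preprocess(expr)
            rng = np.random.default_rng(seed)
            labels = rng.permutation(
                pre.sample_meta.loc[pre.samples, "group"].to_numpy()
            )
            accs.append(lda_validate(pre, labels))
        assert 0.1 < np.mean(accs) < 0.9

    def test_uninformative_feature_majority_rate(self):
        df = pd.DataFrame({f"s{i}": [1.0] for i in range(6)}, index=["G0"])
        meta = pd.DataFrame(
            {"group": ["WT"] * 4 + ["AS"] * 2, "sex": ["M"] * 6},
            index=list(df.columns),
        )
        expr = ExpressionMatrix(values=df, sample_meta=meta)
        assert lda_validate(expr) == pytest.approx(4 / 6)


class TestPCAProject:
    def test_separated_clusters(self):
        expr, _ = simulate_expression(
            n_genes=10, n_informative=10, shift_sd_units=6.0,
            samples_per_group=4, seed=3,
        )
        pre = preprocess(expr)
        res = pca_project(pre)
        groups = pre.sample_meta.loc[res.scores.index, "group"]
        pc1_wt = res.scores.loc[groups == "WT", "PC1"]
        pc1_as = res.scores.loc[groups == "AS", "PC1"]
        assert pc1_wt.max() < pc1_as.min() or pc1_as.max() < pc1_wt.min()

    def test_identical_samples_all_zero(self):
        df = pd.DataFrame({f"s{i}": [2.0, 3.0] for i in range(4)},
                          index=["G0", "G1"])
        meta = pd.DataFrame({"group": ["WT"] * 2 + ["AS"] * 2,
                             "sex": ["M"] * 4}, index=list(df.columns))
        res = pca_project(ExpressionMatrix(values=df, sample_meta=meta))
        assert (res.scores.to_numpy() == 0).all()
        assert res.degenerate_pc2

    def test_duplicating_samples_preserves_structure(self):
        expr, _ = simulate_expression(n_genes=8, n_informative=0,
                                      samples_per_group=3, seed=5)
        base = pca_project(expr).scores
        dup_values = pd.concat(
            [expr.values, expr.values.add_suffix("_dup", axis=1)], axis=1
        )
        dup_meta = pd.concat(
            [expr.sample_meta,
             expr.sample_meta.set_axis(expr.sample_meta.index + "_dup")]
        )
        dup = pca_project(
            ExpressionMatrix(values=dup_values, sample_meta=dup_meta)
        ).scores
        # originals keep their mutual geometry up to a global scale
        ratio = np.linalg.norm(dup.loc[base.index, "PC1"]) / np.linalg.norm(
            base["PC1"]
        )
        np.testing.assert_allclose(
            dup.loc[base.index, "PC1"].to_numpy(),
            ratio * base["PC1"].to_numpy(),
            atol=1e-8,
        )


class TestPipeline:
    def test_end_to_end_combined_panels(self):
        expr, truth = simulate_expression(
            n_genes=40, n_informative=6, shift_sd_units=5.0,
            samples_per_group=5, seed=17,
        )
        genes = list(expr.genes)
        panel_a = GenePanel("apoptosis", tuple(genes[:20]))
        panel_b = GenePanel("proliferation", tuple(genes[20:]))
        cfg = RFConfig(n_iterations=30, trees_per_forest=25,
                       top_k_per_iteration=3, seed=2)
        sel = run_marker_pipeline(
            expr, [panel_a, panel_b],
            n_select={"apoptosis": 4, "proliferation": 2}, config=cfg,
        )
        assert len(sel.selected) == 6
        assert sel.lda_accuracy == 1.0
        assert sel.pc_scores.shape == (10, 2)
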