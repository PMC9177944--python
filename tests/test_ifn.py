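import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from ifnsig.expression import filter_low_expressed, normalize
from ifnsig.fixtures import load_ifn_gene_list, load_table1
from ifnsig.ifn import (
    annotate_ifn,
    compare_ifn_scores,
    compute_ifn_score,
    fisher_ifn_enrichment,
)
from ifnsig.synthetic import SimConfig, simulate_counts


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the minimum-likelihood rule."""
    n1, n2 = a + b, c + d
    k = a + c
    obs = hypergeom.pmf(a, n1 + n2, k, n1)
    total = 0.0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        pr = hypergeom.pmf(x, n1 + n2, k, n1)
        if pr <= obs * (1 + 1e-9):
            total += pr
    return min(total, 1.0)


class TestAnnotate:
    def test_reference_table_flags_25_of_33_upregulated(self):
        table1 = load_table1()
        ann = annotate_ifn(table1.drop(columns=["ifn_regulated"]), load_ifn_gene_list())
        up = ann[ann["log2fc"] > 0]
        down = ann[ann["log2fc"] < 0]
        assert int(up["ifn_regulated"].sum()) == 25
        assert int(down["ifn_regulated"].sum()) == 7
        # packaged flags and annotation agree gene by gene
        assert (ann["ifn_regulated"] == table1["ifn_regulated"]).all()

    def test_case_insensitive_match(self):
        res = pd.DataFrame({"log2fc": [1.0]}, index=["s100a8"])
        ann = annotate_ifn(res, {"S100A8"})
        assert bool(ann["ifn_regulated"].iloc[0])

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            annotate_ifn(pd.DataFrame(index=["a"]), set())

    def test_empty_results_pass_through(self):
        ann = annotate_ifn(pd.DataFrame(index=[]), {"X"})
        assert len(ann) == 0


class TestFisher:
    def test_reference_counts_give_printed_p(self):
        # 25/33 up vs 7/27 down IFN-regulated
        odds, p = fisher_ifn_enrichment(33, 25, 27, 7)
        assert round(p, 4) == 0.0002  # printed to 1 significant figure
        assert 100 * 25 / 33 == pytest.approx(75.76, abs=0.01)

    def test_identical_proportions_give_p_one(self):
        _, p = fisher_ifn_enrichment(10, 5, 10, 5)
        assert p == pytest.approx(1.0)

    def test_row_swap_symmetry(self):
        _, p1 = fisher_ifn_enrichment(20, 12, 15, 3)
        _, p2 = fisher_ifn_enrichment(15, 3, 20, 12)
        assert p1 == pytest.approx(p2)

    def test_matches_enumeration_oracle_on_small_margins(self):
        for up_total in range(1, 9):
            for down_total in range(1, 9):
                for up_ifn in range(up_total + 1):
                    for down_ifn in range(down_total + 1):
                        _, p = fisher_ifn_enrichment(up_total, up_ifn, down_total, down_ifn)
                        oracle = fisher_two_sided_oracle(
                            up_ifn, up_total - up_ifn, down_ifn, down_total - down_ifn)
                        assert p == pytest.approx(oracle, abs=1e-9), (
                            up_total, up_ifn, down_total, down_ifn)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="up"):
            fisher_ifn_enrichment(5, 7, 3, 1)


class TestScore:
    def _toy_expr(self):
        rng = np.random.default_rng(0)
        genes = ["IFI27", "IFI44L", "IFIT1", "ISG15", "RSAD2", "SIGLEC1", "OTHER"]
        samples = [f"c{i}" for i in range(5)] + [f"p{i}" for i in range(4)]
        return pd.DataFrame(rng.normal(8, 2, (len(genes), len(samples))),
                            index=genes, columns=samples), [f"c{i}" for i in range(5)]

    def test_control_mean_exactly_zero(self):
        expr, controls = self._toy_expr()
        panel = compute_ifn_score(expr, controls)
        assert abs(panel.ifn_score[controls].mean()) < 1e-12
        np.testing.assert_allclose(
            panel.expression_scores[controls].std(axis=1, ddof=1), 1.0)

    def test_sample_at_control_mean_scores_zero(self):
        expr, controls = self._toy_expr()
        expr["avg"] = expr[controls].mean(axis=1)
        panel = compute_ifn_score(expr, controls)
        assert panel.ifn_score["avg"] == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_above_on_each_gene_scores_six(self):
        expr, controls = self._toy_expr()
        expr["hi"] = expr[controls].mean(axis=1) + expr[controls].std(axis=1, ddof=1)
        panel = compute_ifn_score(expr, controls)
        assert panel.ifn_score["hi"] == pytest.approx(6.0)

    def test_shift_invariance_and_scale_equivariance(self):
        expr, controls = self._toy_expr()
        base = compute_ifn_score(expr, controls)
        shifted = expr.copy()
        shifted.loc["ISG15"] += 100.0
        assert np.allclose(compute_ifn_score(shifted, controls).ifn_score, base.ifn_score)
        scaled = expr.copy()
        scaled.loc["ISG15"] *= 3.0
        np.testing.assert_allclose(
            compute_ifn_score(scaled, controls).expression_scores.loc["ISG15"],
            base.expression_scores.loc["ISG15"])

    def test_missing_panel_gene_named(self):
        expr, controls = self._toy_expr()
        with pytest.raises(KeyError, match="IFI27"):
            compute_ifn_score(expr.drop(index="IFI27"), controls)

    def test_zero_control_sd_named(self):
        expr, controls = self._toy_expr()
        expr.loc["RSAD2", controls] = 5.0
        with pytest.raises(ValueError, match="RSAD2"):
            compute_ifn_score(expr, controls)


class TestCompare:
    def test_identical_groups_give_zero_t(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0] * 2,
                      index=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        t, df, p = compare_ifn_scores(s, [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_student_variant_hand_example(self):
        s = pd.Series([1, 2, 3, 4, 5, 6, 7, 8],
                      index=[f"s{i}" for i in range(8)], dtype=float)
        t, df, p = compare_ifn_scores(s, [f"s{i}" for i in range(4)],
                                      [f"s{i}" for i in range(4, 8)], variant="student")
        assert t == pytest.approx(-4.3818, abs=1e-3)
        assert df == pytest.approx(6.0)
        assert p == pytest.approx(0.00466, abs=1e-4)

    def test_group_too_small(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError):
            compare_ifn_scores(s, ["a"], ["b", "c"])

    def test_planted_ifn_shift_detected(self):
        # one-control-SD shift per panel gene separates groups strongly
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimConfig(n_genes=800, seed=seed)
            counts, truth = simulate_counts(cfg)
            filtered = filter_low_expressed(counts)
            log_norm = normalize(filtered, scale="log2")
            ctl = filtered.samples_in_group("CTL")
            fm = filtered.samples_in_group("FM")
            panel = compute_ifn_score(log_norm.values, ctl, truth.panel_genes)
            _, _, p = compare_ifn_scores(panel.ifn_score, fm, ctl)
            hits += p < 0.01
        assert hits >= int(0.95 * n_seeds)
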