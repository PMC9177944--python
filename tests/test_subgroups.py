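import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ifnsig.expression import filter_low_expressed, normalize, zscore_rows
from ifnsig.subgroups import (
    compare_subgroups,
    fm_score,
    fss_total,
    hierarchical_cluster,
    identify_high_subset,
    validate_clinical,
)
from ifnsig.synthetic import SimConfig, simulate_counts


class TestHierarchical:
    def test_two_blobs_recovered_by_first_bipartition(self):
        from scipy.cluster.hierarchy import fcluster

        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.3, size=(5, 4))
        b = rng.normal(5, 0.3, size=(5, 4))
        df = pd.DataFrame(np.vstack([a, b]).T,
                          columns=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)])
        Z, _ = hierarchical_cluster(df, axis="columns")
        labels = fcluster(Z, 2, criterion="maxclust")
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicate_rows_merge_at_height_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=list("abc"))
        Z, _ = hierarchical_cluster(df, axis="rows")
        assert Z[0, 2] == pytest.approx(0.0)

    def test_distances_match_brute_force_euclidean(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(5, 3)))
        # single pair: linkage of 2 items is just their distance
        for i in range(4):
            pair = df.iloc[[i, i + 1]]
            Z, _ = hierarchical_cluster(pair, axis="rows")
            manual = np.sqrt(((pair.iloc[0] - pair.iloc[1]) ** 2).sum())
            assert Z[0, 2] == pytest.approx(manual)

    def test_nan_rejected(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="finite"):
            hierarchical_cluster(df, axis="rows")

    def test_partition_invariant_under_permutation(self):
        from scipy.cluster.hierarchy import fcluster

        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(6, 10)),
                          columns=[f"s{i}" for i in range(10)])
        df.iloc[:, 5:] += 4.0
        Z1, _ = hierarchical_cluster(df, axis="columns")
        perm = rng.permutation(df.columns)
        Z2, _ = hierarchical_cluster(df[perm], axis="columns")
        l1 = pd.Series(fcluster(Z1, 2, "maxclust"), index=df.columns)
        l2 = pd.Series(fcluster(Z2, 2, "maxclust"), index=perm)
        groups1 = frozenset(frozenset(l1.index[l1 == k]) for k in set(l1))
        groups2 = frozenset(frozenset(l2.index[l2 == k]) for k in set(l2))
        assert groups1 == groups2


class TestIdentifySubset:
    def test_planted_subset_recovered(self, normalized_cohort):
        _, filtered, truth, log_norm = normalized_cohort
        up = sorted(truth.de_genes_up & set(filtered.gene_ids))
        z = zscore_rows(log_norm.values.loc[up])
        assign = identify_high_subset(z, sorted(truth.fm_samples))
        assert assign.distinct
        inter = assign.high_subset & truth.subset_samples
        union = assign.high_subset | truth.subset_samples
        assert len(inter) / len(union) >= 0.8

    def test_no_planted_subset_not_distinct(self):
        cfg = SimConfig(n_genes=600, subset_size=0, seed=6)
        counts, truth = simulate_counts(cfg)
        filtered = filter_low_expressed(counts)
        log_norm = normalize(filtered, scale="log2")
        rng = np.random.default_rng(0)
        feats = list(rng.choice(filtered.gene_ids, 33, replace=False))
        z = zscore_rows(log_norm.values.loc[feats])
        assign = identify_high_subset(z, sorted(truth.fm_samples))
        assert not assign.distinct
        assert assign.high_subset == set()

    def test_identical_samples_not_distinct(self):
        z = pd.DataFrame(np.zeros((10, 8)) + np.arange(10)[:, None],
                         columns=[f"f{i}" for i in range(8)])
        z = z + 0  # constant columns, all samples identical
        assign = identify_high_subset(z, [f"f{i}" for i in range(8)])
        assert not assign.distinct

    def test_subset_recovery_degrades_with_amplification(self):
        # median Jaccard non-increasing as the planted amplification shrinks
        med = {}
        for amp in (2.0, 1.5, 1.0):
            jacs = []
            for seed in range(8):
                cfg = SimConfig(n_genes=800, subset_amplification=amp, seed=seed)
                counts, truth = simulate_counts(cfg)
                filtered = filter_low_expressed(counts)
                log_norm = normalize(filtered, scale="log2")
                up = sorted(truth.de_genes_up & set(filtered.gene_ids))
                z = zscore_rows(log_norm.values.loc[up])
                assign = identify_high_subset(z, sorted(truth.fm_samples))
                union = assign.high_subset | truth.subset_samples
                jacs.append(len(assign.high_subset & truth.subset_samples) / len(union))
            med[amp] = float(np.median(jacs))
        assert med[2.0] >= med[1.5] >= med[1.0]


class TestClinicalScores:
    def test_fm_score_bounds(self):
        assert fm_score(0, 0) == 0
        assert fm_score(19, 12) == 31

    @pytest.mark.parametrize("wpi, sss", [(20, 0), (-1, 5), (0, 13)])
    def test_fm_score_out_of_range(self, wpi, sss):
        with pytest.raises(ValueError):
            fm_score(wpi, sss)

    def test_fss_total_and_range(self):
        assert fss_total([1] * 9) == 9
        assert fss_total([7] * 9) == 63
        with pytest.raises(ValueError, match="item 3"):
            fss_total([4, 4, 8, 4, 4, 4, 4, 4, 4])
        with pytest.raises(ValueError, match="9 items"):
            fss_total([4] * 8)

    def test_validate_clinical_catches_inconsistency(self):
        clin = pd.DataFrame({"WPI": [10], "SSS": [5], "FM_score": [16], "group": ["FM"]},
                            index=["s1"])
        with pytest.raises(ValueError, match="inconsistent"):
            validate_clinical(clin)


class TestCompareSubgroups:
    def test_identical_groups_p_one(self):
        v = pd.Series([20.0, 22.0, 24.0] * 2, index=[f"x{i}" for i in range(6)])
        res = compare_subgroups(v, ["x0", "x1", "x2"], ["x3", "x4", "x5"])
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(0)
        v = pd.Series(rng.normal(20, 4, 25), index=[f"s{i}" for i in range(25)])
        a = [f"s{i}" for i in range(7)]
        b = [f"s{i}" for i in range(7, 25)]
        r1 = compare_subgroups(v, a, b)
        r2 = compare_subgroups(v, b, a)
        assert r1["t"] == pytest.approx(-r2["t"])
        assert r1["p"] == pytest.approx(r2["p"])

    def test_empirical_power_matches_welch_oracle(self):
        # planted shift, n = 7 vs 18, compare to the noncentral-t power
        rng = np.random.default_rng(3)
        n1, n2, sd, shift = 7, 18, 3.0, 4.0
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            a = pd.Series(rng.normal(21 + shift, sd, n1))
            b = pd.Series(rng.normal(21, sd, n2))
            v = pd.concat([a, b], ignore_index=True)
            v.index = [f"s{i}" for i in range(n1 + n2)]
            res = compare_subgroups(v, v.index[:n1], v.index[n1:])
            rejections += res["p"] < 0.05
        emp = rejections / n_rep
        # Welch-Satterthwaite df with equal true variances
        v1, v2 = sd**2 / n1, sd**2 / n2
        df_w = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        ncp = shift / (sd * np.sqrt(1 / n1 + 1 / n2))
        crit = stats.t.ppf(0.975, df_w)
        analytic = 1 - stats.nct.cdf(crit, df_w, ncp) + stats.nct.cdf(-crit, df_w, ncp)
        assert emp == pytest.approx(analytic, abs=0.06)

    def test_group_too_small(self):
        v = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError):
            compare_subgroups(v, ["a"], ["b", "c"])
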