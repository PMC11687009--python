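import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ifnsynergy as ifs
from ifnsynergy.cohort import CohortTable, apply_metadata_filter
from ifnsynergy.normalize import AbundanceMatrix
from ifnsynergy.synthetic import simulate_cohort_sample_sheet


def abundance(rows, genes, lines, unit="log2TPM1"):
    return AbundanceMatrix(pd.DataFrame(rows, index=genes, columns=lines), unit)


class TestWildtypeFilter:
    def test_synthetic_sample_sheet_retains_45(self):
        """58-line panel with 13 engineered/off-treatment lines -> 45 kept."""
        sheet = simulate_cohort_sample_sheet(n_total=58, n_excluded=13, seed=1)
        kept = apply_metadata_filter(sheet)
        assert len(kept) == 45

    def test_identity_when_nothing_flagged(self, cohort_default):
        _, untreated, treated, metadata, _ = cohort_default
        table = CohortTable(untreated, treated, metadata)
        out = ifs.filter_wildtype(table)
        assert list(out.lines) == list(table.lines)

    def test_all_flagged_empties_cohort_with_warning(self, cohort_default):
        _, untreated, treated, metadata, _ = cohort_default
        meta = metadata.copy()
        meta["engineered"] = True
        table = CohortTable(untreated, treated, meta)
        with pytest.warns(UserWarning, match="every line"):
            out = ifs.filter_wildtype(table)
        assert len(out.lines) == 0

    def test_missing_flags_rejected(self, cohort_default):
        _, untreated, treated, metadata, _ = cohort_default
        table = CohortTable(untreated, treated, metadata)
        table.metadata = metadata.drop(columns=["engineered"])
        with pytest.raises(ValueError, match="engineered"):
            ifs.filter_wildtype(table)


class TestResponseScore:
    def test_mean_of_two_genes(self):
        m = abundance([[3.0], [5.0]], ["g1", "g2"], ["l1"])
        score = ifs.ifng_response_score(m, ["g1", "g2"])
        assert score["l1"] == pytest.approx(4.0)

    def test_absent_member_warned_and_ignored(self):
        m = abundance([[3.0], [5.0]], ["g1", "g2"], ["l1"])
        with pytest.warns(UserWarning, match="ghost"):
            score = ifs.ifng_response_score(m, ["g1", "ghost"])
        assert score["l1"] == pytest.approx(3.0)

    def test_empty_intersection_rejected(self):
        m = abundance([[3.0]], ["g1"], ["l1"])
        with pytest.raises(ValueError):
            ifs.ifng_response_score(m, ["nope"])

    def test_invariant_to_genes_outside_set(self, rng):
        genes = [f"g{i}" for i in range(10)]
        lines = [f"l{j}" for j in range(5)]
        base = rng.uniform(0, 8, size=(10, 5))
        m1 = abundance(base, genes, lines)
        extended = np.vstack([base, rng.uniform(0, 8, size=(3, 5))])
        m2 = abundance(extended, genes + ["x1", "x2", "x3"], lines)
        s1 = ifs.ifng_response_score(m1, genes[:4])
        s2 = ifs.ifng_response_score(m2, genes[:4])
        pd.testing.assert_series_equal(s1, s2)

    def test_hand_computed_toy_cohort(self):
        rows = [[1.0, 2.0, 3.0, 4.0, 5.0], [3.0, 4.0, 5.0, 6.0, 7.0]]
        m = abundance(rows, ["g1", "g2"], [f"l{j}" for j in range(5)])
        score = ifs.ifng_response_score(m, ["g1", "g2"])
        np.testing.assert_allclose(score, [2.0, 3.0, 4.0, 5.0, 6.0])


class TestRankAndSplit:
    def test_45_lines_halves_22_23(self, rng):
        values = pd.Series(rng.normal(size=45), index=[f"l{i:02d}" for i in range(45)])
        labels = ifs.rank_and_split(values, "halves")
        assert labels.value_counts().to_dict() == {"lower": 23, "upper": 22}

    def test_45_lines_quartiles_12_each(self, rng):
        values = pd.Series(rng.normal(size=45), index=[f"l{i:02d}" for i in range(45)])
        labels = ifs.rank_and_split(values, "quartiles")
        counts = labels.value_counts().to_dict()
        assert counts["high"] == 12 and counts["low"] == 12

    def test_even_split(self):
        values = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        labels = ifs.rank_and_split(values, "halves")
        assert (labels == "upper").sum() == 2 and (labels == "lower").sum() == 2
        assert labels["a"] == "upper" and labels["d"] == "lower"

    def test_halves_partition_property(self, rng):
        for n in (5, 8, 13, 45):
            values = pd.Series(rng.normal(size=n), index=[f"l{i}" for i in range(n)])
            labels = ifs.rank_and_split(values, "halves")
            upper, lower = (labels == "upper").sum(), (labels == "lower").sum()
            assert upper + lower == n
            if n % 2:
                assert upper == lower - 1

    def test_quartile_groups_disjoint(self, rng):
        values = pd.Series(rng.normal(size=9), index=[f"l{i}" for i in range(9)])
        labels = ifs.rank_and_split(values, "quartiles")
        assert (labels == "high").sum() == 3 and (labels == "low").sum() == 3
        assert not (set(labels[labels == "high"].index) & set(labels[labels == "low"].index))

    def test_ties_resolved_by_line_id_with_warning(self):
        values = pd.Series([1.0, 1.0, 2.0, 0.5], index=["b", "a", "c", "d"])
        with pytest.warns(UserWarning, match="ties"):
            labels = ifs.rank_and_split(values, "halves")
        assert labels["c"] == "upper" and labels["a"] == "upper"


class TestSplitHighLow:
    def test_largest_gap(self):
        values = pd.Series([1.0, 1.1, 1.2, 5.0, 5.1], index=list("abcde"))
        labels = ifs.split_high_low(values, "largest_gap")
        assert set(values.index[labels == "low"]) == {"a", "b", "c"}
        assert set(values.index[labels == "high"]) == {"d", "e"}

    def test_explicit_threshold(self):
        values = pd.Series([1.0, 2.0, 4.0], index=list("abc"))
        labels = ifs.split_high_low(values, "threshold", threshold=3.0)
        assert labels.tolist() == ["low", "low", "high"]

    def test_all_equal_threshold_single_group(self):
        values = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        labels = ifs.split_high_low(values, "threshold", threshold=3.0)
        assert (labels == "low").all()

    def test_all_equal_largest_gap_rejected(self):
        values = pd.Series([2.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError):
            ifs.split_high_low(values, "largest_gap")


class TestAssociate:
    def test_monotone_extremes(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        assert ifs.associate(x, x * 2 + 1, "spearman").value == pytest.approx(1.0)
        assert ifs.associate(x, -x, "spearman").value == pytest.approx(-1.0)

    def test_ties_match_average_rank_oracle(self):
        """Six points with ties: Pearson on average ranks equals our r_s."""
        x = pd.Series([1.0, 2.0, 2.0, 3.0, 4.0, 5.0], index=list("abcdef"))
        y = pd.Series([2.0, 1.0, 3.0, 3.0, 5.0, 4.0], index=list("abcdef"))
        res = ifs.associate(x, y, "spearman")
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert res.value == pytest.approx(expected)

    def test_linreg_recovers_slope(self, rng):
        x = pd.Series(rng.uniform(0, 10, 30))
        y = 2.5 * x + 1.0 + rng.normal(0, 0.01, 30)
        res = ifs.associate(x, y, "linreg")
        assert res.value == pytest.approx(2.5, abs=0.01)
        assert res.extras["intercept"] == pytest.approx(1.0, abs=0.05)

    def test_constant_input_flagged(self):
        x = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            res = ifs.associate(x, y, "spearman")
        assert np.isnan(res.value)

    def test_too_few_points_rejected(self):
        x = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError):
            ifs.associate(x, x, "spearman")


class TestCompareGroups:
    def test_separated_groups_strongly_significant(self):
        values = pd.Series(
            np.concatenate([np.arange(10) + 100.0, np.arange(10)]),
            index=[f"s{i}" for i in range(20)],
        )
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=values.index)
        res = ifs.compare_groups(values, labels, "two_group")
        assert res.p < 0.001

    def test_null_calibration_over_label_permutations(self):
        """Permuted labels reject at 0.05 in at most ~5% of runs."""
        rng = np.random.default_rng(11)
        base = rng.normal(size=20)
        idx = [f"s{i}" for i in range(20)]
        rejections = 0
        for _ in range(100):
            labels = pd.Series(rng.permutation(["a"] * 10 + ["b"] * 10), index=idx)
            res = ifs.compare_groups(pd.Series(base, index=idx), labels, "two_group")
            rejections += res.p < 0.05
        assert rejections <= 10

    def test_kruskal_with_dunn_posthoc(self, rng):
        values = pd.Series(
            np.concatenate([rng.normal(0, 1, 8), rng.normal(0, 1, 8), rng.normal(5, 1, 8)]),
            index=[f"s{i}" for i in range(24)],
        )
        labels = pd.Series(["a"] * 8 + ["b"] * 8 + ["c"] * 8, index=values.index)
        res = ifs.compare_groups(values, labels, "multi_group")
        assert res.p < 0.01
        posthoc = res.extras["posthoc"]
        assert set(posthoc.columns) >= {"group_1", "group_2", "p", "padj"}
        ac = posthoc[(posthoc["group_1"] == "a") & (posthoc["group_2"] == "c")]
        ab = posthoc[(posthoc["group_1"] == "a") & (posthoc["group_2"] == "b")]
        assert ac["padj"].iloc[0] < ab["padj"].iloc[0]

    def test_paired_wilcoxon(self, rng):
        pairs = [f"p{i}" for i in range(12)]
        before = rng.normal(0, 1, 12)
        after = before + 1.0
        values = pd.Series(
            np.concatenate([before, after]), index=[f"s{i}" for i in range(24)]
        )
        labels = pd.Series(["pre"] * 12 + ["post"] * 12, index=values.index)
        pair_ids = pd.Series(pairs + pairs, index=values.index)
        res = ifs.compare_groups(values, labels, "paired", pair_ids=pair_ids)
        assert res.p < 0.01

    def test_paired_zero_differences_flagged(self):
        values = pd.Series([1.0, 2.0, 1.0, 2.0], index=list("abcd"))
        labels = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        pair_ids = pd.Series(["p1", "p2", "p1", "p2"], index=list("abcd"))
        with pytest.warns(UserWarning, match="zero"):
            res = ifs.compare_groups(values, labels, "paired", pair_ids=pair_ids)
        assert res.p == 1.0

    def test_unbalanced_pairing_rejected(self):
        values = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        labels = pd.Series(["x", "x", "y"], index=list("abc"))
        pair_ids = pd.Series(["p1", "p2", "p1"], index=list("abc"))
        with pytest.raises(ValueError, match="p2"):
            ifs.compare_groups(values, labels, "paired", pair_ids=pair_ids)


class TestCorrelationMatrix:
    def test_duplicated_column_perfectly_correlated(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        r, _ = ifs.correlation_matrix(AbundanceMatrix(df, "zscore"))
        assert r.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        df = pd.DataFrame(rng.normal(size=(1000, 5)), columns=list("abcde"))
        r, _ = ifs.correlation_matrix(AbundanceMatrix(df, "zscore"))
        off = r.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.abs(off).mean() < 0.1

    def test_bonferroni_multiplication(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        _, p = ifs.correlation_matrix(AbundanceMatrix(df, "zscore"), "bonferroni")
        raw = [
            stats.pearsonr(df[c1], df[c2]).pvalue
            for c1, c2 in [("a", "b"), ("a", "c"), ("b", "c")]
        ]
        for (c1, c2), pr in zip([("a", "b"), ("a", "c"), ("b", "c")], raw):
            assert p.loc[c1, c2] == pytest.approx(min(pr * 3, 1.0))

    def test_constant_column_flagged(self, rng):
        df = pd.DataFrame(
            {"a": np.ones(20), "b": rng.normal(size=20), "c": rng.normal(size=20)}
        )
        with pytest.warns(UserWarning, match="constant"):
            r, _ = ifs.correlation_matrix(AbundanceMatrix(df, "zscore"))
        assert np.isnan(r.loc["a", "b"])


class TestPca:
    def test_rank_one_data_single_component(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        df = pd.DataFrame(
            {"s1": base, "s2": 2 * base, "s3": 3 * base, "s4": 0.5 * base},
            index=[f"g{i}" for i in range(5)],
        )
        _, _, explained = ifs.pca_embed(AbundanceMatrix(df, "zscore"), k_top=5)
        assert explained[0] >= 0.999

    def test_explained_variance_sorted_and_loadings_orthonormal(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(20, 6)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(6)],
        )
        _, loadings, explained = ifs.pca_embed(AbundanceMatrix(df, "zscore"), k_top=20)
        assert (np.diff(explained) <= 1e-12).all()
        gram = loadings.to_numpy().T @ loadings.to_numpy()
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-9)

    def test_sign_convention_deterministic(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(15, 5)),
            index=[f"g{i}" for i in range(15)],
            columns=[f"s{j}" for j in range(5)],
        )
        m = AbundanceMatrix(df, "zscore")
        s1, l1, _ = ifs.pca_embed(m, k_top=15)
        s2, l2, _ = ifs.pca_embed(m, k_top=15)
        pd.testing.assert_frame_equal(s1, s2)
        for pc in l1.columns:
            nz = l1[pc][l1[pc].abs() > 1e-12]
            assert nz.iloc[0] > 0

    def test_k_top_too_large_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError):
            ifs.pca_embed(AbundanceMatrix(df, "zscore"), k_top=10)


class TestCohortRecovery:
    def test_mitf_low_lines_have_higher_induced_pdl1(self):
        """Planted dedifferentiation coupling is recovered by stratification."""
        wins, rs = 0, []
        for seed in range(10):
            cfg = ifs.SimCohortConfig(seed=seed, pdl1_coupling=0.8, noise_sd=0.2)
            untreated, treated, _, _ = ifs.generate_cohort(cfg)
            l2 = ifs.log2_tpm1(treated)
            mitf = l2.values.loc[cfg.MITF_GENE]
            pdl1 = l2.values.loc[cfg.PDL1_GENE]
            rs.append(ifs.associate(mitf, pdl1, "spearman").value)
            quart = ifs.rank_and_split(mitf, "quartiles")
            low = pdl1[quart[quart == "low"].index].median()
            high = pdl1[quart[quart == "high"].index].median()
            wins += low > high
        assert np.median(rs) < -0.3
        assert wins >= 6  # majority of seeds
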