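import itertools

import numpy as np
import pytest
from scipy import stats as sps

from flybehave import (
    GroupedData,
    check_assumptions,
    compare_groups,
    dunn_posthoc,
    dunn_posthoc_friedman,
    fisher_copulation,
    zero_median_reference_test,
)
from flybehave.errors import DesignError


def _parametric_groups(k, n=30, seed=0):
    rng = np.random.default_rng(seed)
    return {chr(97 + i): rng.normal(10 + i, 2, n) for i in range(k)}


def _nonparametric_groups(k, n=50, seed=100):
    rng = np.random.default_rng(seed)
    return {chr(97 + i): rng.lognormal(1, 1, n) for i in range(k)}


class TestAssumptions:
    def test_normal_same_scale_is_parametric(self):
        ok, evidence = check_assumptions(GroupedData(_parametric_groups(2)))
        assert ok
        assert any(e["test"] == "levene" for e in evidence)

    def test_heavy_tail_is_nonparametric(self):
        rng = np.random.default_rng(3)
        groups = {"a": rng.standard_cauchy(100), "b": rng.normal(0, 1, 100)}
        ok, _ = check_assumptions(GroupedData(groups))
        assert not ok

    def test_constant_group_degenerate(self):
        groups = {"a": np.full(10, 3.0), "b": np.random.default_rng(0).normal(0, 1, 10)}
        ok, evidence = check_assumptions(GroupedData(groups))
        assert not ok
        assert any(e.get("reason") == "degenerate" for e in evidence)

    def test_small_n_skips_dagostino(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.normal(0, 1, 6), "b": rng.normal(0, 1, 6)}
        _, evidence = check_assumptions(GroupedData(groups))
        skipped = [e for e in evidence if e["test"] == "dagostino_pearson"]
        assert all(e["pass"] is None for e in skipped)


class TestDispatchTruthTable:
    """The dispatcher must land on the exact test the decision tree
    prescribes in each (design, parametric, k) cell."""

    EXPECTED = {
        ("independent", True, 2): "unpaired_t",
        ("independent", True, 3): "one_way_anova",
        ("independent", False, 2): "mann_whitney_u",
        ("independent", False, 3): "kruskal_wallis",
        ("dependent", True, 2): "paired_t",
        ("dependent", True, 3): "rm_anova",
        ("dependent", False, 2): "wilcoxon_signed_rank",
        ("dependent", False, 3): "friedman",
    }

    @pytest.mark.parametrize("design,parametric,k",
                             list(itertools.product(
                                 ["independent", "dependent"], [True, False], [2, 3])))
    def test_cell(self, design, parametric, k):
        groups = (_parametric_groups(k) if parametric
                  else _nonparametric_groups(k))
        report = compare_groups(GroupedData(groups, design=design))
        assert report.parametric is parametric
        assert report.test_name == self.EXPECTED[(design, parametric, k)]
        assert 0.0 <= report.p_value <= 1.0
        if k >= 3:
            assert report.posthoc is not None
            assert len(report.posthoc) == 3  # all pairs
        else:
            assert report.posthoc is None

    def test_identical_groups_never_significant(self):
        x = np.arange(20.0)
        report = compare_groups(GroupedData({"a": x, "b": x.copy()},
                                            design="dependent"))
        assert not report.significant

    def test_single_group_is_design_error(self):
        with pytest.raises(DesignError):
            GroupedData({"a": np.arange(5.0)})


class TestPosthoc:
    def test_bonferroni_monotone_and_capped(self):
        table = dunn_posthoc(_nonparametric_groups(4))
        assert (table["p_corrected"] >= table["p_raw"] - 1e-15).all()
        assert (table["p_corrected"] <= 1.0).all()
        assert len(table) == 6

    def test_dunn_matches_brute_force_rederivation(self):
        groups = _nonparametric_groups(3, n=25)
        table = dunn_posthoc(groups)
        pooled = np.concatenate(list(groups.values()))
        ranks = sps.rankdata(pooled)
        n_tot = len(pooled)
        labels = list(groups)
        mean_r, sizes, c = {}, {}, 0
        for lab in labels:
            m = len(groups[lab])
            mean_r[lab] = ranks[c:c + m].mean()
            sizes[lab] = m
            c += m
        _, t = np.unique(pooled, return_counts=True)
        var = n_tot * (n_tot + 1) / 12 - np.sum(t ** 3 - t) / (12 * (n_tot - 1))
        for _, row in table.iterrows():
            a, b = row["group_a"], row["group_b"]
            z = (mean_r[a] - mean_r[b]) / np.sqrt(var * (1 / sizes[a] + 1 / sizes[b]))
            assert row["z"] == pytest.approx(z, rel=1e-12)
            assert row["p_raw"] == pytest.approx(2 * sps.norm.sf(abs(z)), rel=1e-12)

    def test_friedman_dunn_detects_shifted_condition(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(0, 0.5, 40)
        groups = {"x": base, "y": base + rng.normal(0, 0.1, 40),
                  "z": base + 3.0}
        table = dunn_posthoc_friedman(groups)
        row_xy = table[(table.group_a == "x") & (table.group_b == "y")].iloc[0]
        row_xz = table[(table.group_a == "x") & (table.group_b == "z")].iloc[0]
        assert row_xz["p_corrected"] < 0.05 < row_xy["p_corrected"]


def fisher_enumeration_oracle(a, b, c, d):
    """Exhaustive sum of hypergeometric probabilities over all 2x2 tables
    with the observed margins that are no more probable than the observed
    table (two-sided)."""
    n1, k_total = a + b, a + c
    n_total = a + b + c + d
    p_obs = sps.hypergeom.pmf(a, n_total, k_total, n1)
    lo = max(0, k_total - (c + d))
    hi = min(k_total, n1)
    total = sum(
        sps.hypergeom.pmf(k, n_total, k_total, n1)
        for k in range(lo, hi + 1)
        if sps.hypergeom.pmf(k, n_total, k_total, n1) <= p_obs * (1 + 1e-10)
    )
    return min(1.0, total)


class TestFisher:
    def test_identical_proportions(self):
        assert fisher_copulation(5, 10, 5, 10) == pytest.approx(1.0)

    @pytest.mark.parametrize("a,at,b,bt", [
        (0, 10, 10, 10),
        (1, 10, 2, 10),
        (3, 10, 9, 10),
        (2, 20, 11, 20),
    ])
    def test_matches_enumeration_oracle(self, a, at, b, bt):
        p = fisher_copulation(a, at, b, bt)
        oracle = fisher_enumeration_oracle(a, at - a, b, bt - b)
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_symmetry_under_group_swap_and_relabel(self):
        p = fisher_copulation(3, 10, 7, 12)
        assert fisher_copulation(7, 12, 3, 10) == pytest.approx(p, abs=1e-15)
        assert fisher_copulation(7, 10, 5, 12) == pytest.approx(
            fisher_copulation(3, 10, 7, 12), abs=1e-15
        )

    def test_zero_total_is_design_error(self):
        with pytest.raises(DesignError):
            fisher_copulation(0, 0, 1, 10)


class TestZeroMedianReference:
    def test_near_zero_group_not_significant(self):
        rng = np.random.default_rng(2)
        group = rng.normal(0, 1, 30)
        group -= np.median(group)
        report = zero_median_reference_test(group, seed=9)
        assert not report.significant

    def test_large_shift_significant(self):
        rng = np.random.default_rng(2)
        group = rng.normal(0, 1, 30) + 10.0
        report = zero_median_reference_test(group, seed=9)
        assert report.significant

    def test_deterministic_per_seed(self):
        group = np.random.default_rng(4).normal(1, 2, 25)
        r1 = zero_median_reference_test(group, seed=11)
        r2 = zero_median_reference_test(group, seed=11)
        assert r1.p_value == r2.p_value
        r3 = zero_median_reference_test(group, seed=12)
        assert r3.p_value != r1.p_value

    def test_zero_variance_degenerate(self):
        with pytest.raises(DesignError):
            zero_median_reference_test(np.full(10, 2.0), seed=0)


class TestReportSerialization:
    def test_yaml_round_trip_fields(self, tmp_path):
        import yaml

        report = compare_groups(GroupedData(_nonparametric_groups(3)))
        text = report.to_yaml(tmp_path / "r.yaml")
        data = yaml.safe_load(text)
        assert data["test"] == "kruskal_wallis"
        assert 0 <= data["p_value"] <= 1
        assert len(data["posthoc"]) == 3
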