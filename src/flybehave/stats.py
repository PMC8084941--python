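"""Assumption-checked test dispatch for grouped behavioral data.

Every group comparison follows one decision tree.  Variance homogeneity
is assessed with Levene's test and normality with both Shapiro–Wilk and
D'Agostino–Pearson; data are treated as parametric only if every group
passes both normality tests and Levene's test (all at alpha, default
0.05).  Dispatch:

====================  =======================  ============================
design                parametric               nonparametric
====================  =======================  ============================
independent, k = 2    unpaired t-test          Mann–Whitney U
independent, k >= 3   one-way ANOVA + Tukey    Kruskal–Wallis + Dunn
dependent,   k = 2    paired t-test            Wilcoxon signed-rank
dependent,   k >= 3   RM-ANOVA + pairwise      Friedman + Dunn
                      paired t (Bonferroni)
====================  =======================  ============================

Bonferroni correction is applied whenever multiple post hoc comparisons
are performed.  Copulation rates between two groups are compared with
Fisher's exact test.  A single sample can also be compared against a
random reference sample with median zero and matched variance using the
Wilcoxon rank-sum test (used for lightsOFF-baseline speed deltas).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .errors import DesignError

DEFAULT_ALPHA = 0.05
#: D'Agostino–Pearson needs enough observations for the kurtosis moment
#: test; below this it is skipped (Shapiro–Wilk only) and flagged.
DAGOSTINO_MIN_N = 8


@dataclass
class GroupedData:
    """Labelled numeric samples with an independent or dependent design.

    Dependent (repeated measures) designs require equal-length groups with
    subjects aligned by position: element i of every group belongs to
    subject i.
    """

    groups: dict[str, np.ndarray]
    design: str = "independent"  # or "dependent"

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if self.design not in ("independent", "dependent"):
            raise DesignError(f"unknown design {self.design!r}")
        if len(self.groups) < 2:
            raise DesignError("need at least 2 groups")
        if self.design == "dependent":
            lengths = {len(v) for v in self.groups.values()}
            if len(lengths) != 1:
                raise DesignError("dependent design requires aligned equal-n groups")

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    @property
    def values(self) -> list[np.ndarray]:
        return list(self.groups.values())


@dataclass
class StatReport:
    """Outcome of one dispatched comparison."""

    test_name: str
    statistic: Optional[float]
    p_value: float
    alpha: float
    parametric: Optional[bool] = None
    assumptions: list[dict] = field(default_factory=list)
    posthoc: Optional[pd.DataFrame] = None
    notes: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        d = {
            "test": self.test_name,
            "statistic": None if self.statistic is None else float(self.statistic),
            "p_value": float(self.p_value),
            "alpha": self.alpha,
            "parametric": self.parametric,
            "assumptions": self.assumptions,
            "notes": list(self.notes),
        }
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

def check_assumptions(data: GroupedData, alpha: float = DEFAULT_ALPHA
                      ) -> tuple[bool, list[dict]]:
    """Normality (Shapiro–Wilk + D'Agostino–Pearson per group) and variance
    homogeneity (Levene across groups).

    Returns ``(parametric, evidence)``: parametric iff every group passes
    both normality tests AND Levene's test, all at ``alpha`` (p > alpha
    counts as a pass).  Degenerate (constant or tiny) groups are
    non-parametric by fiat, with a reason recorded.
    """
    evidence: list[dict] = []
    parametric = True
    for label, x in data.groups.items():
        if len(x) < 3 or np.ptp(x) == 0:
            evidence.append({"group": label, "test": "normality",
                             "statistic": None, "p": None,
                             "pass": False, "reason": "degenerate"})
            parametric = False
            continue
        w, p_sw = sps.shapiro(x)
        ok = p_sw > alpha
        evidence.append({"group": label, "test": "shapiro_wilk",
                         "statistic": float(w), "p": float(p_sw), "pass": bool(ok)})
        parametric &= ok
        if len(x) >= DAGOSTINO_MIN_N:
            k2, p_dp = sps.normaltest(x)
            ok = p_dp > alpha
            evidence.append({"group": label, "test": "dagostino_pearson",
                             "statistic": float(k2), "p": float(p_dp),
                             "pass": bool(ok)})
            parametric &= ok
        else:
            evidence.append({"group": label, "test": "dagostino_pearson",
                             "statistic": None, "p": None, "pass": None,
                             "reason": f"skipped_n<{DAGOSTINO_MIN_N}"})
    try:
        w, p_lev = sps.levene(*data.values)
        ok = p_lev > alpha
        evidence.append({"group": "all", "test": "levene", "statistic": float(w),
                         "p": float(p_lev), "pass": bool(ok)})
        parametric &= ok
    except ValueError:
        evidence.append({"group": "all", "test": "levene", "statistic": None,
                         "p": None, "pass": False, "reason": "degenerate"})
        parametric = False
    return bool(parametric), evidence


# ---------------------------------------------------------------------------
# post hoc tests
# ---------------------------------------------------------------------------

def bonferroni(p: float, m: int) -> float:
    return float(min(1.0, p * m))


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise test after Kruskal–Wallis.

    Uses pooled ranks over all observations with a tie correction; z for a
    pair (i, j) is the mean-rank difference over its standard error, p is
    two-sided normal, corrected p is Bonferroni over all pairs.
    """
    labels = list(groups)
    values = [np.asarray(groups[l], float) for l in labels]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for label, x in zip(labels, values):
        mean_ranks[label] = float(np.mean(ranks[start:start + len(x)]))
        sizes[label] = len(x)
        start += len(x)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_factor * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z),
                     "p_raw": float(p), "p_corrected": bonferroni(p, len(pairs))})
    return pd.DataFrame(rows)


def dunn_posthoc_friedman(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise test after Friedman: treatments ranked within each
    subject (block); z = mean-rank difference / sqrt(k(k+1)/(6n))."""
    labels = list(groups)
    mat = np.column_stack([np.asarray(groups[l], float) for l in labels])
    n, k = mat.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, mat)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pairs = list(itertools.combinations(range(k), 2))
    rows = []
    for i, j in pairs:
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": float(z),
                     "p_raw": float(p), "p_corrected": bonferroni(p, len(pairs))})
    return pd.DataFrame(rows)


def _tukey_posthoc(data: GroupedData, alpha: float) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(data.values)
    labels = np.concatenate(
        [[label] * len(x) for label, x in data.groups.items()]
    )
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return frame.rename(columns={"group1": "group_a", "group2": "group_b",
                                 "p-adj": "p_corrected"})


def _paired_t_posthoc(data: GroupedData) -> pd.DataFrame:
    pairs = list(itertools.combinations(data.labels, 2))
    rows = []
    for a, b in pairs:
        t, p = sps.ttest_rel(data.groups[a], data.groups[b])
        rows.append({"group_a": a, "group_b": b, "statistic": float(t),
                     "p_raw": float(p), "p_corrected": bonferroni(p, len(pairs))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# omnibus dispatch
# ---------------------------------------------------------------------------

def _rm_anova(data: GroupedData) -> tuple[float, float]:
    from statsmodels.stats.anova import AnovaRM

    n = len(data.values[0])
    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), data.k),
        "condition": np.repeat(data.labels, n),
        "value": np.concatenate(data.values),
    })
    res = AnovaRM(long, depvar="value", subject="subject",
                  within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    return float(row["F Value"]), float(row["Pr > F"])


def compare_groups(data: GroupedData, alpha: float = DEFAULT_ALPHA) -> StatReport:
    """Dispatch the appropriate omnibus test (and post hoc table for
    k >= 3) according to the design and the assumption checks."""
    parametric, evidence = check_assumptions(data, alpha)
    k = data.k
    posthoc = None
    if data.design == "independent":
        if parametric:
            if k == 2:
                name = "unpaired_t"
                stat, p = sps.ttest_ind(*data.values)
            else:
                name = "one_way_anova"
                stat, p = sps.f_oneway(*data.values)
                posthoc = _tukey_posthoc(data, alpha)
        else:
            if k == 2:
                name = "mann_whitney_u"
                stat, p = sps.mannwhitneyu(*data.values, alternative="two-sided")
            else:
                name = "kruskal_wallis"
                stat, p = sps.kruskal(*data.values)
                posthoc = dunn_posthoc(data.groups)
    else:
        if parametric:
            if k == 2:
                name = "paired_t"
                stat, p = sps.ttest_rel(*data.values)
            else:
                name = "rm_anova"
                stat, p = _rm_anova(data)
                posthoc = _paired_t_posthoc(data)
        else:
            if k == 2:
                name = "wilcoxon_signed_rank"
                stat, p = sps.wilcoxon(*data.values)
            else:
                name = "friedman"
                stat, p = sps.friedmanchisquare(*data.values)
                posthoc = dunn_posthoc_friedman(data.groups)
    return StatReport(
        test_name=name, statistic=float(stat), p_value=float(p), alpha=alpha,
        parametric=parametric, assumptions=evidence, posthoc=posthoc,
    )


def fisher_copulation(a_success: int, a_total: int,
                      b_success: int, b_total: int) -> float:
    """Two-sided Fisher's exact p for a difference in copulation rate
    between two groups (successes = copulating females)."""
    for s, t in ((a_success, a_total), (b_success, b_total)):
        if t <= 0:
            raise DesignError("group total must be positive")
        if not 0 <= s <= t:
            raise DesignError("successes must lie in [0, total]")
    table = [[a_success, a_total - a_success], [b_success, b_total - b_success]]
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return float(p)


def zero_median_reference_test(
    group: np.ndarray, seed: int, alpha: float = DEFAULT_ALPHA
) -> StatReport:
    """Wilcoxon rank-sum comparison of one sample against a random
    reference with median zero and matched variance.

    The reference is drawn from a normal with the group's sample standard
    deviation (same n) and then median-centred, the simplest construction
    with median around zero and equivalent variance.  Deterministic per
    seed.  Used e.g. to ask whether lightsOFF − baseline speed deltas
    recentre on zero after activation ends.
    """
    group = np.asarray(group, dtype=float)
    if len(group) < 5:
        raise DesignError("need n >= 5 for the reference comparison")
    sd = float(np.std(group, ddof=1))
    if sd == 0:
        raise DesignError("zero-variance group: reference comparison degenerate")
    rng = np.random.default_rng(seed)
    reference = rng.normal(0.0, sd, size=len(group))
    reference -= np.median(reference)
    stat, p = sps.ranksums(group, reference)
    return StatReport(
        test_name="wilcoxon_rank_sum_vs_zero_median_reference",
        statistic=float(stat), p_value=float(p), alpha=alpha,
        notes=[f"reference: normal(0, sd={sd:.6g}) median-centred, n={len(group)}"],
    )
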