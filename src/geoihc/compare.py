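"""Group comparisons and correlation structure of the IHC-derived metrics.

Wilcoxon rank-sum tests compare nearest-neighbor distance distributions
(cells as observations), Welch two-sample t-tests compare metric values
between first-line therapy responders and resistant patients, and Spearman
correlations summarize pairwise relations between metrics with the usual
strength bins (weak 0.2-0.4, moderate 0.4-0.6, strong 0.6-1.0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: Sample-size bound below which the rank-sum p value is computed by exact
#: enumeration rather than the continuity-corrected normal approximation.
EXACT_WILCOXON_MAX_N = 50


@dataclass
class ComparisonResult:
    label: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    summary_a: float        # median (Wilcoxon) or mean (t-test)
    summary_b: float
    test: str
    statistic: float
    p: float


def wilcoxon_test(sample_a: np.ndarray, sample_b: np.ndarray, *,
                  label: str = "", group_a: str = "A",
                  group_b: str = "B") -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison.

    Exact enumeration is used for small samples (both n <= 50, no ties
    across groups); otherwise the normal approximation with continuity
    correction.  Fully tied inputs give p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        stat = float(len(a) * len(b) / 2.0)
        return ComparisonResult(label, group_a, group_b, len(a), len(b),
                                float(np.median(a)), float(np.median(b)),
                                "wilcoxon", stat, 1.0)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= EXACT_WILCOXON_MAX_N
                         and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return ComparisonResult(label, group_a, group_b, len(a), len(b),
                            float(np.median(a)), float(np.median(b)),
                            "wilcoxon", float(res.statistic),
                            float(min(res.pvalue, 1.0)))


def ttest_two_sample(sample_a: np.ndarray, sample_b: np.ndarray, *,
                     label: str = "", group_a: str = "A",
                     group_b: str = "B") -> ComparisonResult:
    """Welch two-sample t-test (unequal variances), two-tailed."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2 for a t-test")
    if np.var(a) == 0 and np.var(b) == 0:
        if a[0] == b[0]:
            return ComparisonResult(label, group_a, group_b, len(a), len(b),
                                    float(np.mean(a)), float(np.mean(b)),
                                    "welch_t", 0.0, 1.0)
        raise ValueError("both samples have zero variance; t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(label, group_a, group_b, len(a), len(b),
                            float(np.mean(a)), float(np.mean(b)),
                            "welch_t", float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# Spearman correlation matrix
# ---------------------------------------------------------------------------

def correlation_strength(r: float) -> str:
    """Strength label for a Spearman coefficient, following the bins used in
    the field: weak (0.2-0.4), moderate (0.4-0.6), strong (0.6-1.0); values
    between -0.4 and 0.2 are 'none/weak-negative', below -0.4 'negative'."""
    if math.isnan(r):
        return "undefined"
    if r >= 0.6:
        return "strong"
    if r >= 0.4:
        return "moderate"
    if r >= 0.2:
        return "weak"
    if r >= -0.4:
        return "none/weak-negative"
    return "negative"


@dataclass
class CorrelationMatrix:
    metrics: list[str]
    r: pd.DataFrame          # symmetric, diagonal 1
    n: pd.DataFrame          # complete pairs used per entry
    strength: pd.DataFrame   # strength label per entry


def spearman_matrix(table: pd.DataFrame, metric_names: Optional[Sequence[str]] = None,
                    min_pairs: int = 3) -> CorrelationMatrix:
    """Pairwise Spearman rho between metric columns, with pairwise deletion.

    Pairs with fewer than ``min_pairs`` complete observations, or involving
    a constant metric, are flagged NaN / 'undefined'.
    """
    if metric_names is None:
        metric_names = [c for c in table.columns
                        if pd.api.types.is_numeric_dtype(table[c])]
    names = list(metric_names)
    k = len(names)
    r = pd.DataFrame(np.eye(k), index=names, columns=names)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=names, columns=names)
    for name in names:
        n.loc[name, name] = int(table[name].notna().sum())
    for a, b in combinations(names, 2):
        pair = table[[a, b]].dropna()
        n.loc[a, b] = n.loc[b, a] = len(pair)
        if len(pair) < min_pairs or pair[a].nunique() <= 1 or pair[b].nunique() <= 1:
            r.loc[a, b] = r.loc[b, a] = np.nan
            if len(pair) >= min_pairs:
                log.warning("Spearman undefined for constant metric pair (%s, %s)", a, b)
            continue
        rho = stats.spearmanr(pair[a], pair[b]).statistic
        r.loc[a, b] = r.loc[b, a] = float(rho)
    strength = r.map(correlation_strength)
    return CorrelationMatrix(metrics=names, r=r, n=n, strength=strength)


# ---------------------------------------------------------------------------
# Stratified NN-distance comparisons
# ---------------------------------------------------------------------------

def stratified_nn_comparison(nn_table: pd.DataFrame, strata_col: str,
                             strata_pair: tuple[str, str],
                             pairs: Sequence[tuple[str, str]] = (
                                 ("aSMA", "Ki67"), ("aSMA", "Casp3")),
                             ) -> list[ComparisonResult]:
    """Wilcoxon comparisons of NN-distance distributions across two strata.

    ``nn_table`` is long-format with columns ``from_marker, to_marker,
    distance`` and a stratum column.  For each directed marker pair the two
    strata's distance distributions are compared; in addition, within each
    stratum the two target types (e.g. distance-to-Ki67 vs distance-to-
    Casp3 from the same source type) are compared against each other.
    Strata or pairs without cells are skipped with a log entry.
    """
    results: list[ComparisonResult] = []
    s_a, s_b = strata_pair

    def subset(stratum, frm, to):
        m = ((nn_table[strata_col] == stratum)
             & (nn_table["from_marker"] == frm)
             & (nn_table["to_marker"] == to))
        return nn_table.loc[m, "distance"].to_numpy(dtype=float)

    for frm, to in pairs:
        a = subset(s_a, frm, to)
        b = subset(s_b, frm, to)
        if len(a) == 0 or len(b) == 0:
            log.warning("NN comparison %s->%s skipped: empty stratum (%s vs %s)",
                        frm, to, s_a, s_b)
            continue
        results.append(wilcoxon_test(a, b, label=f"{frm}->{to}",
                                     group_a=str(s_a), group_b=str(s_b)))
    # within-stratum comparison of the two target types
    if len(pairs) == 2 and pairs[0][0] == pairs[1][0]:
        frm = pairs[0][0]
        for stratum in strata_pair:
            a = subset(stratum, frm, pairs[0][1])
            b = subset(stratum, frm, pairs[1][1])
            if len(a) == 0 or len(b) == 0:
                log.warning("within-stratum NN comparison skipped for %s", stratum)
                continue
            results.append(wilcoxon_test(
                a, b, label=f"{frm}->{pairs[0][1]} vs {frm}->{pairs[1][1]}",
                group_a=f"{stratum}:{pairs[0][1]}", group_b=f"{stratum}:{pairs[1][1]}"))
    return results


def comparison_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
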