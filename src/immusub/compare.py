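"""Cross-subtype comparison statistics and derived microenvironment fractions.

Rank tests (Kruskal-Wallis with Dunn-Bonferroni post hoc, Wilcoxon
rank-sum) and count associations (Fisher exact / Pearson chi-square) for
comparing immune and genomic features between subtypes, plus the two
derived quantities used on deconvolution output: stromal fraction
(1 - tumour purity) and absolute immune-cell proportions (relative
proportions scaled by the leukocyte fraction).

Dunn's test is written out here (pooled midranks with tie correction, the
Dunn 1964 form) since no installed package provides it; everything else
delegates to scipy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import SubtypeLabels
from .containers import SurvivalData
from .survival import km_estimate, logrank_test

__all__ = [
    "GroupComparisonResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "rank_sum_test",
    "count_association",
    "stromal_fraction",
    "absolute_proportions",
    "response_stratified_survival",
]

log = logging.getLogger(__name__)


@dataclass
class GroupComparisonResult:
    test: str
    statistic: float
    df: int | None
    p: float
    pairwise: pd.DataFrame | None = None  # group_a, group_b, statistic, p_raw, p_adj
    adjustment: str | None = None


def _split(values, groups):
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups differ in length")
    levels = pd.unique(groups)
    return [values[groups == g] for g in levels], list(levels)


def kruskal_wallis(values, groups) -> GroupComparisonResult:
    """Kruskal-Wallis H with midrank tie correction (chi-square p, k-1 df)."""
    samples, levels = _split(values, groups)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    if np.ptp(np.asarray(values, float)) == 0:
        # every observation identical: the tie correction is degenerate and
        # there is no evidence of a difference
        return GroupComparisonResult("kruskal-wallis", 0.0, len(levels) - 1, 1.0)
    H, p = stats.kruskal(*samples)
    return GroupComparisonResult("kruskal-wallis", float(H), len(levels) - 1, float(p))


def dunn_posthoc(values, groups, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z-tests on the pooled midranks after Kruskal-Wallis.

    z_ij = (rbar_i - rbar_j) / sqrt[(N(N+1)/12 - T) (1/n_i + 1/n_j)] with
    tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p, Bonferroni
    multiplied by the number of pairs and capped at 1.
    """
    if adjust != "bonferroni":
        raise ValueError("only bonferroni adjustment is implemented")
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    samples, levels = _split(values, groups)
    for g, s in zip(levels, samples):
        if len(s) == 0:
            raise ValueError(f"group {g!r} is empty")
    N = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    var_unit = N * (N + 1) / 12.0 - tie_term
    mean_rank = {g: ranks[groups == g].mean() for g in levels}
    n = {g: (groups == g).sum() for g in levels}
    pairs = list(combinations(levels, 2))
    rows = []
    for a, b in pairs:
        denom = np.sqrt(var_unit * (1.0 / n[a] + 1.0 / n[b]))
        z = 0.0 if denom == 0 else (mean_rank[a] - mean_rank[b]) / denom
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, z, p_raw, min(1.0, p_raw * len(pairs))))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "z", "p_raw", "p_adj"]
    )


def rank_sum_test(x, y, alternative: str = "two-sided"):
    """Wilcoxon rank-sum / Mann-Whitney U.

    Exact p by full enumeration when n1 + n2 <= 12 and there are no ties,
    otherwise the normal approximation with tie-corrected variance and
    continuity correction.  Returns (U of the first sample, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def count_association(table, method: str = "auto") -> GroupComparisonResult:
    """Association in an r x c count table.

    ``auto`` chooses Fisher's exact test (2x2 only, two-sided by the
    probability-mass rule) when any expected count is below 5, otherwise
    the Pearson chi-square without continuity correction.  Zero-margin
    tables are degenerate: p = 1 with a warning.
    """
    T = np.asarray(table)
    if (T < 0).any() or not np.issubdtype(T.dtype, np.integer):
        T = T.astype(float)
        if not np.allclose(T, np.round(T)) or (T < 0).any():
            raise ValueError("counts must be non-negative integers")
        T = T.astype(int)
    if (T.sum(axis=0) == 0).any() or (T.sum(axis=1) == 0).any():
        log.warning("zero-margin contingency table; association undefined")
        return GroupComparisonResult("degenerate", 0.0, None, 1.0)
    expected = np.outer(T.sum(axis=1), T.sum(axis=0)) / T.sum()
    if method == "auto":
        method = "fisher" if (T.shape == (2, 2) and (expected < 5).any()) else "chisq"
    if method == "fisher":
        if T.shape != (2, 2):
            raise ValueError("Fisher's exact test supports 2x2 tables only")
        odds, p = stats.fisher_exact(T, alternative="two-sided")
        return GroupComparisonResult("fisher", float(odds), None, float(p))
    chi2, p, df, _ = stats.chi2_contingency(T, correction=False)
    return GroupComparisonResult("chi-square", float(chi2), int(df), float(p))


def stromal_fraction(purity):
    """Stromal (non-tumour) fraction = 1 - tumour purity; elementwise."""
    purity = np.asarray(purity, float)
    if ((purity < 0) | (purity > 1)).any():
        raise ValueError("purity must lie in [0, 1]")
    out = 1.0 - purity
    return float(out) if out.ndim == 0 else out


def absolute_proportions(relative, leukocyte_fraction):
    """Scale relative immune-cell proportions by the leukocyte fraction."""
    rel = np.asarray(relative, float)
    lf = float(leukocyte_fraction)
    if ((rel < 0) | (rel > 1)).any() or not 0 <= lf <= 1:
        raise ValueError("proportions and leukocyte fraction must lie in [0, 1]")
    return rel * lf


def response_stratified_survival(
    data: SurvivalData,
    labels: SubtypeLabels,
    response: pd.Series | None = None,
    subtype_pair: tuple = ("IS2", "IS4"),
) -> dict:
    """Does the subtype survival contrast persist within response strata?

    For each response stratum (e.g. CR vs non-CR) the designated subtype
    pair is compared by KM + log-rank; strata containing fewer than two of
    the pair's subtypes are skipped with a warning.  Also returns the
    subtype x response count table and its chi-square association.
    """
    if response is None:
        if "response" not in data.table:
            raise ValueError("no response column available")
        response = data.table["response"]
    response = pd.Series(response).reindex(data.sample_ids)
    lab = labels.subtype_of_sample.reindex(data.sample_ids)
    keep = lab.isin(subtype_pair) & response.notna() & lab.notna()
    lab, response = lab[keep], response[keep]
    sub = data.subset(lab.index)

    counts = pd.crosstab(lab, response)
    assoc = count_association(counts.to_numpy(), method="chisq")

    strata = {}
    for r in sorted(response.unique()):
        in_stratum = response == r
        present = lab[in_stratum].unique()
        if len(present) < 2:
            log.warning("stratum %r has a single subtype; comparison skipped", r)
            strata[r] = {"skipped": True, "subtypes_present": list(present)}
            continue
        s_data = sub.subset(lab.index[in_stratum])
        stat, df, p = logrank_test(s_data, lab[in_stratum])
        strata[r] = {
            "skipped": False,
            "km": km_estimate(s_data, lab[in_stratum]),
            "logrank": {"statistic": stat, "df": df, "p": p},
        }
    return {"counts": counts, "association": assoc, "strata": strata}
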