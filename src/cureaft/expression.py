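"""Expression-side group comparisons: rank tests between tumour subtypes,
the dichotomized-expression contingency test, and the four-group
(high/low biomarker x metastasis/"cured") proliferation-marker comparison.

The "cured" label is operational: within the high-biomarker group every
event occurred before some last event time t*, so a patient censored
beyond t* is taken as cured, while a patient censored at or before t* is
ambiguous (could still progress) and is excluded.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import SurvivalRecord

__all__ = [
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "fisher_exact_2x2",
    "subtype_by_expression_table",
    "define_outcome_groups",
    "compare_marker",
    "GROUP_NAMES",
]

#: Four-group coding; 0 marks exclusion (ambiguous follow-up).
GROUP_NAMES = {
    1: "high, with DM",
    2: "high, cured",
    3: "low, with DM",
    4: "low, cured",
    0: "excluded",
}

#: Below this combined sample size (and without ties) the Wilcoxon p-value
#: is computed by exact enumeration; otherwise the tie-corrected normal
#: approximation with continuity correction is used.
EXACT_WILCOXON_LIMIT = 20


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Returns the Mann-Whitney U statistic of ``x`` and the two-sided p:
    exact enumeration when the combined sample is small and tie-free,
    normal approximation with tie and continuity corrections otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_WILCOXON_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H test (tie-corrected) across two or more groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("all groups must be nonempty")
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    The two-sided p sums hypergeometric probabilities (margins fixed) of
    every table at most as probable as the observed one.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("table entries must be nonnegative")
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValueError("table entries must be integers")
    _, p = stats.fisher_exact(arr.astype(int), alternative="two-sided")
    return float(p)


def subtype_by_expression_table(
    annotations: pd.DataFrame,
    biomarker: Mapping[str, float],
    cutoff: float,
    subtypes: tuple[str, str] = ("luminalA", "luminalB"),
) -> pd.DataFrame:
    """Contingency table of tumour subtype vs low/high biomarker expression.

    ``annotations`` needs columns ``sample_id`` and ``subtype``;
    ``biomarker`` maps sample id -> expression value (a pandas Series
    indexed by sample id works).  The dichotomization rule matches the
    cutoff scan: value > cutoff is high.
    """
    counts = pd.DataFrame(0, index=list(subtypes), columns=["low", "high"])
    for _, row in annotations.iterrows():
        if row["subtype"] not in subtypes:
            continue
        sid = row["sample_id"]
        try:
            value = float(biomarker[sid])
        except KeyError:
            raise ValueError(f"missing biomarker value for sample {sid!r}")
        counts.loc[row["subtype"], "high" if value > cutoff else "low"] += 1
    return counts


def define_outcome_groups(
    records: Sequence[SurvivalRecord], high_indicator: Sequence[int]
) -> np.ndarray:
    """Assign each record to the four outcome groups (0 = excluded).

    The cure horizon t* is the latest event time within the high group.
    Events go to group 1 (high) or 3 (low); records censored strictly
    beyond t* go to group 2 (high) or 4 (low); records censored at or
    before t* are excluded as ambiguous.
    """
    high = np.asarray(high_indicator, dtype=int)
    if len(high) != len(records):
        raise ValueError("high_indicator must align with records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    high_event_times = times[(high == 1) & events]
    if len(high_event_times) == 0:
        raise ValueError("no events in the high group; cure horizon undefined")
    t_star = float(high_event_times.max())

    labels = np.zeros(len(records), dtype=int)
    labels[events & (high == 1)] = 1
    labels[events & (high == 0)] = 3
    cured = ~events & (times > t_star)
    labels[cured & (high == 1)] = 2
    labels[cured & (high == 0)] = 4
    return labels


def compare_marker(
    marker_values: Sequence[float],
    labels: Sequence[int],
    group_a: int = 1,
    group_b: int = 3,
) -> float:
    """Wilcoxon comparison of a marker gene between two outcome groups."""
    values = np.asarray(marker_values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(values) != len(labels):
        raise ValueError("marker values must align with labels")
    a = values[labels == group_a]
    b = values[labels == group_b]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            f"empty group after exclusions (group {group_a}: {len(a)}, "
            f"group {group_b}: {len(b)})"
        )
    _, p = wilcoxon_rank_sum(a, b)
    return p
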