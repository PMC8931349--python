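"""Aggregation and group comparison of per-curve fit results.

Per-cell values are the median over that cell's (typically triplicate)
curves.  Groups are compared with a Kruskal-Wallis H test followed by
pairwise Welch t-tests as post-hoc analysis; Holm correction of the post-hoc
p values is available but off by default.  Significance labels: '***' for
p < 0.001, 'n.s.' for p > 0.05, '*' in between.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "aggregate_per_cell",
    "summarize_groups",
    "compare_groups",
    "significance_label",
]

DEFAULT_PARAMS = ("E0_Pa", "E1_Pa", "eta_Pa_s", "Eu_Pa", "Eapp_Pa")


@dataclass(frozen=True)
class GroupSummary:
    """Distribution summary of one parameter within one group."""

    group: str
    parameter: str
    n: int
    median: float
    p10: float
    p25: float
    p75: float
    p90: float
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if not (self.p10 <= self.p25 <= self.median <= self.p75 <= self.p90):
            raise ValueError("percentiles out of order")


def significance_label(p: float) -> str:
    if p < 0.001:
        return "***"
    if p > 0.05:
        return "n.s."
    return "*"


def aggregate_per_cell(
    results: pd.DataFrame,
    cell_col: str = "cell_id",
    value_cols: tuple[str, ...] = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Collapse per-curve rows to per-cell medians (one row per cell).

    Group labels are carried through; order of input rows is irrelevant.
    """
    cols = [c for c in value_cols if c in results.columns]
    keys = [cell_col] + (["group"] if "group" in results.columns else [])
    out = results.groupby(keys, sort=True)[cols].median().reset_index()
    return out


def summarize_groups(
    values: pd.DataFrame,
    group_col: str = "group",
    value_cols: tuple[str, ...] = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Box-plot style summary (median, 10/25/75/90th percentiles, mean +- SEM)."""
    rows = []
    for g, sub in values.groupby(group_col, sort=True):
        for c in value_cols:
            if c not in sub.columns:
                continue
            x = sub[c].dropna().to_numpy()
            if len(x) == 0:
                continue
            q = np.percentile(x, [10, 25, 50, 75, 90])
            rows.append(GroupSummary(
                group=str(g), parameter=c, n=len(x), median=float(q[2]),
                p10=float(q[0]), p25=float(q[1]), p75=float(q[3]), p90=float(q[4]),
                mean=float(np.mean(x)),
                sem=float(sps.sem(x)) if len(x) > 1 else 0.0,
            ))
    return pd.DataFrame([asdict(r) for r in rows])


def compare_groups(
    values: dict[str, np.ndarray] | pd.DataFrame,
    group_col: str = "group",
    value_col: str | None = None,
    holm: bool = False,
) -> dict:
    """Kruskal-Wallis across groups plus pairwise Welch t-tests.

    Accepts either a mapping group -> 1-d array, or a DataFrame with a group
    column and a value column.  All-tied input degenerates to H = 0, p = 1.
    Returns a JSON-serialisable dict with the omnibus test, the pairwise
    post-hoc table and significance labels.
    """
    if isinstance(values, pd.DataFrame):
        if value_col is None:
            raise ValueError("value_col required with a DataFrame input")
        values = {
            str(g): sub[value_col].dropna().to_numpy()
            for g, sub in values.groupby(group_col, sort=True)
        }
    groups = {g: np.asarray(x, float) for g, x in sorted(values.items())}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, x in groups.items():
        if len(x) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 observations")

    samples = list(groups.values())
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*samples)

    pairs = []
    for a, b in combinations(groups, 2):
        t, pt = sps.ttest_ind(groups[a], groups[b], equal_var=False)
        pairs.append({"a": a, "b": b, "t": float(t), "p": float(pt)})
    if holm and pairs:
        order = np.argsort([q["p"] for q in pairs])
        m = len(pairs)
        prev = 0.0
        for rank, i in enumerate(order):
            adj = min(1.0, (m - rank) * pairs[i]["p"])
            prev = max(prev, adj)  # enforce monotonicity
            pairs[i]["p_adj"] = prev
    for q in pairs:
        q["label"] = significance_label(q.get("p_adj", q["p"]))

    return {
        "kruskal_H": float(H),
        "kruskal_p": float(p),
        "label": significance_label(p),
        "n_groups": len(groups),
        "n_per_group": {g: int(len(x)) for g, x in groups.items()},
        "pairwise": pairs,
        "holm": holm,
    }
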