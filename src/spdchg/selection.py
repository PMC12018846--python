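"""Top/bottom selection from all-hybrid predictions and field-validation
selection-gain arithmetic (percent gain of the validated top set over the
validated bottom set, over the validated overall mean, and counts exceeding a
check variety at 0% and +5% margins)."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ModelError

__all__ = ["select_extremes", "selection_gain", "SelectionReport", "overlap_counts"]


def _hybrid_id(a: str, b: str) -> str:
    a, b = sorted((str(a), str(b)))
    return f"{a}x{b}"


def select_extremes(
    predictions: pd.DataFrame, k_top: int = 100, k_bottom: int = 100
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The ``k_top`` highest- and ``k_bottom`` lowest-predicted hybrids.

    Ranking is deterministic: ties are broken by (parentA, parentB)
    lexicographic order, so the result is stable under permutation of the
    input rows.
    """
    n = len(predictions)
    if k_top + k_bottom > n:
        raise ModelError(f"k_top + k_bottom = {k_top + k_bottom} exceeds {n} predictions")
    df = predictions.copy()
    df["hybrid"] = [
        _hybrid_id(a, b) for a, b in zip(df["parentA"], df["parentB"])
    ]
    up = df.sort_values(
        ["predicted", "parentA", "parentB"], ascending=[False, True, True], kind="stable"
    )
    down = df.sort_values(
        ["predicted", "parentA", "parentB"], ascending=[True, True, True], kind="stable"
    )
    return up.head(k_top).reset_index(drop=True), down.head(k_bottom).reset_index(drop=True)


@dataclass
class SelectionReport:
    """Field-validation summary for one selection method."""

    method: str
    n_top_validated: int
    n_bottom_validated: int
    mean_top: float
    mean_bottom: float
    overall_mean: float  # mean of ALL validated hybrids
    gain_vs_bottom_pct: float
    gain_vs_mean_pct: float
    check_value: float | None = None
    n_exceed_check: int | None = None
    n_exceed_check_5pct: int | None = None
    extra: dict = field(default_factory=dict)


def selection_gain(
    validated: pd.DataFrame,
    top: list[str] | pd.DataFrame,
    bottom: list[str] | pd.DataFrame,
    check_value: float | None = None,
    method: str = "model",
    hybrid_col: str = "hybrid",
    value_col: str = "observed",
) -> SelectionReport:
    """Percent selection gains over validated field observations.

    gain_vs_bottom = (mean_top - mean_bottom) / mean_bottom * 100 and
    gain_vs_mean = (mean_top - overall_mean) / overall_mean * 100, computed
    only over validated entries; the overall mean is the mean of every
    validated hybrid. ``check_value`` adds counts of validated hybrids that
    exceed the check and exceed it by more than 5%.
    """
    obs = validated.set_index(validated[hybrid_col].astype(str))[value_col].astype(float)

    def ids(sel):
        if isinstance(sel, pd.DataFrame):
            return [str(h) for h in sel["hybrid"]]
        return [str(h) for h in sel]

    top_obs = obs.reindex(ids(top)).dropna()
    bot_obs = obs.reindex(ids(bottom)).dropna()
    for side, vals in (("top", top_obs), ("bottom", bot_obs)):
        if vals.empty:
            raise ModelError(f"no validated observations in the {side} selection")
    mean_top, mean_bottom = float(top_obs.mean()), float(bot_obs.mean())
    overall = float(obs.mean())
    report = SelectionReport(
        method=method,
        n_top_validated=len(top_obs),
        n_bottom_validated=len(bot_obs),
        mean_top=mean_top,
        mean_bottom=mean_bottom,
        overall_mean=overall,
        gain_vs_bottom_pct=(mean_top - mean_bottom) / mean_bottom * 100.0,
        gain_vs_mean_pct=(mean_top - overall) / overall * 100.0,
    )
    if check_value is not None:
        report.check_value = float(check_value)
        report.n_exceed_check = int((obs > check_value).sum())
        report.n_exceed_check_5pct = int((obs > 1.05 * check_value).sum())
    return report


def overlap_counts(selections: dict[str, set | list]) -> dict:
    """Venn-region cardinalities for >= 2 named selections.

    Returns every exclusive region keyed by the sorted tuple of member names,
    plus pairwise intersection counts and the union size.
    """
    if len(selections) < 2:
        raise ModelError("need at least 2 selections")
    sets = {k: set(map(str, v)) for k, v in selections.items()}
    names = sorted(sets)
    union = set().union(*sets.values())
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set().union(*(sets[c] for c in names if c not in combo)) if len(combo) < len(names) else set()
            regions[combo] = len(inside - outside)
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in itertools.combinations(names, 2)
    }
    return {
        "regions": regions,
        "pairwise": pairwise,
        "union": len(union),
        "intersection": len(set.intersection(*sets.values())),
    }
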