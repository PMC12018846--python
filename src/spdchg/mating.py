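"""Sparse partial diallel crossing plans between heterotic groups.

A plan is a duplicate-free list of unordered, non-self parent pairs
(reciprocals collapsed; pairs stored in lexicographic parent order) together
with the heterotic-group assignment of every line.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PlanError

__all__ = [
    "CrossPlan",
    "enumerate_potential_hybrids",
    "generate_spdc_plan",
    "plan_stats",
    "read_plan_tsv",
]


@dataclass
class CrossPlan:
    """Unordered parent-pair list with heterotic-group metadata."""

    pairs: list[tuple[str, str]]
    groups: pd.Series  # line -> heterotic group label

    def __post_init__(self) -> None:
        pairs = [tuple(sorted((str(a), str(b)))) for a, b in self.pairs]
        for a, b in pairs:
            if a == b:
                raise PlanError(f"self cross {a} x {b} not allowed in a plan")
        if len(set(pairs)) != len(pairs):
            raise PlanError("duplicate pairs (after collapsing reciprocals)")
        known = set(self.groups.index.astype(str))
        missing = {p for pair in pairs for p in pair} - known
        if missing:
            raise PlanError(f"lines missing from group table: {sorted(missing)[:5]}")
        self.pairs = pairs
        self.groups = self.groups.copy()
        self.groups.index = self.groups.index.astype(str)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def lines(self) -> list[str]:
        return sorted({p for pair in self.pairs for p in pair})

    def pair_types(self) -> list[str]:
        g = self.groups
        return [
            "between" if g[a] != g[b] else "within" for a, b in self.pairs
        ]

    def to_frame(self) -> pd.DataFrame:
        g = self.groups
        return pd.DataFrame(
            {
                "parentA": [a for a, _ in self.pairs],
                "parentB": [b for _, b in self.pairs],
                "groupA": [g[a] for a, _ in self.pairs],
                "groupB": [g[b] for _, b in self.pairs],
                "type": self.pair_types(),
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_plan_tsv(path: str | Path, groups: pd.Series | None = None) -> CrossPlan:
    df = pd.read_csv(path, sep="\t", dtype=str)
    pairs = list(zip(df["parentA"], df["parentB"]))
    if groups is None:
        ga = df.set_index("parentA")["groupA"]
        gb = df.set_index("parentB")["groupB"]
        groups = pd.concat([ga, gb]).groupby(level=0).first()
    return CrossPlan(pairs, groups)


def enumerate_potential_hybrids(lines) -> list[tuple[str, str]] | int:
    """All unordered non-self pairs of ``lines``.

    Given an integer n, returns the count n(n-1)/2; given a list of line ids,
    returns the sorted pair list.
    """
    if isinstance(lines, (int, np.integer)):
        n = int(lines)
        if n < 2:
            raise PlanError(f"need at least 2 lines, got {n}")
        return n * (n - 1) // 2
    names = sorted(str(s) for s in lines)
    if len(set(names)) != len(names):
        raise PlanError("duplicate line identifiers")
    if len(names) < 2:
        raise PlanError(f"need at least 2 lines, got {len(names)}")
    return list(itertools.combinations(names, 2))


def generate_spdc_plan(
    groups: pd.Series,
    n_crosses: int | None = None,
    crosses_per_line_target: float | None = None,
    between_group_fraction: float = 0.8,
    seed: int = 0,
) -> CrossPlan:
    """Randomized sparse partial diallel in which every line participates.

    A first pass pairs each not-yet-covered line with a random partner
    (drawn from another heterotic group with probability
    ``between_group_fraction``), guaranteeing coverage; remaining crosses are
    filled by weighted random sampling up to the target size. Seed-deterministic.
    """
    groups = groups.copy()
    groups.index = groups.index.astype(str)
    lines = list(groups.index)
    n = len(lines)
    if n < 2:
        raise PlanError("need at least 2 lines")
    if n_crosses is None:
        if crosses_per_line_target is None:
            raise PlanError("give n_crosses or crosses_per_line_target")
        n_crosses = int(round(crosses_per_line_target * n / 2))
    total_possible = n * (n - 1) // 2
    if n_crosses < (n + 1) // 2:
        raise PlanError(
            f"{n_crosses} crosses cannot cover {n} lines (need >= ceil(n/2))"
        )
    if n_crosses > total_possible:
        raise PlanError(
            f"{n_crosses} crosses exceed the {total_possible} possible pairs"
        )
    if not 0.0 <= between_group_fraction <= 1.0:
        raise PlanError("between_group_fraction must be in [0,1]")
    by_group: dict[str, list[str]] = {}
    for ln, gp in groups.items():
        by_group.setdefault(gp, []).append(ln)
    if between_group_fraction > 0 and len(by_group) < 2:
        raise PlanError("between-group crosses requested but only one group present")
    n_between_possible = (
        total_possible - sum(len(v) * (len(v) - 1) // 2 for v in by_group.values())
    )
    if between_group_fraction > 0 and n_between_possible == 0:
        raise PlanError("no between-group pair exists")

    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    degree = {ln: 0 for ln in lines}

    def add(a: str, b: str) -> bool:
        pair = tuple(sorted((a, b)))
        if pair[0] == pair[1] or pair in chosen:
            return False
        chosen.add(pair)
        degree[a] += 1
        degree[b] += 1
        return True

    def sample_partner(a: str, want_between: bool, prefer_uncovered: bool) -> str | None:
        if want_between:
            pool = [x for x in lines if groups[x] != groups[a]]
        else:
            pool = [x for x in by_group[groups[a]] if x != a]
        if not pool:
            return None
        if prefer_uncovered:
            unc = [x for x in pool if degree[x] == 0]
            if unc:
                pool = unc
        for _ in range(50):
            cand = pool[rng.integers(len(pool))]
            if tuple(sorted((a, cand))) not in chosen:
                return cand
        rest = [x for x in pool if tuple(sorted((a, x))) not in chosen]
        return rest[rng.integers(len(rest))] if rest else None

    # pass 1: coverage
    order = list(rng.permutation(lines))
    for ln in order:
        if degree[ln] > 0:
            continue
        want_between = rng.random() < between_group_fraction
        partner = sample_partner(ln, want_between, prefer_uncovered=True)
        if partner is None:
            partner = sample_partner(ln, not want_between, prefer_uncovered=True)
        if partner is None:
            raise PlanError(f"line {ln} cannot reach any cross")
        add(ln, partner)
    # pass 2: fill to size, tracking the between/within mix
    guard = 0
    while len(chosen) < n_crosses:
        guard += 1
        if guard > 60 * n_crosses:
            raise PlanError("could not reach the requested plan size; targets infeasible")
        n_between = sum(1 for a, b in chosen if groups[a] != groups[b])
        frac = n_between / len(chosen)
        if between_group_fraction >= 1.0:
            want_between = True
        elif between_group_fraction <= 0.0:
            want_between = False
        else:
            want_between = frac < between_group_fraction
        a = lines[rng.integers(n)]
        partner = sample_partner(a, want_between, prefer_uncovered=False)
        if partner is None and 0.0 < between_group_fraction < 1.0:
            # soft target: allow the other pair type rather than stall
            partner = sample_partner(a, not want_between, prefer_uncovered=False)
        if partner is not None:
            add(a, partner)
    return CrossPlan(sorted(chosen), groups)


def plan_stats(plan: CrossPlan) -> dict:
    """Participation counts, group x group cross matrix and between/within totals."""
    part = pd.Series(0, index=pd.Index(sorted(plan.groups.index), name="line"), dtype=int)
    for a, b in plan.pairs:
        part[a] += 1
        part[b] += 1
    glabels = sorted(plan.groups.unique())
    mat = pd.DataFrame(0, index=glabels, columns=glabels, dtype=int)
    n_between = 0
    for a, b in plan.pairs:
        ga, gb = sorted((plan.groups[a], plan.groups[b]))
        mat.loc[ga, gb] += 1
        if ga != gb:
            n_between += 1
    return {
        "n_crosses": len(plan),
        "participation": part,
        "participation_distribution": part.value_counts().sort_index(),
        "group_matrix": mat,
        "n_between": n_between,
        "n_within": len(plan) - n_between,
        "mean_crosses_per_line": 2.0 * len(plan) / max(len(part), 1),
    }
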