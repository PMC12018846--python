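"""General combining ability from genomic all-hybrid prediction.

A trained hybrid model is applied to every potential single cross of a line
panel; a line's GCA is its average predicted hybrid performance, centered on
the all-hybrid mean, so complete-diallel GCAs sum to zero by construction.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ModelError
from .genotypes import GenotypeMatrix
from .mixed_models import CvResult, cross_validate, fit_line_model

__all__ = [
    "predict_all_hybrids",
    "estimate_gca",
    "gca_group_summary",
    "gca_cv",
    "rank_parents",
]


def predict_all_hybrids(
    fit,
    genotypes: GenotypeMatrix,
    lines: list[str] | None = None,
    chunk_size: int = 5000,
) -> pd.DataFrame:
    """Predict every potential single cross among ``lines`` (default: the whole
    panel) with a trained hybrid model exposing ``predict(Za, Zd)``.

    Pairs are evaluated in chunks so peak memory stays constant in the number
    of chunks. Returns a frame with parentA, parentB, predicted.
    """
    if fit is None or not hasattr(fit, "predict"):
        raise ModelError("untrained or invalid model")
    names = sorted(lines) if lines is not None else sorted(genotypes.lines)
    if len(names) < 2:
        raise ModelError("need at least 2 lines")
    idx = genotypes.line_index(names)
    X = genotypes.X[idx]
    if np.isnan(X).any():
        raise ModelError("missing genotypes; run qc_filter first")
    if (X == 1).any():
        X = np.where(X == 1, 0.0, X)  # residual hets resolved as in coding inference
    pa, pb, pred = [], [], []
    pairs_iter = itertools.combinations(range(len(names)), 2)
    while True:
        block = list(itertools.islice(pairs_iter, chunk_size))
        if not block:
            break
        i1 = np.fromiter((a for a, _ in block), dtype=int, count=len(block))
        i2 = np.fromiter((b for _, b in block), dtype=int, count=len(block))
        Za = (X[i1] + X[i2]) / 2.0
        Zd = (X[i1] != X[i2]).astype(float)
        pred.append(np.asarray(fit.predict(Za, Zd)).ravel())
        pa.extend(names[a] for a in i1)
        pb.extend(names[b] for b in i2)
    return pd.DataFrame({"parentA": pa, "parentB": pb, "predicted": np.concatenate(pred)})


def estimate_gca(
    predictions: pd.DataFrame,
    trait: str = "trait",
    groups: pd.Series | None = None,
    value_col: str = "predicted",
) -> pd.DataFrame:
    """Per-line GCA from (predicted or observed) hybrid values.

    GCA_i = mean over partners j != i of y_ij, minus the grand mean of all
    hybrid values. Expects the complete diallel of a line set by default but
    works on any stated subset; a line with zero combinations raises.
    Returns a GcaTable frame: line, group, trait, gca, n_combinations.
    """
    vals = predictions[value_col].to_numpy(dtype=float)
    pa = predictions["parentA"].astype(str).to_numpy()
    pb = predictions["parentB"].astype(str).to_numpy()
    if len(vals) == 0:
        raise ModelError("no predictions")
    lines = sorted(set(pa) | set(pb))
    lut = {s: i for i, s in enumerate(lines)}
    sums = np.zeros(len(lines))
    counts = np.zeros(len(lines), dtype=int)
    for arr in (pa, pb):
        ii = np.fromiter((lut[s] for s in arr), dtype=int, count=len(arr))
        np.add.at(sums, ii, vals)
        np.add.at(counts, ii, 1)
    if (counts == 0).any():  # unreachable through the constructor above
        raise ModelError("line with zero hybrid combinations")
    grand = vals.mean()
    gca = sums / counts - grand
    out = pd.DataFrame(
        {
            "line": lines,
            "group": [groups.get(s, "NA") for s in lines] if groups is not None else "NA",
            "trait": trait,
            "gca": gca,
            "n_combinations": counts,
        }
    )
    return out


def gca_group_summary(gca: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Per-heterotic-group GCA means with a one-way ANOVA and Tukey HSD
    compact letter display at ``alpha``.

    Groups with fewer than 2 lines are dropped from the Tukey comparison with
    a warning. With a single group only the summary is returned.
    """
    df = gca[["line", "group", "gca"]].copy()
    summary = (
        df.groupby("group")["gca"].agg(n="size", mean="mean", sd="std").reset_index()
    )
    out = {"summary": summary, "anova_F": np.nan, "anova_p": np.nan, "letters": None}
    groups = [g for _, g in df.groupby("group")["gca"]]
    if len(groups) < 2:
        return out
    F, p = stats.f_oneway(*[g.to_numpy() for g in groups])
    out["anova_F"], out["anova_p"] = float(F), float(p)
    sizes = df.groupby("group")["gca"].size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"groups dropped from Tukey (n<2): {small}", stacklevel=2)
    keep = df[~df["group"].isin(small)]
    if keep["group"].nunique() >= 2:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tk = pairwise_tukeyhsd(keep["gca"], keep["group"], alpha=alpha)
        res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        out["tukey"] = res
        out["letters"] = _compact_letters(
            sorted(keep["group"].unique()),
            {(str(r["group1"]), str(r["group2"])): bool(r["reject"]) for _, r in res.iterrows()},
        )
    return out


def _compact_letters(groups: list[str], reject: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Greedy compact letter display from pairwise rejection decisions."""
    def differ(a, b):
        return reject.get((a, b), reject.get((b, a), False))

    letters: list[set[str]] = []  # each letter = a set of mutually-compatible groups
    for g in groups:
        placed = False
        for s in letters:
            if all(not differ(g, h) for h in s):
                s.add(g)
                placed = True
        if not placed:
            letters.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return {
        g: "".join(alphabet[i] for i, s in enumerate(letters) if g in s) for g in groups
    }


def gca_cv(
    gca: pd.DataFrame,
    genotypes: GenotypeMatrix,
    model: str = "gblup",
    folds: int = 5,
    repeats: int = 20,
    seed: int = 0,
    **model_kw,
) -> CvResult:
    """Cross-validated predictability of GCA from line genotypes.

    Folds partition LINES (never hybrids), so no line contributes to both
    training and testing; the model is trained on training-line GCA against
    additive line dosages and accuracy is the Pearson correlation on held-out
    lines, pooled within a repeat.
    """
    lines = gca["line"].astype(str).tolist()
    if len(lines) < folds:
        raise ModelError(f"fewer lines ({len(lines)}) than folds ({folds})")
    y = gca["gca"].to_numpy(dtype=float)
    Z = genotypes.X[genotypes.line_index(lines)]

    def fit_predict(tr, te):
        f = fit_line_model(model, y[tr], Z[tr], **model_kw)
        return f.predict(Z[te])

    return cross_validate(fit_predict, y, folds=folds, repeats=repeats, seed=seed)


def rank_parents(
    gca: pd.DataFrame,
    trait: str | None = None,
    direction: str = "high",
    top_hybrids: list[tuple[str, str]] | None = None,
    bottom_hybrids: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Deterministic GCA ranking of parents for one trait.

    ``direction`` 'high' ranks the largest GCA first, 'low' the smallest.
    Ties are broken lexicographically by line id. Lines appearing in supplied
    top/bottom hybrid sets are annotated (in_top / in_bottom).
    """
    if direction not in ("high", "low"):
        raise ModelError(f"unknown direction {direction!r} (use 'high' or 'low')")
    df = gca.copy()
    if trait is not None:
        df = df[df["trait"] == trait]
        if df.empty:
            raise ModelError(f"no GCA rows for trait {trait!r}")
    if df["line"].duplicated().any():
        raise ModelError("rank_parents expects a single trait; duplicate lines found")
    df = df.sort_values(
        ["gca", "line"], ascending=[direction == "low", True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    top_lines = {p for pair in (top_hybrids or []) for p in pair}
    bot_lines = {p for pair in (bottom_hybrids or []) for p in pair}
    df["in_top"] = df["line"].isin(top_lines)
    df["in_bottom"] = df["line"].isin(bot_lines)
    return df
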