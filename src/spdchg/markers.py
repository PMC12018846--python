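"""Post-GWAS machinery: significance thresholds, cross-method consensus,
marker-set construction and evaluation, superior-genotype accumulation and
the Type I-V classification of significant SNPs.

External multi-locus GWAS results are first-class inputs (an association
table of SNP x trait x method scores); a simple PC-corrected single-marker
scan is provided as plumbing so the consensus pipeline runs end-to-end on
synthetic data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import pca_scores
from .errors import ModelError
from .genotypes import GenotypeMatrix, infer_hybrid_genotypes
from .mixed_models import fit_hybrid_model

__all__ = [
    "significance_threshold",
    "assoc_scan",
    "read_association_tsv",
    "consensus_snps",
    "MarkerSet",
    "build_marker_sets",
    "evaluate_marker_sets",
    "superior_genotypes",
    "classify_snp_types",
    "HIGHER_BETTER_TRAITS",
    "LOWER_BETTER_TRAITS",
]

ASSOC_COLUMNS = ["snp", "chrom", "pos", "trait", "target", "method", "score", "score_type"]

# default trait directions: yield/ear traits up, architecture/cob traits down
HIGHER_BETTER_TRAITS = {"EW", "EGW", "ERN", "KNR", "ED", "EL"}
LOWER_BETTER_TRAITS = {"CD", "PH", "EH"}


def significance_threshold(m: int) -> float:
    """-log10(1/m) = log10(m): the genome-wide score cutoff for m markers."""
    if m < 1:
        raise ModelError(f"marker count must be >= 1, got {m}")
    return float(np.log10(m))


def assoc_scan(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    n_pcs: int = 3,
    trait: str = "trait",
    target: str = "trait_per_se",
    method: str | None = None,
) -> pd.DataFrame:
    """Single-marker linear-model scan with principal-component correction.

    For each SNP fits y ~ intercept + top ``n_pcs`` PCs + SNP and scores the
    SNP by -log10 of its two-sided p-value. Constant SNPs score 0. This is a
    plumbing stand-in for external multi-locus GWAS tools, labelled
    ``lm_pc{n_pcs}``; import real results with :func:`read_association_tsv`.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = genotypes.X
    n, m = X.shape
    if y.size != n:
        raise ModelError("phenotype length does not match panel size")
    if n_pcs > 0:
        pcs, _ = pca_scores(genotypes, n_pcs)
        C = np.hstack([np.ones((n, 1)), pcs.to_numpy()])
    else:
        C = np.ones((n, 1))
    # residualize y and markers on covariates, then per-marker slope t-test
    Q, _ = np.linalg.qr(C)
    ry = y - Q @ (Q.T @ y)
    RX = X - Q @ (Q.T @ X)
    df = n - C.shape[1] - 1
    if df < 1:
        raise ModelError("not enough residual degrees of freedom")
    sxx = np.sum(RX**2, axis=0)
    ok = sxx > 1e-12
    score = np.zeros(m)
    sxy = RX.T @ ry
    syy = float(ry @ ry)
    with np.errstate(divide="ignore", invalid="ignore"):
        bhat = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
        rss = syy - bhat * sxy
        rss = np.maximum(rss, 1e-300)
        tstat = bhat / np.sqrt(rss / (df * np.where(ok, sxx, 1.0)))
    p = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
    score[ok] = -np.log10(np.maximum(p, 1e-300))
    return pd.DataFrame(
        {
            "snp": genotypes.markers,
            "chrom": genotypes.chrom,
            "pos": genotypes.pos,
            "trait": trait,
            "target": target,
            "method": method or f"lm_pc{n_pcs}",
            "score": score,
            "score_type": "-log10p",
        }
    )


def read_association_tsv(path) -> pd.DataFrame:
    """Read an externally produced association table (columns snp, chrom, pos,
    trait, target, method, score, score_type)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise ModelError(f"association table lacks columns: {missing}")
    if (df["score"] < 0).any():
        raise ModelError("association scores must be >= 0")
    if df.duplicated(["snp", "trait", "target", "method"]).any():
        raise ModelError("duplicate (snp, trait, target, method) rows")
    return df[ASSOC_COLUMNS]


def threshold_table(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Keep rows at or above a method's own significance cutoff
    (-log10 >= log10(m) for p-value scans, LOD >= 3 for LOD-based methods)."""
    return table[table["score"] >= threshold].copy()


def consensus_snps(
    tables: list[pd.DataFrame], min_methods: int, trait: str | None = None,
    target: str | None = None,
) -> list[str]:
    """SNPs significant for the same trait/target in at least ``min_methods``
    distinct methods. Each input table must already be thresholded by its own
    rule. Empty inputs yield an empty list."""
    frames = [t for t in tables if t is not None and len(t)]
    all_methods = set()
    for t in tables:
        if t is not None and "method" in t:
            all_methods.update(t["method"].unique())
    # an empty table still represents one method's (null) result
    n_methods = max(len(all_methods), len([t for t in tables if t is not None]))
    if min_methods > max(n_methods, 1):
        raise ModelError(
            f"min_methods={min_methods} exceeds the {n_methods} methods supplied"
        )
    if not frames:
        return []
    df = pd.concat(frames, ignore_index=True)
    if trait is not None:
        df = df[df["trait"] == trait]
    if target is not None:
        df = df[df["target"] == target]
    counts = df.groupby("snp")["method"].nunique()
    return sorted(counts[counts >= min_methods].index.astype(str))


@dataclass
class MarkerSet:
    name: str
    snps: list[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snps)


_SET_NAMES = (
    "All SNPs",
    "GCA_SNP1", "Rnd GCA_SNP1",
    "GCA_SNP2", "Rnd GCA_SNP2",
    "Trait_SNP1", "Rnd Trait_SNP1",
    "Trait_SNP2", "Rnd Trait_SNP2",
)


def build_marker_sets(
    gca_tables: list[pd.DataFrame],
    trait_tables: list[pd.DataFrame],
    all_snps: list[str],
    seed: int = 0,
) -> dict[str, MarkerSet]:
    """The nine named marker sets used to compare prediction accuracy.

    GCA_SNP1 / GCA_SNP2: SNPs significant for GCA in >=1 / >=2 methods;
    Trait_SNP1 / Trait_SNP2 likewise for the trait per se; each consensus set
    has a random counterpart of exactly the same size drawn uniformly without
    replacement from the genotyped panel (seed-deterministic), plus All SNPs.
    Input tables must already be thresholded.
    """
    all_snps = [str(s) for s in all_snps]
    rng = np.random.default_rng(seed)
    sets: dict[str, MarkerSet] = {
        "All SNPs": MarkerSet("All SNPs", list(all_snps), {"kind": "all"})
    }
    specs = [
        ("GCA_SNP1", gca_tables, 1),
        ("GCA_SNP2", gca_tables, 2),
        ("Trait_SNP1", trait_tables, 1),
        ("Trait_SNP2", trait_tables, 2),
    ]
    panel = set(all_snps)
    for name, tables, level in specs:
        snps = [s for s in consensus_snps(tables, level) if s in panel]
        sets[name] = MarkerSet(name, snps, {"kind": "consensus", "min_methods": level})
        rnd_name = f"Rnd {name}"
        if not snps:
            warnings.warn(f"{name} is empty; {rnd_name} will be empty too", stacklevel=2)
            chosen = []
        else:
            chosen = sorted(rng.choice(all_snps, size=len(snps), replace=False))
        sets[rnd_name] = MarkerSet(
            rnd_name, list(chosen), {"kind": "random", "reference": name, "seed": seed}
        )
    assert tuple(sets) == _SET_NAMES or set(sets) == set(_SET_NAMES)
    return sets


def evaluate_marker_sets(
    sets: dict[str, MarkerSet],
    genotypes: GenotypeMatrix,
    train_pairs,
    y_train: np.ndarray,
    test_pairs,
    y_test: np.ndarray,
    model: str = "gblup",
    **model_kw,
) -> pd.DataFrame:
    """Prediction accuracy (Pearson r on a disjoint test hybrid set) per
    marker set: the model is retrained on the training hybrids using only the
    set's SNPs."""
    marker_pos = {s: j for j, s in enumerate(genotypes.markers)}
    train_coding = infer_hybrid_genotypes(genotypes, train_pairs)
    test_coding = infer_hybrid_genotypes(genotypes, test_pairs)
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    rows = []
    for name, ms in sets.items():
        if len(ms) == 0:
            raise ModelError(f"marker set {name!r} is empty")
        cols = np.array([marker_pos[s] for s in ms.snps if s in marker_pos])
        if cols.size == 0:
            raise ModelError(f"marker set {name!r} has no genotyped SNPs")
        fit = fit_hybrid_model(
            model, y_train, train_coding.Za[:, cols], train_coding.Zd[:, cols], **model_kw
        )
        pred = fit.predict(test_coding.Za[:, cols], test_coding.Zd[:, cols])
        rows.append(
            {
                "set": name,
                "n_snps": int(cols.size),
                "accuracy": float(np.corrcoef(y_test, pred)[0, 1]),
            }
        )
    return pd.DataFrame(rows)


def superior_genotypes(
    snps: list[str],
    dosages: np.ndarray,
    markers: list[str],
    values: np.ndarray,
    direction: str = "higher",
    min_class_size: int = 5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Superior genotype class per SNP and per-individual accumulation counts.

    ``dosages`` are additive codes (0/1/2) of the scored individuals (inbred
    lines against GCA values, or hybrids against phenotypes); the superior
    class of a SNP is the dosage class with the most favorable mean value
    (``direction`` 'higher' or 'lower'). Classes below ``min_class_size`` are
    ignored; SNPs with a single usable class are skipped with a warning.

    Returns (per-SNP table, accumulation count of superior genotypes per
    individual across the usable SNPs).
    """
    if direction not in ("higher", "lower"):
        raise ModelError(f"unknown direction {direction!r}")
    values = np.asarray(values, dtype=float)
    X = np.asarray(dosages, dtype=float)
    lut = {s: j for j, s in enumerate(markers)}
    rows = []
    counts = np.zeros(X.shape[0], dtype=int)
    skipped = []
    for s in snps:
        j = lut.get(str(s))
        if j is None:
            raise ModelError(f"SNP {s!r} not genotyped")
        col = X[:, j]
        classes = [c for c in np.unique(col) if np.sum(col == c) >= min_class_size]
        if len(classes) < 2:
            skipped.append(str(s))
            continue
        means = {c: float(values[col == c].mean()) for c in classes}
        best = (max if direction == "higher" else min)(means, key=means.get)
        counts += (col == best).astype(int)
        rows.append(
            {"snp": str(s), "superior_class": float(best),
             **{f"mean_class_{int(c)}": means[c] for c in classes}}
        )
    if skipped:
        warnings.warn(f"skipped SNPs with <2 usable classes: {skipped}", stacklevel=2)
    return pd.DataFrame(rows), counts


def _tukey_superior(col, values, classes, direction, alpha):
    """Classes not significantly worse than the best class, by Tukey HSD."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    means = {c: float(values[col == c].mean()) for c in classes}
    best = (max if direction == "higher" else min)(means, key=means.get)
    mask = np.isin(col, classes)
    tk = pairwise_tukeyhsd(values[mask], col[mask].astype(int), alpha=alpha)
    res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    superior = {best}
    for _, r in res.iterrows():
        a, b = float(r["group1"]), float(r["group2"])
        if best in (a, b) and not bool(r["reject"]):
            superior.add(b if a == best else a)
    return superior, best, means


def classify_snp_types(
    snps: list[str],
    inbred_dosages: np.ndarray,
    inbred_markers: list[str],
    inbred_values: np.ndarray,
    hybrid_dosages: np.ndarray,
    hybrid_markers: list[str],
    hybrid_values: np.ndarray,
    direction: str = "higher",
    alpha: float = 0.05,
    min_class_size: int = 3,
) -> pd.DataFrame:
    """Type I-V classification of significant SNPs.

    Inbreds carry two homozygous classes (Welch t-test); hybrids up to three
    classes (one-way ANOVA + Tukey HSD at ``alpha``; the hybrid superior set
    is every class not significantly worse than the best).

    Type I: both tests significant, single homozygous hybrid superior equal to
    the inbred superior. Type II: both significant, hybrid superior set =
    {heterozygote, homozygote} with the homozygote matching the inbred
    superior. Type III: hybrid superior is the heterozygote alone. Type IV:
    significant, superior hybrid homozygote differs from the inbred superior.
    Type V: no significant difference in either population. Anything else is
    'unclassified' with diagnostics.
    """
    inb_lut = {s: j for j, s in enumerate(inbred_markers)}
    hyb_lut = {s: j for j, s in enumerate(hybrid_markers)}
    inbred_values = np.asarray(inbred_values, dtype=float)
    hybrid_values = np.asarray(hybrid_values, dtype=float)
    Xi = np.asarray(inbred_dosages, dtype=float)
    Xh = np.asarray(hybrid_dosages, dtype=float)
    rows = []
    for s in snps:
        s = str(s)
        ji, jh = inb_lut.get(s), hyb_lut.get(s)
        if ji is None or jh is None:
            raise ModelError(f"SNP {s!r} missing from a panel")
        ci = Xi[:, ji]
        ch = Xh[:, jh]
        inb_classes = [c for c in (0.0, 2.0) if np.sum(ci == c) >= min_class_size]
        hyb_classes = [c for c in (0.0, 1.0, 2.0) if np.sum(ch == c) >= min_class_size]
        flag = "" if len(hyb_classes) == 3 else "missing_hybrid_class"
        rec = {"snp": s, "type": "unclassified", "flag": flag}
        if len(inb_classes) == 2:
            g0 = inbred_values[ci == inb_classes[0]]
            g2 = inbred_values[ci == inb_classes[1]]
            t, p_inb = stats.ttest_ind(g0, g2, equal_var=False)
            inb_sig = bool(p_inb < alpha)
            inb_best = inb_classes[int(np.argmax([g0.mean(), g2.mean()]))] if direction == "higher" else inb_classes[int(np.argmin([g0.mean(), g2.mean()]))]
        else:
            p_inb, inb_sig, inb_best = np.nan, False, np.nan
            rec["flag"] = (rec["flag"] + ";missing_inbred_class").strip(";")
        if len(hyb_classes) >= 2:
            groups = [hybrid_values[ch == c] for c in hyb_classes]
            _, p_hyb = stats.f_oneway(*groups)
            hyb_sig = bool(p_hyb < alpha)
            superior, hyb_best, hyb_means = _tukey_superior(
                ch, hybrid_values, hyb_classes, direction, alpha
            )
        else:
            p_hyb, hyb_sig, superior, hyb_best, hyb_means = np.nan, False, set(), np.nan, {}
        rec.update(
            p_inbred=float(p_inb) if np.isfinite(p_inb) else np.nan,
            p_hybrid=float(p_hyb) if np.isfinite(p_hyb) else np.nan,
            inbred_superior=inb_best,
            hybrid_superior=",".join(str(int(c)) for c in sorted(superior)),
            **{f"hybrid_mean_{int(c)}": v for c, v in hyb_means.items()},
        )
        hom_sup = {c for c in superior if c in (0.0, 2.0)}
        if not inb_sig and not hyb_sig:
            rec["type"] = "V"
        elif inb_sig and hyb_sig:
            if superior == {1.0}:
                rec["type"] = "III"
            elif len(superior) == 1 and hom_sup == {inb_best}:
                rec["type"] = "I"
            elif superior == {1.0} | hom_sup and len(hom_sup) == 1 and inb_best in hom_sup:
                rec["type"] = "II"
            elif len(hom_sup) >= 1 and inb_best not in hom_sup:
                rec["type"] = "IV"
        rows.append(rec)
    return pd.DataFrame(rows)
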