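"""Synthetic breeding populations: structured inbred panels, diallel hybrid
sets and simulated quantitative traits.

The generator emulates the statistical structure that the downstream analyses
assume: several heterotic groups of fully homozygous inbred lines, biallelic
SNPs spread over a handful of chromosomes, hybrids coded from their parents,
and traits controlled by evenly spaced QTL with gamma-distributed effects at
a target heritability. Genotypes follow a Balding-Nichols model: an ancestral
allele frequency per SNP, Beta-perturbed per heterotic group with
differentiation ``fst``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, PlanError
from .genotypes import GenotypeMatrix
from .mating import CrossPlan, enumerate_potential_hybrids, generate_spdc_plan

__all__ = ["SimConfig", "TrueGeneticValues", "sim_genotypes", "sim_trait", "sim_design_study"]


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    n_lines, n_groups : inbred panel size and number of heterotic groups.
    n_snps, n_chromosomes : biallelic markers, spread evenly over chromosomes.
    fst : Balding-Nichols differentiation between heterotic groups, in (0,1).
    n_qtl, h2 : trait architecture - QTL count and broad-sense (additive +
        dominance) heritability target on the simulated hybrid set.
    dominance_ratio : |d|/|a| at every QTL (0 = purely additive trait).
    effect_distribution : name + parameters of the |additive effect| law;
        default gamma(shape=1, scale=1) with random Rademacher signs.
    group_sizes : optional explicit sizes (must sum to n_lines); near-equal
        split when omitted.
    """

    n_lines: int
    n_snps: int
    n_qtl: int
    h2: float
    n_groups: int = 5
    n_chromosomes: int = 10
    fst: float = 0.2
    dominance_ratio: float = 0.5
    effect_distribution: dict = field(
        default_factory=lambda: {"name": "gamma", "shape": 1.0, "scale": 1.0}
    )
    group_sizes: list[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups > self.n_lines:
            raise ConfigError("n_groups > n_lines")
        if self.n_groups < 1 or self.n_lines < 2:
            raise ConfigError("need n_groups >= 1 and n_lines >= 2")
        if not 0.0 < self.fst < 1.0:
            raise ConfigError(f"fst must be in (0,1), got {self.fst}")
        if not 0.0 < self.h2 < 1.0:
            raise ConfigError(f"h2 must be in (0,1), got {self.h2}")
        if self.n_qtl > self.n_snps:
            raise ConfigError("n_qtl > n_snps")
        if self.n_qtl < 1:
            raise ConfigError("need n_qtl >= 1")
        if self.dominance_ratio < 0:
            raise ConfigError("dominance_ratio must be >= 0")
        if self.effect_distribution.get("name", "gamma") != "gamma":
            raise ConfigError("only the gamma effect distribution is implemented")
        if self.group_sizes is not None:
            if len(self.group_sizes) != self.n_groups or sum(self.group_sizes) != self.n_lines:
                raise ConfigError("group_sizes must have n_groups entries summing to n_lines")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TrueGeneticValues:
    """Ground truth of a simulated trait on a hybrid set."""

    genetic_values: pd.Series  # per hybrid ("AxB")
    phenotypes: pd.Series
    true_gca: pd.Series  # per line, complete-diallel definition
    qtl_indices: np.ndarray
    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    residual_variance: float


def _group_sizes(config: SimConfig) -> list[int]:
    if config.group_sizes is not None:
        return list(config.group_sizes)
    base = config.n_lines // config.n_groups
    sizes = [base] * config.n_groups
    for i in range(config.n_lines - base * config.n_groups):
        sizes[i] += 1
    return sizes


def sim_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, pd.Series]:
    """Draw a structured panel of fully homozygous inbred lines ({0,2} dosages).

    Balding-Nichols: ancestral frequency p ~ U(0.05, 0.95) per SNP; group
    frequency ~ Beta(p(1-fst)/fst, (1-p)(1-fst)/fst); each inbred line carries
    two copies of a single allele drawn at its group frequency. Markers are
    assigned evenly to chromosomes with increasing bp positions.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _group_sizes(config)
    p_anc = rng.uniform(0.05, 0.95, size=config.n_snps)
    c = (1.0 - config.fst) / config.fst
    X = np.empty((config.n_lines, config.n_snps))
    group = np.empty(config.n_lines, dtype=object)
    row = 0
    for gi, size in enumerate(sizes):
        q = rng.beta(p_anc * c, (1.0 - p_anc) * c)
        X[row : row + size] = 2.0 * (
            rng.random((size, config.n_snps)) < q
        )
        group[row : row + size] = f"HG{gi + 1}"
        row += size
    lines = [f"L{i + 1:03d}" for i in range(config.n_lines)]
    per_chrom = np.array_split(np.arange(config.n_snps), config.n_chromosomes)
    chrom = np.empty(config.n_snps, dtype=object)
    pos = np.empty(config.n_snps, dtype=np.int64)
    for ci, idx in enumerate(per_chrom):
        chrom[idx] = str(ci + 1)
        if len(idx):
            step = max(int(2e8 / max(len(idx), 1)), 1)
            pos[idx] = (np.arange(len(idx)) + 1) * step
    markers = [f"snp_{chrom[j]}_{pos[j]}" for j in range(config.n_snps)]
    g = GenotypeMatrix(X, lines, markers, chrom, pos)
    return g, pd.Series(group, index=lines, name="group")


def _qtl_indices(n_snps: int, n_qtl: int) -> np.ndarray:
    """Evenly spaced marker indices genome-wide, first at floor(spacing/2)."""
    spacing = n_snps / n_qtl
    idx = np.floor(spacing / 2.0 + spacing * np.arange(n_qtl)).astype(int)
    return np.minimum(idx, n_snps - 1)


def sim_trait(
    genotypes: GenotypeMatrix,
    hybrids,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> TrueGeneticValues:
    """Simulate a trait on a hybrid set from parental genotypes.

    QTL sit at evenly spaced marker indices; |additive effects| are gamma
    draws with Rademacher signs, dominance effects d = dominance_ratio * |a|.
    A hybrid's genetic value is sum(a * x_add) + sum(d * x_dom) with
    x_add the mean parental dosage and x_dom the heterozygosity indicator.
    Residual variance is calibrated on the realized hybrid set so that
    Var(g) / Var(g + e) equals the target h2; phenotype = g + e.

    True per-line GCA is computed over the complete diallel of the parent
    panel (mean genetic value of all hybrids carrying the line, centered on
    the all-hybrid mean), which makes it sum to exactly zero.
    """
    if hasattr(hybrids, "pairs"):
        pairs = hybrids.pairs
    else:
        pairs = [tuple(sorted((str(a), str(b)))) for a, b in hybrids]
    if not pairs:
        raise PlanError("empty hybrid set")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    qtl = _qtl_indices(genotypes.n_markers, config.n_qtl)
    dist = config.effect_distribution
    a_mag = rng.gamma(dist.get("shape", 1.0), dist.get("scale", 1.0), size=config.n_qtl)
    signs = rng.choice([-1.0, 1.0], size=config.n_qtl)
    a = a_mag * signs
    d = config.dominance_ratio * a_mag

    Xq = genotypes.X[:, qtl]

    def genetic_values(pair_list) -> np.ndarray:
        lut = {s: i for i, s in enumerate(genotypes.lines)}
        i1 = np.array([lut[p] for p, _ in pair_list])
        i2 = np.array([lut[q] for _, q in pair_list])
        x_add = (Xq[i1] + Xq[i2]) / 2.0
        x_dom = (Xq[i1] != Xq[i2]).astype(float)
        return x_add @ a + x_dom @ d

    g_vals = genetic_values(pairs)
    var_g = float(np.var(g_vals))
    var_e = var_g * (1.0 - config.h2) / config.h2 if var_g > 0 else 1.0
    e = rng.normal(0.0, np.sqrt(var_e), size=len(pairs))
    names = [f"{p}x{q}" for p, q in pairs]
    gv = pd.Series(g_vals, index=names, name="genetic_value")
    phen = pd.Series(g_vals + e, index=names, name="phenotype")

    all_pairs = enumerate_potential_hybrids(genotypes.lines)
    g_all = genetic_values(all_pairs)
    grand = g_all.mean()
    sums = pd.Series(0.0, index=genotypes.lines)
    counts = pd.Series(0, index=genotypes.lines)
    for (p, q), val in zip(all_pairs, g_all):
        sums[p] += val
        sums[q] += val
        counts[p] += 1
        counts[q] += 1
    true_gca = sums / counts - grand
    true_gca.name = "true_gca"
    return TrueGeneticValues(gv, phen, true_gca, qtl, a, d, var_e)


def sim_design_study(
    config: SimConfig,
    n_lines_grid,
    n_hybrids_grid,
    n_reps: int = 20,
    seed: int | None = None,
    on_infeasible: str = "raise",
    reml_max_iter: int = 40,
) -> pd.DataFrame:
    """Accuracy of genomic GCA estimation across design sizes.

    ``config.n_lines`` is the full candidate panel whose GCAs are wanted.
    For every (n_lines, n_hybrids) cell and replicate: draw a structured
    panel, involve a random subset of ``n_lines`` parents in a sparse partial
    diallel of ``n_hybrids`` crosses (every involved line appears at least
    once), simulate the trait on those hybrids at the configured architecture,
    fit the additive+dominance mixed model, predict the complete diallel of
    the WHOLE panel, derive per-line GCA and report its correlation with the
    true GCA over all candidate lines. Returns a tidy frame with mean +- sd
    accuracy per cell.

    Cells with n_hybrids exceeding the potential diallel of the involved
    lines, or below ceil(n/2), raise PlanError; with ``on_infeasible="skip"``
    they are recorded as NaN.
    """
    from .combining import estimate_gca, predict_all_hybrids
    from .mixed_models import reml_fit
    from .genotypes import infer_hybrid_genotypes

    n_lines_grid = list(n_lines_grid)
    n_hybrids_grid = list(n_hybrids_grid)
    if not n_lines_grid or not n_hybrids_grid:
        raise ConfigError("empty design grid")
    if max(n_lines_grid) > config.n_lines:
        raise ConfigError("grid n_lines exceeds the candidate panel size")
    if seed is None:
        seed = config.seed
    rows = []
    for n_lines in n_lines_grid:
        for n_hyb in n_hybrids_grid:
            feasible = (n_hyb <= n_lines * (n_lines - 1) // 2) and (
                n_hyb >= (n_lines + 1) // 2
            )
            if not feasible:
                if on_infeasible == "skip":
                    rows.append(
                        {"n_lines": n_lines, "n_hybrids": n_hyb, "mean_accuracy": np.nan,
                         "sd_accuracy": np.nan, "n_reps": 0}
                    )
                    continue
                raise PlanError(
                    f"infeasible cell: {n_hyb} hybrids from {n_lines} lines"
                )
            accs = []
            for rep in range(n_reps):
                rep_seed = (seed + 7919 * rep + 104729 * n_lines + 13 * n_hyb) % (2**31)
                rng = np.random.default_rng(rep_seed)
                cfg = SimConfig(
                    n_lines=config.n_lines,
                    n_groups=config.n_groups,
                    n_snps=config.n_snps,
                    n_chromosomes=config.n_chromosomes,
                    fst=config.fst,
                    n_qtl=config.n_qtl,
                    h2=config.h2,
                    dominance_ratio=config.dominance_ratio,
                    effect_distribution=config.effect_distribution,
                    seed=rep_seed,
                )
                g, groups = sim_genotypes(cfg)
                involved = sorted(rng.choice(g.lines, size=n_lines, replace=False))
                plan = generate_spdc_plan(
                    groups.loc[involved], n_crosses=n_hyb,
                    between_group_fraction=0.8, seed=rep_seed + 1,
                )
                truth = sim_trait(g, plan, cfg)
                coding = infer_hybrid_genotypes(g, plan)
                fit = reml_fit(
                    truth.phenotypes.to_numpy(), coding.Za, coding.Zd,
                    max_iter=reml_max_iter,
                )
                preds = predict_all_hybrids(fit, g)
                gca = estimate_gca(preds, groups=groups)
                est = gca.set_index("line")["gca"].reindex(truth.true_gca.index)
                accs.append(float(np.corrcoef(est, truth.true_gca)[0, 1]))
            rows.append(
                {
                    "n_lines": n_lines,
                    "n_hybrids": n_hyb,
                    "mean_accuracy": float(np.mean(accs)),
                    "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                    "n_reps": len(accs),
                }
            )
    return pd.DataFrame(rows)
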