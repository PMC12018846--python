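"""Genotype containers, I/O, quality control, hybrid coding and kinship matrices.

Dosages count copies of the *panel minor allele* (0/1/2); inbred parents are
expected to be (nearly) homozygous, so hybrid genotypes can be inferred from
the parental pair: the additive code of a hybrid is the mean parental dosage
and the dominance code is the heterozygosity indicator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateIDError, FormatError, ModelError, QCError

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "HybridCoding",
    "KinshipPair",
    "QcReport",
    "read_genotypes",
    "write_dosage_tsv",
    "write_vcf",
    "qc_filter",
    "infer_hybrid_genotypes",
    "additive_kinship",
    "dominance_kinship",
    "build_kinships",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix plus a marker map.

    Parameters
    ----------
    X : float array (n_lines, n_markers), np.nan for missing calls
    lines : line identifiers (unique)
    markers : marker identifiers (unique)
    chrom : per-marker chromosome label
    pos : per-marker physical position (bp, 1-based)
    """

    X: np.ndarray
    lines: list[str]
    markers: list[str]
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.lines = [str(s) for s in self.lines]
        self.markers = [str(s) for s in self.markers]
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, m = self.X.shape
        if len(self.lines) != n or len(self.markers) != m:
            raise ModelError("label lengths do not match dosage matrix shape")
        if len(set(self.lines)) != n:
            raise DuplicateIDError("duplicate line identifiers")
        if len(set(self.markers)) != m:
            raise DuplicateIDError("duplicate marker identifiers")
        if len(self.chrom) != m or len(self.pos) != m:
            raise ModelError("marker map length mismatch")

    # -- basic properties ---------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.X.shape[0]

    @property
    def n_markers(self) -> int:
        return self.X.shape[1]

    def line_index(self, names: Iterable[str]) -> np.ndarray:
        lut = {s: i for i, s in enumerate(self.lines)}
        try:
            return np.array([lut[str(s)] for s in names], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise ModelError(f"unknown line identifier {e.args[0]!r}") from None

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.markers, "chrom": self.chrom, "pos": self.pos}
        )

    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.X), axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker, missing calls ignored."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            p = np.nanmean(self.X, axis=0) / 2.0
        p = np.where(np.isnan(p), 0.0, p)
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.X[:, keep],
            self.lines,
            [self.markers[int(i)] for i in keep],
            self.chrom[keep],
            self.pos[keep],
        )

    def subset_lines(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = self.line_index(names)
        return GenotypeMatrix(
            self.X[idx], [self.lines[i] for i in idx], self.markers, self.chrom, self.pos
        )


@dataclass
class HybridCoding:
    """Per-hybrid additive (mean parental dosage) and dominance (heterozygosity)
    design matrices inferred from homozygous parents."""

    hybrids: list[str]
    pairs: list[tuple[str, str]]
    Za: np.ndarray
    Zd: np.ndarray
    markers: list[str]


@dataclass
class KinshipPair:
    """Additive and dominance genomic relationship matrices with the centering
    statistics used to build them (reused for any test-set rows)."""

    K_a: np.ndarray
    K_d: np.ndarray | None
    freqs: np.ndarray
    dom_means: np.ndarray | None = None


@dataclass
class QcReport:
    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_kept: int
    removed_missing: list[str] = field(default_factory=list)
    removed_maf: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_HAPMAP_FIXED = 11  # rs# alleles chrom pos strand assembly# center protLSID assayLSID panelLSID QCcode
_HAPMAP_MISSING = {"NN", "N", "--", "//", "00"}


def read_genotypes(path: str | Path, format: str, map_path: str | Path | None = None) -> GenotypeMatrix:
    """Read a genotype panel and orient dosages to the panel minor allele.

    ``format`` is one of ``vcf`` (GT fields of biallelic SNPs), ``hapmap``
    (tab-separated, 11 fixed columns then one call column per line) or
    ``dosage_tsv`` (lines x markers, header row of marker ids; optional
    companion map TSV with columns marker/chrom/pos). Allele-based formats
    are re-oriented so dosages count the panel minor allele; a dosage TSV is
    taken as already carrying the intended coding and round-trips unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "vcf":
        return _orient_minor(_read_vcf(path))
    if format == "hapmap":
        return _orient_minor(_read_hapmap(path))
    if format == "dosage_tsv":
        return _read_dosage_tsv(path, map_path)
    raise FormatError(f"unknown genotype format {format!r}")


def _orient_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = np.nanmean(g.X, axis=0) / 2.0
    flip = p > 0.5
    if flip.any():
        g.X[:, flip] = 2.0 - g.X[:, flip]
    return g


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise DuplicateIDError("duplicate sample names in VCF")
    rows, markers, chrom, pos = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3 = missing
        gt[gt == 3] = np.nan
        rows.append(gt)
        markers.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
    if n_multi:
        log.info("dropped %d multi-allelic sites from %s", n_multi, path)
    if not rows:
        raise FormatError(f"no biallelic SNPs in {path}")
    X = np.vstack(rows).T
    return GenotypeMatrix(X, samples, markers, np.array(chrom), np.array(pos))


def _read_hapmap(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] <= _HAPMAP_FIXED:
        raise FormatError("HapMap file has no sample columns")
    samples = list(df.columns[_HAPMAP_FIXED:])
    if len(set(samples)) != len(samples):
        raise DuplicateIDError("duplicate sample names in HapMap file")
    markers = df.iloc[:, 0].tolist()
    chrom = df.iloc[:, 2].to_numpy()
    pos = df.iloc[:, 3].astype(np.int64).to_numpy()
    calls = df.iloc[:, _HAPMAP_FIXED:].to_numpy()
    n_multi = 0
    rows = []
    keep = []
    for j in range(df.shape[0]):
        alleles = str(df.iloc[j, 1]).split("/")
        if len(alleles) != 2:
            n_multi += 1
            continue
        a, b = alleles
        row = np.full(len(samples), np.nan)
        for i, call in enumerate(calls[j]):
            call = str(call).strip()
            if call in _HAPMAP_MISSING or call == "nan":
                continue
            if len(call) != 2 or any(c not in (a, b) for c in call):
                raise FormatError(
                    f"call {call!r} inconsistent with alleles {a}/{b} at {markers[j]}"
                )
            row[i] = sum(c == b for c in call)  # count of second allele
        rows.append(row)
        keep.append(j)
    if n_multi:
        log.info("dropped %d non-biallelic HapMap rows from %s", n_multi, path)
    if not rows:
        raise FormatError(f"no biallelic SNPs in {path}")
    X = np.vstack(rows).T
    keep = np.array(keep)
    return GenotypeMatrix(X, samples, [markers[j] for j in keep], chrom[keep], pos[keep])


def _read_dosage_tsv(path: Path, map_path: str | Path | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    markers = [str(c) for c in df.columns]
    lines = [str(i) for i in df.index]
    X = df.to_numpy(dtype=float)
    if map_path is not None:
        mp = pd.read_csv(map_path, sep="\t", dtype={"marker": str})
        mp = mp.set_index("marker").reindex(markers)
        if mp["pos"].isna().any():
            raise FormatError("map file does not cover all markers")
        chrom, pos = mp["chrom"].to_numpy(), mp["pos"].astype(np.int64).to_numpy()
    else:
        chrom = np.array(["1"] * len(markers))
        pos = np.arange(1, len(markers) + 1, dtype=np.int64)
    return GenotypeMatrix(X, lines, markers, chrom, pos)


def write_dosage_tsv(g: GenotypeMatrix, path: str | Path, map_path: str | Path | None = None) -> None:
    df = pd.DataFrame(g.X, index=g.lines, columns=g.markers)
    df.index.name = "line"
    df.to_csv(path, sep="\t", float_format="%g")
    if map_path is not None:
        g.marker_frame().to_csv(map_path, sep="\t", index=False)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF writer: GT-only, REF=A (major), ALT=B (minor)."""
    code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.lines) + "\n")
        for j in range(g.n_markers):
            calls = [
                "./." if np.isnan(v) else code[int(round(v))] for v in g.X[:, j]
            ]
            fh.write(
                f"{g.chrom[j]}\t{g.pos[j]}\t{g.markers[j]}\tA\tB\t.\t.\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_filter(
    g: GenotypeMatrix, max_missing: float = 0.20, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove markers with missing rate strictly above ``max_missing`` or minor
    allele frequency strictly below ``min_maf`` (computed before imputation),
    then mean-impute any remaining missing calls per marker."""
    miss = g.missing_rate()
    maf = g.maf()
    bad_miss = miss > max_missing
    bad_maf = (~bad_miss) & (maf < min_maf)
    keep = ~(bad_miss | bad_maf)
    report = QcReport(
        n_input=g.n_markers,
        n_removed_missing=int(bad_miss.sum()),
        n_removed_maf=int(bad_maf.sum()),
        n_kept=int(keep.sum()),
        removed_missing=[m for m, b in zip(g.markers, bad_miss) if b],
        removed_maf=[m for m, b in zip(g.markers, bad_maf) if b],
    )
    if report.n_kept == 0:
        raise QCError(
            f"all {g.n_markers} markers removed by QC "
            f"(missing>{max_missing}: {report.n_removed_missing}, "
            f"MAF<{min_maf}: {report.n_removed_maf})"
        )
    out = g.subset_markers(np.flatnonzero(keep))
    # mean imputation per marker
    if np.isnan(out.X).any():
        col_mean = np.nanmean(out.X, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(out.X))
        out.X[nan_r, nan_c] = col_mean[nan_c]
    return out, report


# ---------------------------------------------------------------------------
# hybrid genotype inference
# ---------------------------------------------------------------------------

def infer_hybrid_genotypes(
    g: GenotypeMatrix, pairs, het_tolerance: float = 0.05
) -> HybridCoding:
    """Infer additive/dominance codings of hybrids from their inbred parents.

    ``pairs`` is a CrossPlan or an iterable of (parentA, parentB) tuples.
    Parents must be essentially homozygous: a line whose heterozygosity exceeds
    ``het_tolerance`` raises; residual heterozygous calls below the tolerance
    are resolved to the major-allele homozygote (dosage 0) with a warning.
    """
    if hasattr(pairs, "pairs"):  # CrossPlan
        pairs = pairs.pairs
    pairs = [(str(a), str(b)) for a, b in pairs]
    if not pairs:
        raise ModelError("empty hybrid set")
    parents = sorted({p for pair in pairs for p in pair})
    idx = g.line_index(parents)
    X = g.X[idx]
    if np.isnan(X).any():
        raise QCError("parental genotypes contain missing calls; run qc_filter first")
    het = np.mean(X == 1, axis=1)
    too_het = het > het_tolerance
    if too_het.any():
        bad = [parents[i] for i in np.flatnonzero(too_het)]
        raise QCError(
            f"parent heterozygosity above tolerance {het_tolerance}: {', '.join(bad)}"
        )
    if (X == 1).any():
        n_line = int((X == 1).any(axis=1).sum())
        warnings.warn(
            f"resolved residual heterozygous calls to the major homozygote in {n_line} line(s)",
            stacklevel=2,
        )
        X = np.where(X == 1, 0.0, X)
    lut = {p: i for i, p in enumerate(parents)}
    i1 = np.array([lut[a] for a, _ in pairs])
    i2 = np.array([lut[b] for _, b in pairs])
    Za = (X[i1] + X[i2]) / 2.0
    Zd = (X[i1] != X[i2]).astype(float)
    hybrids = [f"{a}x{b}" for a, b in pairs]
    return HybridCoding(hybrids, pairs, Za, Zd, list(g.markers))


# ---------------------------------------------------------------------------
# kinships
# ---------------------------------------------------------------------------

def additive_kinship(Za: np.ndarray, freqs: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """VanRaden-style additive kinship K = W W'/m with W = Za - 2p.

    ``freqs`` are the (training-panel) allele frequencies used for centering;
    computed from ``Za`` when omitted. Returns (K, freqs).
    """
    Za = np.asarray(Za, dtype=float)
    if np.isnan(Za).any():
        raise ModelError("missing entries in additive coding")
    if freqs is None:
        freqs = Za.mean(axis=0) / 2.0
    if np.allclose(Za.var(axis=0), 0.0):
        raise ModelError("all markers monomorphic: zero-variance additive coding")
    W = Za - 2.0 * freqs
    K = W @ W.T / Za.shape[1]
    return (K + K.T) / 2.0, freqs


def dominance_kinship(Zd: np.ndarray, means: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Dominance kinship K = W W'/m with W the column mean-centered heterozygosity
    indicator. Returns (K, means)."""
    Zd = np.asarray(Zd, dtype=float)
    if np.isnan(Zd).any():
        raise ModelError("missing entries in dominance coding")
    if means is None:
        means = Zd.mean(axis=0)
    W = Zd - means
    K = W @ W.T / Zd.shape[1]
    return (K + K.T) / 2.0, means


def build_kinships(coding: HybridCoding) -> KinshipPair:
    K_a, freqs = additive_kinship(coding.Za)
    K_d, means = dominance_kinship(coding.Zd)
    return KinshipPair(K_a, K_d, freqs, means)
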