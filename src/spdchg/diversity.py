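"""Population-diversity utilities: simple-matching distance, neighbor-joining,
PCA of the dosage matrix, and LD decay with physical distance."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .errors import ModelError
from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = ["simple_matching_distance", "nj_tree", "pca_scores", "ld_decay", "LdCurve"]


def simple_matching_distance(g: GenotypeMatrix | np.ndarray, labels=None) -> pd.DataFrame:
    """Pairwise proportion of markers with unequal dosage calls.

    Accepts a GenotypeMatrix (post-QC, no missing data) or a raw dosage array
    with ``labels``. Returns a symmetric labelled DataFrame with zero diagonal.
    """
    if isinstance(g, GenotypeMatrix):
        X, labels = g.X, g.lines
    else:
        X = np.asarray(g, dtype=float)
        labels = list(labels) if labels is not None else [str(i) for i in range(X.shape[0])]
    if X.shape[0] < 2:
        raise ModelError("need at least 2 lines for a distance matrix")
    if np.isnan(X).any():
        raise ModelError("missing data; run qc_filter first")
    n, m = X.shape
    # equality counts via one-hot indicators per dosage class
    eq = np.zeros((n, n))
    for v in np.unique(X):
        I = (X == v).astype(float)
        eq += I @ I.T
    D = 1.0 - eq / m
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=labels, columns=labels)


def nj_tree(d: pd.DataFrame | np.ndarray, labels=None) -> str:
    """Saitou-Nei neighbor joining; returns a newick string.

    Negative branch lengths are clamped to zero (logged). The input matrix
    must be symmetric with a zero diagonal.
    """
    if isinstance(d, pd.DataFrame):
        labels = [str(x) for x in d.index]
        D = d.to_numpy(dtype=float)
    else:
        D = np.asarray(d, dtype=float)
        labels = [str(x) for x in labels] if labels is not None else [
            f"t{i}" for i in range(D.shape[0])
        ]
    n = D.shape[0]
    if n < 3:
        raise ModelError("need at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ModelError("distance matrix is not symmetric")
    D = D.copy()
    nodes = list(labels)  # newick fragment per active node
    n_clamped = 0
    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (k - 2))
        vj = D[i, j] - vi
        if vi < 0 or vj < 0:
            n_clamped += 1
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        new = f"({nodes[i]}:{vi:.10g},{nodes[j]}:{vj:.10g})"
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        D = np.delete(np.delete(D, (i, j), axis=0), (i, j), axis=1)
        dnew = np.delete(dnew, (i, j))
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = D[:-1, -1] = dnew
        nodes = [x for t, x in enumerate(nodes) if t not in (i, j)] + [new]
    # closing 3-star: v_a = (d_ab + d_ac - d_bc)/2 and cyclic
    va = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    vb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    vc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    if min(va, vb, vc) < 0:
        n_clamped += 1
    va, vb, vc = (max(v, 0.0) for v in (va, vb, vc))
    if n_clamped:
        log.info("clamped negative branch lengths at %d join(s)", n_clamped)
    return f"({nodes[0]}:{va:.10g},{nodes[1]}:{vb:.10g},{nodes[2]}:{vc:.10g});"


def pca_scores(
    g: GenotypeMatrix | np.ndarray, n_components: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the column-centered dosage matrix.

    Returns (score table with one row per line, variance-explained fractions
    of the requested components). Fractions over the full decomposition sum
    to 1.
    """
    if isinstance(g, GenotypeMatrix):
        X, labels = g.X, g.lines
    else:
        X = np.asarray(g, dtype=float)
        labels = [str(i) for i in range(X.shape[0])]
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s.max() * max(Xc.shape) * np.finfo(float).eps)) if s.size else 0
    if n_components > rank:
        raise ModelError(f"n_components={n_components} exceeds rank {rank}")
    scores = U[:, :n_components] * s[:n_components]
    varexp = (s**2 / np.sum(s**2))[:n_components]
    table = pd.DataFrame(
        scores, index=labels, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return table, varexp


@dataclass
class LdCurve:
    """Binned mean r^2 against physical distance, with the distance at which
    the monotone-smoothed curve first drops below a threshold."""

    bins: pd.DataFrame  # bin_start, bin_end, mean_r2, smoothed_r2, n_pairs
    r2_threshold: float
    decay_distance: float  # bp; nan if the curve never drops below threshold

    def write_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)


def ld_decay(
    g: GenotypeMatrix,
    max_dist_bp: int = 1_000_000,
    bin_bp: int = 10_000,
    r2_threshold: float = 0.2,
) -> LdCurve:
    """LD decay: squared Pearson correlation of dosage vectors for all
    intra-chromosome marker pairs within ``max_dist_bp``, binned by distance.

    Bin means are smoothed by monotone non-increasing (isotonic) regression
    before thresholding; the decay distance is the first bin midpoint at which
    the smoothed curve is below ``r2_threshold``.
    """
    X = g.X
    if np.isnan(X).any():
        raise ModelError("missing data; run qc_filter first")
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for ch in np.unique(g.chrom):
        idx = np.flatnonzero(g.chrom == ch)
        idx = idx[np.argsort(g.pos[idx], kind="stable")]
        pos = g.pos[idx]
        Xc = X[:, idx] - X[:, idx].mean(axis=0)
        sd = Xc.std(axis=0)
        for a in range(len(idx) - 1):
            upper = np.searchsorted(pos, pos[a] + max_dist_bp, side="right")
            if upper <= a + 1 or sd[a] == 0:
                continue
            b = slice(a + 1, upper)
            ok = sd[b] > 0
            if not ok.any():
                continue
            r = (Xc[:, a] @ Xc[:, b][:, ok]) / (X.shape[0] * sd[a] * sd[b][ok])
            r2 = r**2
            dist = (pos[b][ok] - pos[a]).astype(int)
            which = np.minimum(dist // bin_bp, n_bins - 1)
            np.add.at(sums, which, r2)
            np.add.at(counts, which, 1)
    if counts.sum() == 0:
        raise ModelError(f"no intra-chromosome pairs within {max_dist_bp} bp")
    have = counts > 0
    mean_r2 = np.full(n_bins, np.nan)
    mean_r2[have] = sums[have] / counts[have]
    mids = (np.arange(n_bins) + 0.5) * bin_bp
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    smoothed = np.full(n_bins, np.nan)
    smoothed[have] = iso.fit_transform(mids[have], mean_r2[have], sample_weight=counts[have])
    below = have & (smoothed < r2_threshold)
    decay = float(mids[np.argmax(below)]) if below.any() else float("nan")
    bins = pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_bp,
            "bin_end": (np.arange(n_bins) + 1) * bin_bp,
            "mean_r2": mean_r2,
            "smoothed_r2": smoothed,
            "n_pairs": counts,
        }
    )
    return LdCurve(bins, r2_threshold, decay)
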