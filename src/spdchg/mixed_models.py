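"""Estimation machinery for genomic prediction.

* EM-REML for variance components of kernel mixed models
  y = Xb + u_a + u_d + e with u_a ~ N(0, K_a * phi_a), u_d ~ N(0, K_d * phi_d);
  the kernels K = W W'/m make this equivalent to the marker-effect model with
  per-marker variance phi/m (ridge / SNP-BLUP).
* GBLUP prediction of unphenotyped individuals (kernel or marker-effect route).
* BayesB: Gibbs sampler with a point mass at zero and a scaled-inverse-
  chi-square slab for marker effects.
* LASSO: cyclic coordinate descent with soft thresholding; lambda by inner CV.
* Multi-environment entry BLUP (environment fixed; genotype and GxE random).
* A fold/repeat cross-validation engine reporting Pearson accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.linalg import cho_factor, cho_solve
from scipy import stats

from .errors import ConfigError, ModelError
from .genotypes import additive_kinship, dominance_kinship

__all__ = [
    "VarianceComponents",
    "McmConfig",
    "CvResult",
    "em_reml",
    "reml_fit",
    "GblupFit",
    "gblup_predict",
    "bayesb_fit",
    "BayesBFit",
    "lasso_fit",
    "LassoFit",
    "cross_validate",
    "env_blup",
    "EnvBlupResult",
    "fit_hybrid_model",
    "fit_line_model",
]

_FLOOR_FACTOR = 1e-10


# ---------------------------------------------------------------------------
# EM-REML
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    phi_a: float
    phi_d: float
    sigma2: float
    loglik: float
    converged: bool
    n_iter: int


def _rank_and_factors(K: np.ndarray) -> int:
    ev = np.linalg.eigvalsh(K)
    tol = max(ev.max(), 0.0) * K.shape[0] * np.finfo(float).eps
    return int(np.sum(ev > max(tol, 1e-12)))


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    kernels: list[np.ndarray],
    max_iter: int = 500,
    tol: float = 1e-6,
    fixed: dict[int, float] | None = None,
):
    """EM-REML for V = sum_k phi_k K_k + sigma2 I.

    Uses the classical EM updates (monotone in the restricted likelihood,
    asserted each step); a single-kernel model is solved in the eigenbasis of
    the kernel so each iteration is O(n p^2). ``fixed`` pins kernel variances
    (index -> value), e.g. ``{1: 0.0}`` drops the second component.

    Returns ``(phi, sigma2, loglik, n_iter, converged, ll_path)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if not np.all(np.isfinite(y)):
        raise ModelError("non-finite phenotypes")
    X = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        raise ModelError("X rows do not match y")
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ModelError("singular fixed-effect design")
    vy_raw = float(np.var(y))
    if vy_raw < 1e-14 * (1.0 + float(np.mean(y)) ** 2):
        # degenerate constant response: all components vanish
        zeros = np.zeros(len(kernels))
        return zeros, 0.0, 0.0, 0, True, [0.0]
    vy = max(vy_raw, 1e-12)
    floor = _FLOOR_FACTOR * vy
    fixed = dict(fixed or {})
    K = [np.asarray(Kk, dtype=float) for Kk in kernels]
    nk = len(K)
    ranks = [_rank_and_factors(Kk) for Kk in K]

    free = [k for k in range(nk) if k not in fixed]
    phi = np.array(
        [fixed.get(k, vy / (len(free) + 1)) for k in range(nk)], dtype=float
    )
    sigma2 = vy / (len(free) + 1) if free else vy / 2.0

    single = nk == 1 and len(free) == 1
    if single:
        k0 = free[0]
        return _em_reml_single(y, X, K[k0], ranks[k0], k0, nk, phi, sigma2,
                               max_iter, tol, floor)

    ll_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = sigma2 * np.eye(n)
        for k in range(nk):
            if phi[k] > 0:
                V += phi[k] * K[k]
        c, low = cho_factor(V, lower=True)
        Vinv = cho_solve((c, low), np.eye(n))
        VinvX = Vinv @ X
        A = X.T @ VinvX
        Ainv = np.linalg.inv(A)
        P = Vinv - VinvX @ Ainv @ VinvX.T
        Py = P @ y
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        sign, logdetA = np.linalg.slogdet(A)
        ll = -0.5 * (logdetV + logdetA + float(y @ Py))
        if ll_path and ll < ll_path[-1] - 1e-5 * (1.0 + abs(ll_path[-1])):
            raise AssertionError(
                f"EM-REML log-likelihood decreased at iteration {it}: "
                f"{ll_path[-1]:.8g} -> {ll:.8g}"
            )
        done = bool(ll_path) and abs(ll - ll_path[-1]) < tol
        ll_path.append(ll)
        if done:
            converged = True
            break
        for k in range(nk):
            if k in fixed:
                continue
            trPK = float(np.sum(P * K[k]))
            yPKPy = float(Py @ (K[k] @ Py))
            phi[k] = max(
                (phi[k] ** 2 * yPKPy + phi[k] * ranks[k] - phi[k] ** 2 * trPK)
                / ranks[k],
                floor,
            )
        trP = float(np.trace(P))
        sigma2 = max(
            (sigma2**2 * float(Py @ Py) + n * sigma2 - sigma2**2 * trP) / n, floor
        )
    return phi, sigma2, ll_path[-1], it, converged, ll_path


def _em_reml_single(y, X, K, rank, k0, nk, phi, sigma2, max_iter, tol, floor):
    """One-kernel EM-REML in the eigenbasis of K (each iteration O(n p^2))."""
    n, p = X.shape
    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    ll_path: list[float] = []
    converged = False
    ph = phi[k0]
    it = 0
    for it in range(1, max_iter + 1):
        d = ph * lam + sigma2
        dinv = 1.0 / d
        XtD = Xt * dinv[:, None]
        A = Xt.T @ XtD
        Ainv = np.linalg.inv(A)
        Pyt = dinv * yt - XtD @ (Ainv @ (XtD.T @ yt))
        ll = -0.5 * (
            float(np.sum(np.log(d)))
            + float(np.linalg.slogdet(A)[1])
            + float(yt @ Pyt)
        )
        if ll_path and ll < ll_path[-1] - 1e-5 * (1.0 + abs(ll_path[-1])):
            raise AssertionError("EM-REML log-likelihood decreased")
        done = bool(ll_path) and abs(ll - ll_path[-1]) < tol
        ll_path.append(ll)
        if done:
            converged = True
            break
        # traces of P against K and I without forming P
        B = XtD.T * lam[None, :] @ XtD  # X' D^-1 Lam D^-1 X
        trPK = float(np.sum(lam * dinv)) - float(np.trace(Ainv @ B))
        C = XtD.T @ XtD
        trP = float(np.sum(dinv)) - float(np.trace(Ainv @ C))
        yPKPy = float(Pyt @ (lam * Pyt))
        ph = max((ph**2 * yPKPy + ph * rank - ph**2 * trPK) / rank, floor)
        sigma2 = max(
            (sigma2**2 * float(Pyt @ Pyt) + n * sigma2 - sigma2**2 * trP) / n,
            floor,
        )
    out_phi = np.zeros(nk)
    out_phi[k0] = ph
    return out_phi, sigma2, ll_path[-1], it, converged, ll_path


def reml_se(
    y: np.ndarray, X: np.ndarray | None, kernels: list[np.ndarray],
    phi: np.ndarray, sigma2: float,
) -> np.ndarray:
    """Asymptotic standard errors of (phi_1..phi_K, sigma2) from the inverse
    REML Fisher information I_jk = 0.5 tr(P V_j P V_k)."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    X = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, dtype=float))
    V = sigma2 * np.eye(n)
    for ph, Kk in zip(phi, kernels):
        V += ph * Kk
    c, low = cho_factor(V, lower=True)
    Vinv = cho_solve((c, low), np.eye(n))
    VinvX = Vinv @ X
    P = Vinv - VinvX @ np.linalg.inv(X.T @ VinvX) @ VinvX.T
    parts = [P @ Kk for Kk in kernels] + [P]
    k = len(parts)
    info = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            info[i, j] = info[j, i] = 0.5 * float(np.sum(parts[i] * parts[j].T))
    return np.sqrt(np.diag(np.linalg.pinv(info)))


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------

@dataclass
class GblupFit:
    """Trained additive(+dominance) GBLUP model.

    Prediction of new individuals goes through the equivalent marker-effect
    representation gamma = (phi/m) W' V^-1 (y - Xb), so the all-hybrid space
    can be scored in constant memory per chunk.
    """

    varcomp: VarianceComponents
    beta: np.ndarray
    freqs: np.ndarray
    dom_means: np.ndarray | None
    gamma_a: np.ndarray
    gamma_d: np.ndarray | None
    Vinv_resid: np.ndarray  # V^-1 (y - X beta), for the kernel prediction route
    m: int
    ll_path: list[float] = field(default_factory=list, repr=False)

    @property
    def variance_components(self) -> VarianceComponents:
        return self.varcomp

    def predict(self, Za_new: np.ndarray, Zd_new: np.ndarray | None = None) -> np.ndarray:
        Wa = np.asarray(Za_new, dtype=float) - 2.0 * self.freqs
        out = float(self.beta[0]) + Wa @ self.gamma_a
        if self.gamma_d is not None and Zd_new is not None:
            Wd = np.asarray(Zd_new, dtype=float) - self.dom_means
            out = out + Wd @ self.gamma_d
        return out


def reml_fit(
    y: np.ndarray,
    Za: np.ndarray,
    Zd: np.ndarray | None = None,
    X: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    fix_dominance_zero: bool = False,
) -> GblupFit:
    """Fit the additive(+dominance) genomic mixed model by EM-REML.

    ``Za`` is the additive dosage coding of the training individuals, ``Zd``
    the heterozygosity coding (omit for an additive-only model). Kinships are
    built with training-panel centering, which is stored for test-set rows.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 10:
        raise ModelError(f"need at least 10 observations, got {n}")
    Za = np.asarray(Za, dtype=float)
    if Za.shape[0] != n:
        raise ModelError("Za rows do not match y")
    X = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, dtype=float))
    m = Za.shape[1]
    Ka, freqs = additive_kinship(Za)
    kernels = [Ka]
    dom_means = None
    fixed = {}
    if Zd is not None:
        Zd = np.asarray(Zd, dtype=float)
        if Zd.shape != Za.shape:
            raise ModelError("Zd shape does not match Za")
        Kd, dom_means = dominance_kinship(Zd)
        kernels.append(Kd)
        if fix_dominance_zero:
            fixed = {1: 0.0}
    phi, sigma2, ll, n_iter, converged, ll_path = em_reml(
        y, X, kernels, max_iter=max_iter, tol=tol, fixed=fixed or None
    )
    phi_a = float(phi[0])
    phi_d = float(phi[1]) if len(phi) > 1 else 0.0
    V = sigma2 * np.eye(n) + phi_a * kernels[0]
    if len(kernels) > 1 and phi_d > 0:
        V += phi_d * kernels[1]
    c, low = cho_factor(V, lower=True)
    VinvX = cho_solve((c, low), X)
    beta = np.linalg.solve(X.T @ VinvX, VinvX.T @ y)
    resid = y - X @ beta
    Vinv_r = cho_solve((c, low), resid)
    Wa = Za - 2.0 * freqs
    gamma_a = (phi_a / m) * (Wa.T @ Vinv_r)
    gamma_d = None
    if Zd is not None:
        Wd = Zd - dom_means
        gamma_d = (phi_d / m) * (Wd.T @ Vinv_r)
    vc = VarianceComponents(phi_a, phi_d, float(sigma2), float(ll), converged, n_iter)
    return GblupFit(vc, beta, freqs, dom_means, gamma_a, gamma_d, Vinv_r, m, ll_path)


def gblup_predict(
    fit: GblupFit,
    K_cross_a: np.ndarray,
    K_cross_d: np.ndarray | None = None,
    X_new: np.ndarray | None = None,
) -> np.ndarray:
    """Kernel-route prediction: X_new b + (phi_a K*_a + phi_d K*_d) V^-1 (y - Xb).

    ``K_cross_*`` are test x train kinship blocks built on the union panel with
    training-panel centering.
    """
    K_cross_a = np.atleast_2d(np.asarray(K_cross_a, dtype=float))
    if K_cross_a.shape[1] != fit.Vinv_resid.size:
        raise ModelError("cross-kinship columns do not match the training set")
    u = fit.varcomp.phi_a * K_cross_a @ fit.Vinv_resid
    if K_cross_d is not None and fit.varcomp.phi_d > 0:
        K_cross_d = np.atleast_2d(np.asarray(K_cross_d, dtype=float))
        if K_cross_d.shape != K_cross_a.shape:
            raise ModelError("mismatched cross-kinship blocks")
        u = u + fit.varcomp.phi_d * K_cross_d @ fit.Vinv_resid
    Xn = np.ones((K_cross_a.shape[0], 1)) if X_new is None else np.atleast_2d(X_new)
    return Xn @ fit.beta + u


# ---------------------------------------------------------------------------
# BayesB
# ---------------------------------------------------------------------------

@dataclass
class McmConfig:
    """Gibbs chain settings for BayesB. ``pi`` is the prior probability that a
    marker has a zero effect (inclusion probability 1 - pi)."""

    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 5
    pi: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ConfigError("chain shorter than burn-in")
        if not 0.0 < self.pi < 1.0:
            raise ConfigError("pi must be in (0,1)")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")


@njit(cache=False)
def _bayesb_gibbs(W, y, n_iter, burn_in, thin, pi, nu_b, S_b, nu_e, S_e, seed):
    np.random.seed(seed)
    n, m = W.shape
    cjj = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += W[i, j] * W[i, j]
        cjj[j] = s
    beta = np.zeros(m)
    sigma_j2 = np.full(m, S_b)
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    r = y - mu
    sigma_e2 = S_e
    beta_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    mu_sum = 0.0
    se_sum = 0.0
    n_samp = 0
    for it in range(n_iter):
        # intercept
        s = 0.0
        for i in range(n):
            s += r[i]
        mu_new = mu + s / n + np.random.normal() * np.sqrt(sigma_e2 / n)
        shift = mu - mu_new
        for i in range(n):
            r[i] += shift
        mu = mu_new
        # markers
        for j in range(m):
            c = cjj[j]
            if c <= 0.0:
                continue
            old = beta[j]
            rhs = old * c
            for i in range(n):
                rhs += W[i, j] * r[i]
            s2 = sigma_j2[j]
            v1 = c * s2 + sigma_e2
            logL1 = -0.5 * (np.log(v1) - np.log(sigma_e2)) + 0.5 * rhs * rhs * s2 / (
                sigma_e2 * v1
            )
            if logL1 > 40.0:
                p1 = 1.0
            else:
                p1 = 1.0 / (1.0 + pi / (1.0 - pi) * np.exp(-logL1))
            if np.random.random() < p1:
                var_b = sigma_e2 * s2 / v1
                bnew = rhs * s2 / v1 + np.random.normal() * np.sqrt(var_b)
                incl = 1.0
                sigma_j2[j] = (nu_b * S_b + bnew * bnew) / np.random.chisquare(
                    nu_b + 1.0
                )
            else:
                bnew = 0.0
                incl = 0.0
                sigma_j2[j] = nu_b * S_b / np.random.chisquare(nu_b)
            if bnew != old:
                diff = old - bnew
                for i in range(n):
                    r[i] += W[i, j] * diff
                beta[j] = bnew
            if it >= burn_in and (it - burn_in) % thin == 0:
                beta_sum[j] += bnew
                incl_sum[j] += incl
        # residual variance
        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]
        sigma_e2 = (nu_e * S_e + sse) / np.random.chisquare(nu_e + n)
        if it >= burn_in and (it - burn_in) % thin == 0:
            mu_sum += mu
            se_sum += sigma_e2
            n_samp += 1
    return (
        beta_sum / n_samp,
        incl_sum / n_samp,
        mu_sum / n_samp,
        se_sum / n_samp,
    )


@dataclass
class BayesBFit:
    """Posterior summaries of a BayesB fit on centered marker features."""

    effects: np.ndarray  # posterior-mean effects, original (centered) scale
    inclusion: np.ndarray  # posterior inclusion probability per marker
    mu: float
    sigma_e2: float
    feature_means: np.ndarray
    config: McmConfig

    def predict(self, W_new: np.ndarray) -> np.ndarray:
        W = np.asarray(W_new, dtype=float) - self.feature_means
        return self.mu + W @ self.effects


def bayesb_fit(
    y: np.ndarray,
    W: np.ndarray,
    config: McmConfig | None = None,
    r2_prior: float = 0.5,
) -> BayesBFit:
    """BayesB marker-effect regression via Gibbs sampling.

    Each marker effect is zero with prior probability ``config.pi``; otherwise
    it is normal with a marker-specific variance carrying a scaled-inverse-
    chi-square prior whose scale is matched so that the prior genetic variance
    is ``r2_prior`` x Var(y). Deterministic given the config seed.
    """
    config = config or McmConfig()
    y = np.asarray(y, dtype=float).ravel()
    W = np.asarray(W, dtype=float)
    if np.isnan(W).any() or np.isnan(y).any():
        raise ModelError("missing data in BayesB inputs")
    if W.shape[0] != y.size:
        raise ModelError("marker matrix rows do not match y")
    means = W.mean(axis=0)
    Wc = np.ascontiguousarray(W - means)
    vy = max(float(np.var(y)), 1e-12)
    msx = max(float(np.sum(Wc.var(axis=0))), 1e-12)
    nu_b, nu_e = 4.0, 4.0
    S_b = vy * r2_prior * (nu_b + 2.0) / (nu_b * (1.0 - config.pi) * msx)
    S_e = vy * (1.0 - r2_prior) * (nu_e + 2.0) / nu_e
    eff, incl, mu, se2 = _bayesb_gibbs(
        Wc,
        y,
        config.n_iter,
        config.burn_in,
        config.thin,
        config.pi,
        nu_b,
        S_b,
        nu_e,
        S_e,
        config.seed % (2**31),
    )
    return BayesBFit(eff, incl, float(mu), float(se2), means, config)


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------

@njit(cache=False)
def _cd_lasso_path(X, y, lambdas, tol, max_passes):
    n, m = X.shape
    betas = np.zeros((lambdas.size, m))
    beta = np.zeros(m)
    r = y.copy()
    for li in range(lambdas.size):
        lam = lambdas[li]
        for _ in range(max_passes):
            max_change = 0.0
            for j in range(m):
                bj = beta[j]
                rho = bj
                for i in range(n):
                    rho += X[i, j] * r[i] / n
                if rho > lam:
                    bnew = rho - lam
                elif rho < -lam:
                    bnew = rho + lam
                else:
                    bnew = 0.0
                if bnew != bj:
                    diff = bj - bnew
                    for i in range(n):
                        r[i] += X[i, j] * diff
                    beta[j] = bnew
                    if abs(diff) > max_change:
                        max_change = abs(diff)
            if max_change < tol:
                break
        betas[li] = beta
    return betas


@dataclass
class LassoFit:
    coef: np.ndarray  # original scale, zeros for dropped columns
    intercept: float
    lam: float
    lambdas: np.ndarray
    cv_mse: np.ndarray | None

    def predict(self, W_new: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(W_new, dtype=float) @ self.coef


def lasso_fit(
    y: np.ndarray,
    W: np.ndarray,
    lambdas: np.ndarray | None = None,
    n_lambdas: int = 50,
    inner_cv_folds: int = 5,
    seed: int = 0,
    tol: float = 1e-5,
    max_passes: int = 500,
) -> LassoFit:
    """L1-penalized marker regression.

    Columns are standardized internally; the lambda grid is log-spaced from the
    smallest all-zero value down by three decades; lambda is picked by inner
    k-fold CV (minimum held-out MSE) and the model refit on all data. A grid
    value of exactly 0 falls back to least squares. Coefficients are returned
    on the original scale.
    """
    y = np.asarray(y, dtype=float).ravel()
    W = np.asarray(W, dtype=float)
    n = y.size
    sd = W.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} zero-variance column(s)", stacklevel=2)
    Wk = W[:, keep]
    mean = Wk.mean(axis=0)
    sdk = sd[keep]
    Xs = np.ascontiguousarray((Wk - mean) / sdk)
    ybar = float(y.mean())
    yc = y - ybar
    if lambdas is None:
        lam_max = float(np.max(np.abs(Xs.T @ yc)) / n) if Xs.shape[1] else 1.0
        lambdas = np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1].copy()

    cv_mse = None
    if lambdas.size > 1:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        folds = np.array_split(perm, inner_cv_folds)
        sse = np.zeros(lambdas.size)
        for te in folds:
            tr = np.setdiff1d(perm, te)
            betas = _solve_path(Xs[tr], yc[tr], lambdas, tol, max_passes)
            pred = Xs[te] @ betas.T
            sse += np.sum((yc[te][:, None] - pred) ** 2, axis=0)
        cv_mse = sse / n
        lam = float(lambdas[int(np.argmin(cv_mse))])
    else:
        lam = float(lambdas[0])
    beta_std = _solve_path(Xs, yc, np.array([lam]), tol, max_passes)[0]
    coef = np.zeros(W.shape[1])
    coef[keep] = beta_std / sdk
    intercept = ybar - float((coef[keep] * mean).sum())
    return LassoFit(coef, intercept, lam, lambdas, cv_mse)


def _solve_path(Xs, yc, lambdas, tol, max_passes):
    pos = lambdas > 0
    betas = np.zeros((lambdas.size, Xs.shape[1]))
    if pos.any():
        betas[pos] = _cd_lasso_path(Xs, yc, lambdas[pos].copy(), tol, max_passes)
    if (~pos).any():
        ols, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
        betas[~pos] = ols
    return betas


# ---------------------------------------------------------------------------
# cross-validation engine
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Per-repeat prediction accuracy (Pearson r pooled over the held-out
    predictions of all folds within the repeat)."""

    per_repeat: list[float]
    mean: float
    sd: float
    folds: int
    repeats: int
    seed: int
    flagged_repeats: list[int] = field(default_factory=list)


def cross_validate(
    fit_predict,
    y: np.ndarray,
    folds: int = 5,
    repeats: int = 20,
    seed: int = 0,
) -> CvResult:
    """Repeated k-fold CV. ``fit_predict(train_idx, test_idx)`` must return
    predictions for the test rows. Folds are random (re-drawn each repeat);
    accuracy is the Pearson correlation between observed and pooled held-out
    predicted values within a repeat. Repeats with a constant observed vector
    are flagged and excluded from the mean."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < folds:
        raise ModelError(f"need at least {folds} observations for {folds}-fold CV")
    per_repeat: list[float] = []
    flagged: list[int] = []
    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        perm = rng.permutation(n)
        preds = np.empty(n)
        for te in np.array_split(perm, folds):
            tr = np.setdiff1d(perm, te)
            preds[te] = np.asarray(fit_predict(tr, te)).ravel()
        if np.std(y) == 0 or np.std(preds) == 0:
            flagged.append(rep)
            per_repeat.append(np.nan)
            continue
        per_repeat.append(float(np.corrcoef(y, preds)[0, 1]))
    valid = [r for r in per_repeat if np.isfinite(r)]
    mean = float(np.mean(valid)) if valid else np.nan
    sd = float(np.std(valid, ddof=1)) if len(valid) > 1 else 0.0
    return CvResult(per_repeat, mean, sd, folds, repeats, seed, flagged)


# ---------------------------------------------------------------------------
# model dispatch (uniform interface over GBLUP / BayesB / LASSO)
# ---------------------------------------------------------------------------

class _MarkerHybridFit:
    """Adapter exposing predict(Za, Zd) for marker-effect models trained on the
    stacked [additive | dominance] feature matrix."""

    def __init__(self, inner, with_dominance: bool):
        self.inner = inner
        self.with_dominance = with_dominance

    def predict(self, Za: np.ndarray, Zd: np.ndarray | None = None) -> np.ndarray:
        if self.with_dominance:
            if Zd is None:
                raise ModelError("dominance coding required by this fit")
            F = np.hstack([Za, Zd])
        else:
            F = np.asarray(Za, dtype=float)
        return self.inner.predict(F)


def fit_hybrid_model(
    model: str,
    y: np.ndarray,
    Za: np.ndarray,
    Zd: np.ndarray | None = None,
    **kw,
):
    """Train a hybrid-prediction model ('gblup' | 'bayesb' | 'lasso') on
    additive(+dominance) codings; all fits expose ``predict(Za, Zd)``."""
    model = model.lower()
    if model == "gblup":
        return reml_fit(y, Za, Zd, **kw)
    F = np.hstack([Za, Zd]) if Zd is not None else np.asarray(Za, dtype=float)
    if model == "bayesb":
        return _MarkerHybridFit(bayesb_fit(y, F, **kw), Zd is not None)
    if model == "lasso":
        return _MarkerHybridFit(lasso_fit(y, F, **kw), Zd is not None)
    raise ModelError(f"unknown model {model!r}")


def fit_line_model(model: str, y: np.ndarray, Z: np.ndarray, **kw):
    """Train a per-line model on additive coding only; exposes predict(Z)."""
    model = model.lower()
    if model == "gblup":
        fit = reml_fit(y, Z, None, **kw)

        class _L:
            def predict(self, Zn):
                return fit.predict(Zn, None)

        return _L()
    if model == "bayesb":
        return bayesb_fit(y, Z, **kw)
    if model == "lasso":
        return lasso_fit(y, Z, **kw)
    raise ModelError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# multi-environment BLUP
# ---------------------------------------------------------------------------

@dataclass
class EnvBlupResult:
    blups: pd.Series  # per-entry BLUP phenotype (grand fixed mean + u_g)
    varcomp: dict
    anova: pd.DataFrame  # fixed-effects F tests for genotype and environment


def env_blup(
    df: pd.DataFrame,
    entry_col: str = "genotype",
    env_col: str = "env",
    value_col: str = "value",
    max_iter: int = 200,
    tol: float = 1e-6,
) -> EnvBlupResult:
    """Entry BLUPs from multi-environment replicated data.

    Model: value = mean + environment (fixed) + genotype (random) +
    genotype x environment (random) + residual, fitted by EM-REML on
    incidence-matrix kernels. Returns per-entry BLUPs (grand fixed-effect mean
    plus the genotype effect) together with variance components and the
    fixed-effects ANOVA F tests for genotype and environment.
    """
    d = df[[entry_col, env_col, value_col]].dropna().copy()
    if d.empty:
        raise ModelError("no data")
    entries = sorted(d[entry_col].astype(str).unique())
    envs = sorted(d[env_col].astype(str).unique())
    y = d[value_col].to_numpy(dtype=float)
    n = y.size
    ent_idx = d[entry_col].astype(str).map({e: i for i, e in enumerate(entries)}).to_numpy()
    env_idx = d[env_col].astype(str).map({e: i for i, e in enumerate(envs)}).to_numpy()
    X = np.ones((n, len(envs)))
    for j in range(1, len(envs)):
        X[:, j] = (env_idx == j).astype(float)
    Zg = np.zeros((n, len(entries)))
    Zg[np.arange(n), ent_idx] = 1.0
    Kg = Zg @ Zg.T
    kernels = [Kg]
    use_ge = len(envs) >= 2
    if use_ge:
        cell = ent_idx * len(envs) + env_idx
        _, cell_code = np.unique(cell, return_inverse=True)
        Zge = np.zeros((n, cell_code.max() + 1))
        Zge[np.arange(n), cell_code] = 1.0
        kernels.append(Zge @ Zge.T)
    phi, sigma2, ll, n_iter, converged, _ = em_reml(
        y, X, kernels, max_iter=max_iter, tol=tol
    )
    V = sigma2 * np.eye(n)
    for ph, Kk in zip(phi, kernels):
        V += ph * Kk
    c, low = cho_factor(V, lower=True)
    VinvX = cho_solve((c, low), X)
    beta = np.linalg.solve(X.T @ VinvX, VinvX.T @ y)
    Vinv_r = cho_solve((c, low), y - X @ beta)
    u_g = phi[0] * (Zg.T @ Vinv_r)
    grand = float((X @ beta).mean())
    blups = pd.Series(grand + u_g, index=pd.Index(entries, name=entry_col), name="blup")

    # fixed-effects variance analysis (sequential F tests, genotype and env)
    anova = _fixed_anova(y, ent_idx, env_idx, len(entries), len(envs))
    vc = {
        "genotype": float(phi[0]),
        "gxe": float(phi[1]) if use_ge else 0.0,
        "residual": float(sigma2),
        "loglik": float(ll),
        "converged": converged,
        "n_iter": n_iter,
    }
    return EnvBlupResult(blups, vc, anova)


def _fixed_anova(y, ent_idx, env_idx, n_ent, n_env):
    """Type-II F tests of genotype and environment in the fixed two-way
    (no-interaction) model."""
    n = y.size

    def dummies(idx, k):
        Z = np.zeros((n, k - 1))
        for j in range(1, k):
            Z[:, j - 1] = (idx == j).astype(float)
        return Z

    ones = np.ones((n, 1))
    G = dummies(ent_idx, n_ent)
    E = dummies(env_idx, n_env)

    def rss(M):
        b, res, *_ = np.linalg.lstsq(M, y, rcond=None)
        pred = M @ b
        return float(np.sum((y - pred) ** 2)), np.linalg.matrix_rank(M)

    rss_full, rank_full = rss(np.hstack([ones, G, E]))
    df_resid = n - rank_full
    rows = []
    for name, reduced, df_eff in (
        ("genotype", np.hstack([ones, E]), n_ent - 1),
        ("env", np.hstack([ones, G]), n_env - 1),
    ):
        if df_eff == 0:
            rows.append({"term": name, "df": 0, "F": np.nan, "p": np.nan})
            continue
        rss_red, _ = rss(reduced)
        F = ((rss_red - rss_full) / df_eff) / (rss_full / max(df_resid, 1))
        p = float(stats.f.sf(F, df_eff, max(df_resid, 1)))
        rows.append({"term": name, "df": df_eff, "F": float(F), "p": p})
    return pd.DataFrame(rows)
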