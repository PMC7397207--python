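"""REML variance components, GEBVs and derived summaries.

The univariate engine maximizes the restricted likelihood of
``y ~ N(Xb, K * sigma_a2 + I * sigma_e2)`` by eigen-rotating the GRM once and
profiling the likelihood over the variance ratio ``lambda = sigma_a2 /
sigma_e2`` (1-D bounded optimization on the log scale, residual variance
solved in closed form), followed by an average-information step to obtain
standard errors.  The bivariate engine maximizes the 2-trait restricted
likelihood on the same rotated scale over log-variances and
atanh-correlations; per-eigenvalue 2x2 blocks keep each likelihood
evaluation O(n p^2).

Missing phenotypes (non-coagulating ewes on cheese-making traits) are
handled by case-wise deletion per trait, with the GRM sub-set to match;
GEBVs for unphenotyped animals are predicted through their genomic
covariance with the phenotyped ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .core import GenotypeMatrix
from .qc_grm import GRM, compute_grm
from .traits import TraitArchitecture

_LOG_LAMBDA_BOUNDS = (-18.5, 18.5)  # lambda in ~[1e-8, 1e8]
_ATANH_BOUND = 6.0                  # |r| <= tanh(6) ~ 0.9999877


# ---------------------------------------------------------------------------
# fixed-effect design

def build_fixed_design(pheno: pd.DataFrame,
                       factors: tuple[str, ...] = ("AGE_NB", "FTD", "NBL"),
                       covariates: tuple[str, ...] = ("DIM",)) -> pd.DataFrame:
    """Incidence matrix: intercept + drop-first factor dummies + covariates.

    Factors absent from the table are skipped; columns made redundant by the
    realized data (empty levels, collinearity) are dropped with a warning so
    the returned design always has full column rank.
    """
    cols = {"intercept": np.ones(len(pheno))}
    for f in factors:
        if f not in pheno.columns:
            continue
        dummies = pd.get_dummies(pheno[f].astype("category"), prefix=f,
                                 drop_first=True, dtype=float)
        for c in dummies.columns:
            cols[c] = dummies[c].to_numpy()
    for c in covariates:
        if c in pheno.columns:
            cols[c] = pheno[c].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=pheno.index)
    # enforce estimability via pivoted QR
    arr = X.to_numpy()
    q, r, piv = _pivoted_qr(arr)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(r[0, 0]))))
    if rank < arr.shape[1]:
        keep = sorted(piv[:rank])
        dropped = [X.columns[i] for i in range(arr.shape[1]) if i not in keep]
        warnings.warn(f"dropping rank-deficient design columns: {dropped}",
                      stacklevel=2)
        X = X.iloc[:, keep]
    return X


def _pivoted_qr(a: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(a, mode="economic", pivoting=True)
    return q, r, piv


# ---------------------------------------------------------------------------
# univariate REML

@dataclass
class VarCompResult:
    sigma_a2: float
    sigma_e2: float
    h2: float
    se_sigma_a2: float
    se_sigma_e2: float
    se_h2: float
    beta: pd.Series
    loglik: float
    converged: bool
    n_iter: int
    n_used: int
    lambda_: float
    loglik_history: list[float] = field(default_factory=list)


def _rotated(grm: GRM | np.ndarray, mask: np.ndarray,
             eig_cache: dict | None = None):
    """Eigendecomposition of the GRM restricted to the observation mask."""
    key = mask.tobytes() if eig_cache is not None else None
    if eig_cache is not None and key in eig_cache:
        return eig_cache[key]
    K = grm.matrix if isinstance(grm, GRM) else np.asarray(grm)
    if mask.all() and isinstance(grm, GRM):
        d, U = grm.eig()
    else:
        Ks = K[np.ix_(mask.nonzero()[0], mask.nonzero()[0])]
        d, U = np.linalg.eigh(Ks)
        d = np.clip(d, 0.0, None)
    out = (d, U)
    if eig_cache is not None:
        eig_cache[key] = out
    return out


def _profile_negloglik(log_lam: float, d: np.ndarray, yt: np.ndarray,
                       Xt: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Negative REML log-likelihood profiled over sigma_e2 at fixed lambda."""
    lam = np.exp(log_lam)
    v = lam * d + 1.0
    w = 1.0 / v
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    try:
        cf = np.linalg.cholesky(XtWX)
    except np.linalg.LinAlgError:
        return np.inf, np.nan, np.zeros(Xt.shape[1])
    beta = np.linalg.solve(cf.T, np.linalg.solve(cf, XtWy))
    n, p = Xt.shape
    rss = float(yt @ (w * yt) - XtWy @ beta)
    rss = max(rss, 1e-300)
    sigma_e2 = rss / (n - p)
    logdet_xwx = 2.0 * float(np.sum(np.log(np.diag(cf))))
    nll = 0.5 * (np.sum(np.log(v)) + logdet_xwx
                 + (n - p) * np.log(sigma_e2) + (n - p))
    return nll, sigma_e2, beta


def _ai_matrix(d, yt, Xt, sigma_a2, sigma_e2):
    """Average-information matrix for (sigma_a2, sigma_e2) on the rotated scale."""
    v = sigma_a2 * d + sigma_e2
    w = 1.0 / v
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    XtWX_inv = np.linalg.inv(XtWX)

    def P(u):
        wu = w * u
        return wu - Xw @ (XtWX_inv @ (Xw.T @ u))

    py = P(yt)
    u_a = d * py
    u_e = py
    pa, pe = P(u_a), P(u_e)
    AI = 0.5 * np.array([[u_a @ pa, u_a @ pe], [u_e @ pa, u_e @ pe]])
    return AI


def fit_univariate_reml(y: np.ndarray, X: np.ndarray | pd.DataFrame,
                        grm: GRM | np.ndarray, tol: float = 1e-6,
                        max_iter: int = 100,
                        eig_cache: dict | None = None,
                        lambda_hint: float | None = None) -> VarCompResult:
    """Univariate GRM-REML fit of one trait.

    ``lambda_hint`` narrows the initial search bracket around a previous
    solution (used to warm-start stepwise refits); the bracket is widened
    back to the full range whenever the optimum lands on its edge, so the
    result matches a cold start.
    """
    y = np.asarray(y, dtype=float)
    X_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    mask = np.isfinite(y)
    if mask.sum() <= Xa.shape[1] + 1:
        raise ValueError("too few non-missing observations")
    d, U = _rotated(grm, mask, eig_cache)
    yo, Xo = y[mask], Xa[mask]
    yt = U.T @ yo
    Xt = U.T @ Xo

    lo, hi = _LOG_LAMBDA_BOUNDS
    if lambda_hint is not None and lambda_hint > 0:
        c = np.log(lambda_hint)
        lo_h, hi_h = max(lo, c - 4.0), min(hi, c + 4.0)
    else:
        lo_h, hi_h = lo, hi

    history: list[float] = []

    def neg(log_lam):
        val = _profile_negloglik(log_lam, d, yt, Xt)[0]
        best = -val if not history else max(history[-1], -val)
        history.append(best)
        return val

    def solve(a, b):
        # coarse scan guards against local minima of the profile, then a
        # bounded 1-D refine within the bracketing interval
        grid = np.linspace(a, b, 41)
        vals = [neg(g) for g in grid]
        k = int(np.argmin(vals))
        a_ref = grid[max(0, k - 1)]
        b_ref = grid[min(len(grid) - 1, k + 1)]
        return optimize.minimize_scalar(
            neg, bounds=(a_ref, b_ref), method="bounded",
            options={"xatol": tol, "maxiter": max_iter})

    res = solve(lo_h, hi_h)
    # widen if the hint bracket pinned the optimum at an interior edge
    if (lo_h, hi_h) != (lo, hi) and (res.x - lo_h < 0.5 or hi_h - res.x < 0.5):
        res = solve(lo, hi)
    log_lam = float(res.x)
    nll, sigma_e2, beta = _profile_negloglik(log_lam, d, yt, Xt)
    lam = np.exp(log_lam)
    sigma_a2 = lam * sigma_e2
    h2 = sigma_a2 / (sigma_a2 + sigma_e2)

    try:
        AI = _ai_matrix(d, yt, Xt, sigma_a2, sigma_e2)
        AI_inv = np.linalg.inv(AI)
        se_a = float(np.sqrt(max(AI_inv[0, 0], 0.0)))
        se_e = float(np.sqrt(max(AI_inv[1, 1], 0.0)))
        tot = sigma_a2 + sigma_e2
        g = np.array([sigma_e2, -sigma_a2]) / tot**2
        se_h2 = float(np.sqrt(max(g @ AI_inv @ g, 0.0)))
    except np.linalg.LinAlgError:
        se_a = se_e = se_h2 = np.nan

    converged = bool(res.success) and np.isfinite(nll)
    names = X_names or [f"b{i}" for i in range(Xa.shape[1])]
    return VarCompResult(
        sigma_a2=float(sigma_a2), sigma_e2=float(sigma_e2), h2=float(h2),
        se_sigma_a2=se_a, se_sigma_e2=se_e, se_h2=se_h2,
        beta=pd.Series(beta, index=names), loglik=float(-nll),
        converged=converged, n_iter=int(res.nfev), n_used=int(mask.sum()),
        lambda_=float(lam), loglik_history=history,
    )


def reml_grid_search(y, X, grm, n_grid: int = 200,
                     log_bounds: tuple[float, float] = (-7.0, 7.0)) -> float:
    """Brute-force h2 by a log-spaced lambda grid (independent cross-check)."""
    y = np.asarray(y, dtype=float)
    Xa = np.asarray(X, dtype=float)
    mask = np.isfinite(y)
    d, U = _rotated(grm, mask, None)
    yt, Xt = U.T @ y[mask], U.T @ Xa[mask]
    grid = np.linspace(*log_bounds, n_grid)
    nll = [_profile_negloglik(g, d, yt, Xt)[0] for g in grid]
    lam = np.exp(grid[int(np.argmin(nll))])
    return float(lam / (1.0 + lam))


def fit_all_traits(pheno: pd.DataFrame, traits: list[str],
                   X: pd.DataFrame, grm: GRM,
                   eig_cache: dict | None = None,
                   lambda_hints: dict[str, float] | None = None,
                   ) -> dict[str, VarCompResult]:
    """Univariate fits per trait, sharing eigendecompositions across traits
    with the same missingness pattern (one decomposition covers all 7 milk
    traits, one more the cheese traits)."""
    cache = {} if eig_cache is None else eig_cache
    out = {}
    for t in traits:
        hint = (lambda_hints or {}).get(t)
        out[t] = fit_univariate_reml(pheno[t].to_numpy(), X, grm,
                                     eig_cache=cache, lambda_hint=hint)
    return out


# ---------------------------------------------------------------------------
# bivariate REML

@dataclass
class BivarResult:
    gen_cov: np.ndarray          # 2x2 genetic covariance
    res_cov: np.ndarray          # 2x2 residual covariance
    r_g: float
    se_r_g: float
    r_p: float
    h2: tuple[float, float]
    loglik: float
    converged: bool
    boundary: bool               # |r| pinned at the parameterization bound
    n_used: int


def _bivar_negloglik(theta, d, y1, y2, Xt):
    la1, la2, za, le1, le2, ze = theta
    ga1, ga2 = np.exp(la1), np.exp(la2)
    e1, e2 = np.exp(le1), np.exp(le2)
    rg, re = np.tanh(za), np.tanh(ze)
    gc = rg * np.sqrt(ga1 * ga2)
    ec = re * np.sqrt(e1 * e2)

    a = d * ga1 + e1
    b = d * gc + ec
    c = d * ga2 + e2
    det = a * c - b * b
    if np.any(det <= 0):
        return np.inf
    ia, ib, ic = c / det, -b / det, a / det

    n, p = Xt.shape
    yVy = float(y1 @ (ia * y1) + 2.0 * y1 @ (ib * y2) + y2 @ (ic * y2))
    Xa_ = Xt * ia[:, None]
    Xb_ = Xt * ib[:, None]
    Xc_ = Xt * ic[:, None]
    XVX = np.block([[Xt.T @ Xa_, Xt.T @ Xb_], [Xb_.T @ Xt, Xt.T @ Xc_]])
    XVy = np.concatenate([Xa_.T @ y1 + Xb_.T @ y2, Xb_.T @ y1 + Xc_.T @ y2])
    try:
        cf = np.linalg.cholesky(XVX)
    except np.linalg.LinAlgError:
        return np.inf
    beta = np.linalg.solve(cf.T, np.linalg.solve(cf, XVy))
    quad = yVy - XVy @ beta
    logdet_v = float(np.sum(np.log(det)))
    logdet_x = 2.0 * float(np.sum(np.log(np.diag(cf))))
    return 0.5 * (logdet_v + logdet_x + quad)


def fit_bivariate_reml(y1: np.ndarray, y2: np.ndarray,
                       X: np.ndarray | pd.DataFrame, grm: GRM | np.ndarray,
                       tol: float = 1e-8, max_iter: int = 500,
                       eig_cache: dict | None = None) -> BivarResult:
    """Bivariate GRM-REML on the complete cases of both traits.

    Maximizes the restricted likelihood over (log genetic variances, atanh
    genetic correlation, log residual variances, atanh residual correlation)
    on the eigen-rotated scale; boundary genetic correlations (|r_g| -> 1)
    are absorbed by the atanh parameterization and flagged.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    Xa = np.asarray(X, dtype=float)
    mask = np.isfinite(y1) & np.isfinite(y2)
    if mask.sum() < 50:
        raise ValueError("need >= 50 overlapping non-missing animals")
    d, U = _rotated(grm, mask, eig_cache)
    y1t, y2t = U.T @ y1[mask], U.T @ y2[mask]
    Xt = U.T @ Xa[mask]

    # univariate starts
    uni1 = fit_univariate_reml(y1, Xa, grm, eig_cache=eig_cache)
    uni2 = fit_univariate_reml(y2, Xa, grm, eig_cache=eig_cache)
    r0 = float(np.clip(np.corrcoef(y1t, y2t)[0, 1], -0.8, 0.8))
    floor = 1e-8
    theta0 = np.array([
        np.log(max(uni1.sigma_a2, floor)), np.log(max(uni2.sigma_a2, floor)),
        np.arctanh(r0),
        np.log(max(uni1.sigma_e2, floor)), np.log(max(uni2.sigma_e2, floor)),
        np.arctanh(r0),
    ])
    def objective(theta):
        # clamp the correlation parameters so the simplex cannot leave the
        # parameter space (tanh keeps |r| < 1; the clamp keeps it finite)
        th = theta.copy()
        th[2] = np.clip(th[2], -_ATANH_BOUND, _ATANH_BOUND)
        th[5] = np.clip(th[5], -_ATANH_BOUND, _ATANH_BOUND)
        return _bivar_negloglik(th, d, y1t, y2t, Xt)

    res = optimize.minimize(
        objective, theta0, method="Nelder-Mead",
        options={"maxiter": max_iter * 20, "xatol": 1e-6, "fatol": tol,
                 "adaptive": True})
    # one restart from the incumbent guards against premature collapse
    res2 = optimize.minimize(
        objective, res.x, method="Nelder-Mead",
        options={"maxiter": max_iter * 20, "xatol": 1e-8, "fatol": tol,
                 "adaptive": True})
    if res2.fun < res.fun:
        res = res2
    res.x[2] = np.clip(res.x[2], -_ATANH_BOUND, _ATANH_BOUND)
    res.x[5] = np.clip(res.x[5], -_ATANH_BOUND, _ATANH_BOUND)

    la1, la2, za, le1, le2, ze = res.x
    ga1, ga2 = np.exp(la1), np.exp(la2)
    e1, e2 = np.exp(le1), np.exp(le2)
    rg, re = float(np.tanh(za)), float(np.tanh(ze))
    gc = rg * np.sqrt(ga1 * ga2)
    ec = re * np.sqrt(e1 * e2)
    boundary = abs(za) >= _ATANH_BOUND - 1e-3

    se_rg = np.nan
    try:
        H = _numerical_hessian(
            lambda th: _bivar_negloglik(th, d, y1t, y2t, Xt), res.x)
        cov = np.linalg.inv(H)
        se_za = float(np.sqrt(max(cov[2, 2], 0.0)))
        se_rg = (1.0 - rg**2) * se_za
    except np.linalg.LinAlgError:
        pass

    tot1, tot2 = ga1 + e1, ga2 + e2
    r_p = (gc + ec) / np.sqrt(tot1 * tot2)
    return BivarResult(
        gen_cov=np.array([[ga1, gc], [gc, ga2]]),
        res_cov=np.array([[e1, ec], [ec, e2]]),
        r_g=rg, se_r_g=float(se_rg), r_p=float(r_p),
        h2=(float(ga1 / tot1), float(ga2 / tot2)),
        loglik=float(-res.fun), converged=bool(res.success),
        boundary=bool(boundary), n_used=int(mask.sum()),
    )


def _numerical_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
    if not np.all(np.isfinite(H)):
        raise np.linalg.LinAlgError("non-finite Hessian")
    return H


# ---------------------------------------------------------------------------
# GEBV, variance fractions, z-score

def compute_gebv(y: np.ndarray, X: np.ndarray | pd.DataFrame, grm: GRM,
                 varcomp: VarCompResult) -> np.ndarray:
    """BLUP breeding values a_hat = sigma_a2 * K V^-1 (y - X b_hat).

    Animals with missing phenotypes receive predictions through their GRM
    covariance with the phenotyped animals.
    """
    y = np.asarray(y, dtype=float)
    Xa = np.asarray(X, dtype=float)
    n = grm.n
    if varcomp.sigma_a2 <= 0:
        return np.zeros(n)
    mask = np.isfinite(y)
    obs = mask.nonzero()[0]
    K_oo = grm.matrix[np.ix_(obs, obs)]
    V = varcomp.sigma_a2 * K_oo + varcomp.sigma_e2 * np.eye(len(obs))
    Xo, yo = Xa[obs], y[obs]
    Vinv_X = np.linalg.solve(V, Xo)
    Vinv_y = np.linalg.solve(V, yo)
    XtVX = Xo.T @ Vinv_X
    beta = np.linalg.solve(XtVX, Xo.T @ Vinv_y)
    alpha = np.linalg.solve(V, yo - Xo @ beta)
    return varcomp.sigma_a2 * (grm.matrix[:, obs] @ alpha)


def gebv_table(pheno: pd.DataFrame, traits: list[str], X: pd.DataFrame,
               grm: GRM, fits: dict[str, VarCompResult]) -> pd.DataFrame:
    cols = {t: compute_gebv(pheno[t].to_numpy(), X, grm, fits[t])
            for t in traits}
    return pd.DataFrame(cols, index=pheno["animal_id"].tolist())


def variance_fraction(subset_snps: list[str], G: GenotypeMatrix,
                      pheno: pd.DataFrame, traits: list[str],
                      X: pd.DataFrame, full_sigma_a2: dict[str, float],
                      lambda_hints: dict[str, float] | None = None,
                      ) -> tuple[dict[str, float], float]:
    """Fraction of the all-SNP genetic variance captured by a SNP subset.

    Builds a GRM from the subset, refits the univariate REML per trait and
    returns sigma_a2(subset) / sigma_a2(all) per trait plus the across-trait
    mean.  Fractions may exceed 1.
    """
    if not subset_snps:
        raise ValueError("empty SNP subset")
    sub = G.subset_snps(list(subset_snps))
    grm = compute_grm(sub)
    cache: dict = {}
    fracs = {}
    for t in traits:
        denom = full_sigma_a2[t]
        if denom <= 0:
            fracs[t] = np.nan
            continue
        fit = fit_univariate_reml(pheno[t].to_numpy(), X, grm,
                                  eig_cache=cache,
                                  lambda_hint=(lambda_hints or {}).get(t))
        fracs[t] = fit.sigma_a2 / denom
    vals = [v for v in fracs.values() if np.isfinite(v)]
    return fracs, float(np.mean(vals))


def zscore_summary(gebv: pd.DataFrame, arch: TraitArchitecture) -> pd.Series:
    """Cross-trait cheese-merit z-score from per-trait GEBVs.

    Each GEBV column is standardized, sign-inverted for the traits where
    smaller values mean better cheese-making (clotting/firming times, the
    RCT/A60 ratio, SCC and pH), summed across traits, and the sum is
    standardized again; the result has mean exactly 0 and SD exactly 1.
    """
    missing = [t for t in arch.traits if t not in gebv.columns]
    if missing:
        raise ValueError(f"GEBV table missing traits: {missing}")
    total = np.zeros(len(gebv))
    for t in arch.traits:
        col = gebv[t].to_numpy(dtype=float)
        sd = col.std()
        if sd == 0:
            warnings.warn(f"zero-variance GEBV column {t} contributes 0",
                          stacklevel=2)
            continue
        z = (col - col.mean()) / sd
        if arch.invert_for_zscore.get(t, False):
            z = -z
        total += z
    sd = total.std()
    if sd > 0:
        total = (total - total.mean()) / sd
    return pd.Series(total, index=gebv.index, name="zscore")


def se_weighted_h2(estimates: list[tuple[float, float]],
                   max_weight: float = 1e8) -> float:
    """Inverse-SE weighted mean of h2 estimates; zero SEs get capped weight."""
    if not estimates:
        raise ValueError("no estimates")
    h = np.array([e[0] for e in estimates])
    se = np.array([e[1] for e in estimates])
    w = np.where(se > 0, 1.0 / np.where(se > 0, se, 1.0), max_weight)
    w = np.minimum(w, max_weight)
    return float(np.sum(w * h) / np.sum(w))
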