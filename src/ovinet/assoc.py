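"""Single-SNP mixed-model GWAS and the multi-trait pleiotropy statistic.

The default GWAS backend is an EMMAX-style Wald test: variance components
are fixed at the null-model REML estimates and every SNP is tested as a
fixed covariate by generalized least squares under
``V = K sigma_a2 + I sigma_e2``.  An alternative backend back-solves SNP
effects from the GBLUP breeding values.  P-values are two-sided normal on
t = beta/se (at n ~ 1000 the df correction is negligible).

The pleiotropy statistic for gene i is the quadratic form
``MT_i = t_i' V^-1 t_i`` of its signed t-values across the traits, with V
the trait-by-trait correlation matrix of t-values estimated over all genes;
under the null MT is approximately chi-square with df = number of traits.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix
from .qc_grm import GRM
from .varcomp import VarCompResult, fit_univariate_reml, compute_gebv, _rotated


def gwas_single_trait(G: GenotypeMatrix, y: np.ndarray,
                      X: np.ndarray | pd.DataFrame, grm: GRM,
                      varcomp: VarCompResult | None = None,
                      backend: str = "emmax",
                      eig_cache: dict | None = None) -> pd.DataFrame:
    """Per-SNP association tests for one trait.

    Returns a DataFrame with snp_id, chrom, pos, beta, se, t, p, flag and a
    ``backend`` column recording which test produced the numbers.
    """
    y = np.asarray(y, dtype=float)
    Xa = np.asarray(X, dtype=float)
    if varcomp is None:
        varcomp = fit_univariate_reml(y, Xa, grm, eig_cache=eig_cache)
    if backend == "emmax":
        beta, se = _emmax_scan(G, y, Xa, grm, varcomp, eig_cache)
    elif backend == "gblup":
        beta, se = _gblup_scan(G, y, Xa, grm, varcomp)
    else:
        raise ValueError(f"unknown GWAS backend: {backend}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(t))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "snp_id": G.snp_ids,
        "chrom": G.snp_map["chrom"].to_numpy(),
        "pos": G.snp_map["pos"].to_numpy(),
        "beta": beta,
        "se": se,
        "t": t,
        "p": p,
        "flag": np.where(se > 0, "ok", "collinear"),
        "backend": backend,
    })


def _emmax_scan(G, y, Xa, grm, varcomp, eig_cache):
    mask = np.isfinite(y)
    d, U = _rotated(grm, mask, eig_cache)
    yt = U.T @ y[mask]
    Xt = U.T @ Xa[mask]
    Mt = U.T @ G.imputed_dosage()[mask]
    v = varcomp.sigma_a2 * d + varcomp.sigma_e2
    w = 1.0 / v
    Xw = Xt * w[:, None]
    XtWX_inv = np.linalg.inv(Xt.T @ Xw)
    # residualize y and every SNP against X under the weighted inner product
    y_r = yt - Xt @ (XtWX_inv @ (Xw.T @ yt))
    M_r = Mt - Xt @ (XtWX_inv @ (Xw.T @ Mt))
    gg = np.einsum("ij,ij->j", M_r, M_r * w[:, None])
    gy = M_r.T @ (w * y_r)
    ok = gg > 1e-10
    beta = np.where(ok, gy / np.where(ok, gg, 1.0), 0.0)
    se = np.where(ok, 1.0 / np.sqrt(np.where(ok, gg, 1.0)), 0.0)
    return beta, se


def _gblup_scan(G, y, Xa, grm, varcomp):
    """Back-solve SNP effects from GBLUP: u = Z' V^-1 (y - Xb) * sigma_a2/c."""
    mask = np.isfinite(y)
    obs = mask.nonzero()[0]
    M = G.imputed_dosage()
    p_frq = M.mean(axis=0) / 2.0
    Z = M - 2.0 * p_frq
    c = grm.denominator
    Zo = Z[obs]
    V = varcomp.sigma_a2 * grm.matrix[np.ix_(obs, obs)] \
        + varcomp.sigma_e2 * np.eye(len(obs))
    Vinv = np.linalg.inv(V)
    Xo, yo = Xa[obs], y[obs]
    XtVX = Xo.T @ Vinv @ Xo
    beta_f = np.linalg.solve(XtVX, Xo.T @ Vinv @ yo)
    r = yo - Xo @ beta_f
    k = varcomp.sigma_a2 / c
    u = k * (Zo.T @ (Vinv @ r))
    # Var(u_j) = k^2 * z_j' Vinv (V - X(X'VinvX)^-1 X') Vinv z_j ~ k^2 z'Vinv z
    VZ = Vinv @ Zo
    var_u = k**2 * np.einsum("ij,ij->j", Zo, VZ)
    se = np.sqrt(np.clip(var_u, 0.0, None))
    return u, se


def run_gwas(G: GenotypeMatrix, pheno: pd.DataFrame, traits: list[str],
             X: pd.DataFrame, grm: GRM,
             fits: dict[str, VarCompResult] | None = None,
             backend: str = "emmax") -> dict[str, pd.DataFrame]:
    """GWAS for every trait, sharing rotations across traits."""
    cache: dict = {}
    out = {}
    for t in traits:
        vc = fits.get(t) if fits else None
        out[t] = gwas_single_trait(G, pheno[t].to_numpy(), X, grm,
                                   varcomp=vc, backend=backend,
                                   eig_cache=cache)
    return out


def build_effect_matrix(gwas_results: dict[str, pd.DataFrame],
                        snp_gene_map: pd.DataFrame,
                        trait_order: list[str],
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x trait matrices of signed t-values and p-values.

    One row per mapped gene (via its representative SNP), columns in the
    canonical trait order regardless of input ordering.
    """
    missing = [t for t in trait_order if t not in gwas_results]
    if missing:
        raise ValueError(f"GWAS results missing traits: {missing}")
    snp_to_gene = dict(zip(snp_gene_map["snp_id"], snp_gene_map["gene_id"]))
    t_cols, p_cols = {}, {}
    for t in trait_order:
        res = gwas_results[t].set_index("snp_id")
        t_cols[t] = res["t"]
        p_cols[t] = res["p"]
    tmat = pd.DataFrame(t_cols)
    pmat = pd.DataFrame(p_cols)
    keep = [s for s in tmat.index if s in snp_to_gene]
    tmat = tmat.loc[keep]
    pmat = pmat.loc[keep]
    genes = [snp_to_gene[s] for s in keep]
    tmat.index = genes
    pmat.index = genes
    if tmat.isna().any().any():
        raise ValueError("effect matrix has missing cells")
    order = np.argsort(genes, kind="stable")
    return tmat.iloc[order], pmat.iloc[order]


def pleiotropy_statistic(t_matrix: pd.DataFrame,
                         trim_top_frac: float = 0.0) -> pd.DataFrame:
    """Multi-trait pleiotropy chi-square per gene.

    ``trim_top_frac`` optionally excludes the rows with the largest mean |t|
    from the estimation of the trait-correlation matrix V (V itself is
    applied to every row).
    """
    k = t_matrix.shape[1]
    if t_matrix.shape[0] < 2 * k:
        warnings.warn("fewer than 2x n_traits genes; V may be unstable",
                      stacklevel=2)
    T = t_matrix.to_numpy(dtype=float)
    est = T
    if trim_top_frac > 0:
        score = np.abs(T).mean(axis=1)
        cut = np.quantile(score, 1.0 - trim_top_frac)
        est = T[score <= cut]
    V = np.corrcoef(est, rowvar=False)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        warnings.warn("singular t-correlation matrix; ridge-regularized",
                      stacklevel=2)
        Vinv = np.linalg.inv(V + 1e-6 * np.eye(k))
    mt = np.einsum("ij,jk,ik->i", T, Vinv, T)
    mt = np.clip(mt, 0.0, None)
    p = stats.chi2.sf(mt, df=k)
    return pd.DataFrame({"gene_id": t_matrix.index, "mt": mt, "df": k,
                         "p": p}).set_index("gene_id")
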