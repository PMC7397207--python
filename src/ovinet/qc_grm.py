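"""Genotype quality control, VanRaden GRM, SNP-to-gene mapping, pedigromics.

QC keeps markers with minor allele frequency strictly above 5% and a
Hardy-Weinberg p-value strictly above 0.05 (chi-square goodness-of-fit by
default, Wigginton exact test selectable).  The genomic relationship matrix
follows VanRaden method 1, G = ZZ' / (2 * sum p(1-p)) with Z = M - 2p and
observed allele frequencies; missing dosages are mean-imputed.  SNPs are
assigned to genes when they lie within the gene span or a 20-kb window
around it, reduced to one representative SNP per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix, GeneAnnotation


# ---------------------------------------------------------------------------
# Hardy-Weinberg

def hwe_test(n_aa: int, n_ab: int, n_bb: int, method: str = "chi2") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    ``chi2`` is the 1-df goodness-of-fit test against expected counts at the
    observed allele frequency; ``exact`` is the Wigginton mid-less exact test
    on heterozygote counts.  Monomorphic samples return p = 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    if method == "chi2":
        exp = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        obs = np.array([n_aa, n_ab, n_bb], dtype=float)
        chi2 = float(np.sum((obs - exp) ** 2 / exp))
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact(n_aa, n_ab, n_bb)
    raise ValueError(f"unknown HWE method: {method}")


def _hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Wigginton et al. exact HWE test (sum of probabilities <= observed)."""
    n = n_aa + n_ab + n_bb
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    # heterozygote count shares the parity of the rare allele count
    het_vals = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.zeros(len(het_vals))
    # recurrence on log scale: P(het+2)/P(het) = ...
    for i in range(1, len(het_vals)):
        het = het_vals[i - 1]
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        ratio = (4.0 * hom_r * hom_c) / ((het + 2.0) * (het + 1.0))
        logp[i] = logp[i - 1] + np.log(ratio)
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[het_vals == n_ab][0]
    return float(min(1.0, prob[prob <= obs + 1e-12].sum()))


# ---------------------------------------------------------------------------
# QC filter

def genotype_counts(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP counts of the three genotype classes (missing ignored)."""
    D = G.dosage
    return pd.DataFrame({
        "snp_id": G.snp_ids,
        "n_ref": np.nansum(D == 0, axis=0).astype(int),
        "n_het": np.nansum(D == 1, axis=0).astype(int),
        "n_alt": np.nansum(D == 2, axis=0).astype(int),
    })


def qc_filter(G: GenotypeMatrix, maf_min: float = 0.05,
              hwe_p_min: float = 0.05, hwe_method: str = "chi2",
              ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter SNPs on MAF > maf_min and HWE p > hwe_p_min (both strict).

    Returns the filtered matrix and a per-SNP report with the failing rule
    for each removed marker.
    """
    counts = genotype_counts(G)
    maf = G.minor_allele_freq()
    hwe_p = np.array([
        hwe_test(int(r.n_alt), int(r.n_het), int(r.n_ref), method=hwe_method)
        if (r.n_ref + r.n_het + r.n_alt) > 0 else 0.0
        for r in counts.itertuples()
    ])
    maf_ok = np.nan_to_num(maf, nan=0.0) > maf_min
    hwe_ok = hwe_p > hwe_p_min
    keep = maf_ok & hwe_ok
    reasons = np.where(keep, "pass",
                       np.where(~maf_ok & ~hwe_ok, "maf;hwe",
                                np.where(~maf_ok, "maf", "hwe")))
    report = pd.DataFrame({
        "snp_id": G.snp_ids,
        "maf": maf,
        "hwe_p": hwe_p,
        "kept": keep,
        "rule_failed": reasons,
    })
    if not keep.any():
        import warnings

        warnings.warn("QC removed every SNP", stacklevel=2)
        filtered = GenotypeMatrix(ids=list(G.ids),
                                  snp_map=G.snp_map.iloc[:0],
                                  dosage=G.dosage[:, :0])
        return filtered, report
    filtered = GenotypeMatrix(
        ids=list(G.ids),
        snp_map=G.snp_map.loc[keep].reset_index(drop=True),
        dosage=G.dosage[:, keep],
    )
    return filtered, report


# ---------------------------------------------------------------------------
# GRM

@dataclass
class GRM:
    """VanRaden genomic relationship matrix with its scaling constant."""

    ids: list[str]
    matrix: np.ndarray
    denominator: float          # 2 * sum p(1-p)
    n_snps: int
    _eig: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (values, vectors), amortized across traits."""
        if self._eig is None:
            w, U = np.linalg.eigh(self.matrix)
            self._eig = (np.clip(w, 0.0, None), U)
        return self._eig

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]

    def submatrix(self, idx: np.ndarray) -> np.ndarray:
        return self.matrix[np.ix_(idx, idx)]


def compute_grm(G: GenotypeMatrix) -> GRM:
    """VanRaden method 1 GRM from observed allele frequencies."""
    if G.n_snps < 2:
        raise ValueError("need at least 2 SNPs to build a GRM")
    M = G.imputed_dosage()
    p = M.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: zero GRM denominator")
    Z = M - 2.0 * p
    K = (Z @ Z.T) / denom
    K = (K + K.T) / 2.0
    return GRM(ids=list(G.ids), matrix=K, denominator=denom, n_snps=G.n_snps)


def relationship_edges(grm: GRM, threshold: float = 0.20) -> pd.DataFrame:
    """Pedigromics edge list: pairs with genomic relationship > threshold."""
    i, j = np.triu_indices(grm.n, k=1)
    g = grm.matrix[i, j]
    keep = g > threshold
    return pd.DataFrame({
        "id_i": [grm.ids[a] for a in i[keep]],
        "id_j": [grm.ids[b] for b in j[keep]],
        "g_ij": g[keep],
    })


# ---------------------------------------------------------------------------
# SNP -> gene assignment

def assign_snps_to_genes(snp_map: pd.DataFrame, ann: GeneAnnotation,
                         window: int = 20000) -> pd.DataFrame:
    """Map SNPs to genes within the gene span +/- ``window`` bp (inclusive).

    Two-stage reduction: each SNP gets its nearest gene body (distance 0
    inside the span; ties broken by smaller gene start, then gene_id), then
    each gene keeps the single SNP nearest its midpoint (ties: smaller pos),
    so every retained SNP is the representative of exactly one gene.
    Unmapped SNPs are dropped.  Returns columns snp_id, gene_id, distance.
    """
    records = []
    genes_by_chrom = dict(tuple(ann.table.groupby("chrom", sort=False)))
    for chrom, snps in snp_map.groupby("chrom", sort=False):
        genes = genes_by_chrom.get(chrom)
        if genes is None:
            continue
        gs = genes["start"].to_numpy()[None, :]
        ge = genes["end"].to_numpy()[None, :]
        pos = snps["pos"].to_numpy()[:, None]
        dist = np.maximum(0, np.maximum(gs - pos, pos - ge))
        within = dist <= window
        for r, snp_id in enumerate(snps["snp_id"]):
            hits = np.flatnonzero(within[r])
            if hits.size == 0:
                continue
            d = dist[r, hits]
            order = sorted(
                range(len(hits)),
                key=lambda q: (d[q],
                               genes["start"].iloc[hits[q]],
                               genes["gene_id"].iloc[hits[q]]),
            )
            best = hits[order[0]]
            records.append((snp_id, genes["gene_id"].iloc[best],
                            int(d[order[0]]), int(snps["pos"].iloc[r]),
                            int(genes["start"].iloc[best]),
                            int(genes["end"].iloc[best])))
    if not records:
        return pd.DataFrame(columns=["snp_id", "gene_id", "distance"])
    df = pd.DataFrame(records, columns=["snp_id", "gene_id", "distance",
                                        "pos", "g_start", "g_end"])
    mid = (df["g_start"] + df["g_end"]) / 2.0
    df["mid_dist"] = (df["pos"] - mid).abs()
    df = (df.sort_values(["gene_id", "mid_dist", "pos"], kind="mergesort")
            .groupby("gene_id", as_index=False, sort=True).first())
    out = df[["snp_id", "gene_id", "distance"]].sort_values(
        "snp_id", kind="mergesort").reset_index(drop=True)
    return out
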