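"""Synthetic dairy-sheep study generator.

Emulates the statistical structure the downstream analysis assumes: a
commercial ewe population (default n=1039) genotyped on a gene-linked SNP
panel, 14 milk and cheese-making traits with the published heritabilities and
genomic correlations, fixed flock/parity/lactation-stage effects, and
missing cheese-making phenotypes for non-coagulating milk samples
(131 of 1039 in the source population).

Everything is seeded and bit-reproducible; :class:`SimulationTruth` carries
the causal SNPs, effects and true breeding values needed by parameter
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix, GeneAnnotation
from .traits import TraitArchitecture


@dataclass
class SimulationTruth:
    """Ground truth of one phenotype simulation."""

    causal_snps: list[str]
    effects: pd.DataFrame            # causal SNP x trait raw-dosage effects
    tbv: pd.DataFrame                # animal x trait true breeding values
    fixed_effects: dict[str, pd.DataFrame]  # factor -> level x trait values
    dim_slope: pd.Series             # per-trait DIM slope
    seed: int


def _chrom_layout(m: int, n_chrom: int, spacing: int) -> pd.DataFrame:
    """Evenly spaced SNP positions across ``n_chrom`` chromosomes."""
    per = np.full(n_chrom, m // n_chrom)
    per[: m % n_chrom] += 1
    rows = []
    i = 0
    for c in range(n_chrom):
        for j in range(per[c]):
            rows.append((f"snp{i:06d}", c + 1, (j + 1) * spacing))
            i += 1
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


def simulate_genotypes(n: int, m: int, maf_range: tuple[float, float] = (0.05, 0.5),
                       ld_rho: float = 0.0, missing_rate: float = 0.0,
                       seed: int = 0, n_chrom: int = 3,
                       spacing: int = 1000) -> GenotypeMatrix:
    """Simulate an n x m dosage matrix with optional local LD.

    Haplotypes are generated per chromosome from a latent Gaussian AR(1)
    chain with lag-1 correlation ``ld_rho``, thresholded at each SNP's allele
    frequency (a first-order Markov copying process along the chromosome);
    the two haplotypes of an individual are independent and summed into a
    dosage.  ``ld_rho = 0`` gives independent SNPs.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must lie in [0, 1)")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    layout = _chrom_layout(m, n_chrom, spacing)
    if lo == hi:
        p = np.full(m, lo)
    else:
        p = rng.uniform(lo, hi, size=m)
    thresh = stats.norm.ppf(p)  # allele 'alt' iff latent z < threshold

    dosage = np.zeros((n, m))
    for _hap in range(2):
        z = np.empty((n, m))
        start = 0
        for _, grp in layout.groupby("chrom", sort=False):
            k = len(grp)
            e = rng.standard_normal((n, k))
            block = np.empty((n, k))
            block[:, 0] = e[:, 0]
            scale = np.sqrt(1.0 - ld_rho**2)
            for j in range(1, k):
                block[:, j] = ld_rho * block[:, j - 1] + scale * e[:, j]
            z[:, start:start + k] = block
            start += k
        dosage += (z < thresh).astype(float)

    if missing_rate > 0:
        mask = rng.random((n, m)) < missing_rate
        dosage[mask] = np.nan

    snp_map = layout.assign(allele_ref="A", allele_alt="B")
    ids = [f"ewe{i:05d}" for i in range(n)]
    return GenotypeMatrix(ids=ids, snp_map=snp_map, dosage=dosage)


def simulate_annotation(m_genes: int, genome: list[int],
                        tf_fraction: float = 0.06, cf_fraction: float = 0.06,
                        seed: int = 0, min_len: int = 1000,
                        max_len: int = 20000) -> GeneAnnotation:
    """Place non-overlapping gene intervals on the given chromosome lengths.

    Genes are allocated to chromosomes proportionally to length, laid out
    left-to-right with random gaps, and labelled TF / CF / other with
    deterministic counts ``round(fraction * m_genes)``.
    """
    if tf_fraction + cf_fraction >= 1.0:
        raise ValueError("tf_fraction + cf_fraction must be < 1")
    if m_genes < 1:
        raise ValueError("m_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genome = [int(L) for L in genome]
    total = sum(genome)
    counts = np.array([round(m_genes * L / total) for L in genome])
    # fix rounding drift on the largest chromosome
    counts[int(np.argmax(genome))] += m_genes - counts.sum()

    rows = []
    gi = 0
    for c, (L, k) in enumerate(zip(genome, counts), start=1):
        if k == 0:
            continue
        if L < k * (min_len + 1):
            raise ValueError(f"chromosome {c} too short for {k} genes")
        # shrink gene lengths on short chromosomes so half the sequence
        # stays intergenic
        max_eff = int(min(max_len, max(min_len, (L - k) // (2 * k))))
        lengths = rng.integers(min_len, max_eff + 1, size=k)
        slack = L - lengths.sum() - k  # >=1bp gap between genes
        if slack < 0:
            raise ValueError(f"chromosome {c} too short for {k} genes")
        gaps = rng.multinomial(slack, np.ones(k) / k)
        pos = 1
        for j in range(k):
            start = pos + gaps[j]
            end = start + lengths[j] - 1
            rows.append((f"gene{gi:05d}", c, int(start), int(end)))
            pos = end + 2
            gi += 1
    tbl = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])

    n_tf = round(tf_fraction * m_genes)
    n_cf = round(cf_fraction * m_genes)
    labels = np.array(["other"] * m_genes, dtype=object)
    chosen = rng.choice(m_genes, size=n_tf + n_cf, replace=False)
    labels[chosen[:n_tf]] = "TF"
    labels[chosen[n_tf:]] = "CF"
    tbl["class"] = labels
    return GeneAnnotation(table=tbl)


def _exact_scale(E: np.ndarray, target_sd: np.ndarray) -> np.ndarray:
    """Rescale each column to the target sample SD (exact-variance scaling)."""
    out = E - E.mean(axis=0)
    sd = out.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fac = np.where(sd > 0, target_sd / np.where(sd > 0, sd, 1.0), 0.0)
    return out * fac


def simulate_phenotypes(G: GenotypeMatrix, arch: TraitArchitecture,
                        n_causal: int = 200, non_coag_rate: float = 0.0,
                        seed: int = 0, candidate_snps: list[str] | None = None,
                        fixed_effect_sd: float = 0.2,
                        resid_corr: np.ndarray | None = None,
                        ) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate correlated phenotypes under the additive mixed model.

    Phenotype = trait mean + fixed effects (AGE_NB, FTD, NBL factors and a
    DIM covariate) + true breeding value + residual.  Causal SNPs are drawn
    uniformly from ``candidate_snps`` (default: all SNPs); per-trait effects
    are multivariate normal across traits with the architecture's genetic
    correlation, applied on the raw dosage scale (matching the VanRaden GRM
    scaling).  TBV and residual columns are rescaled to hit the target
    genetic and residual variances exactly in-sample, so the realized per-
    trait heritability equals the architecture's h2 up to fixed-effect noise.

    Animals flagged non-coagulating (exactly ``round(rate * n)`` of them,
    drawn without replacement) have every cheese-group trait set missing.
    """
    if n_causal < 1 or n_causal > G.n_snps:
        raise ValueError("n_causal must be in [1, m]")
    if not 0.0 <= non_coag_rate < 1.0:
        raise ValueError("non_coag_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = G.n_individuals
    traits = arch.traits
    k = len(traits)

    pool = candidate_snps if candidate_snps is not None else G.snp_ids
    if n_causal > len(pool):
        raise ValueError("n_causal exceeds candidate pool")
    causal = sorted(rng.choice(len(pool), size=n_causal, replace=False))
    causal_ids = [pool[i] for i in causal]

    C = arch.genetic_corr.loc[traits, traits].to_numpy()
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    if w.min() < -1e-8:
        raise ValueError("genetic correlation matrix not PSD")
    L = V * np.sqrt(np.clip(w, 0.0, None))
    B = rng.standard_normal((n_causal, k)) @ L.T  # correlated across traits

    col_idx = G.snp_map.set_index("snp_id").index.get_indexer(causal_ids)
    Zc = G.imputed_dosage()[:, col_idx]
    Zc = Zc - Zc.mean(axis=0)
    g_sd = np.array([arch.genetic_sd(t) for t in traits])
    tbv = _exact_scale(Zc @ B, g_sd)

    e_sd = np.array([arch.residual_sd(t) for t in traits])
    if resid_corr is None:
        E = rng.standard_normal((n, k))
    else:
        Rc = np.asarray(resid_corr, dtype=float)
        wr, Vr = np.linalg.eigh((Rc + Rc.T) / 2.0)
        E = rng.standard_normal((n, k)) @ (Vr * np.sqrt(np.clip(wr, 0, None))).T
    E = _exact_scale(E, e_sd)

    # fixed effects: level assignment shared across traits, per-trait values
    p_sd = np.array([arch.pheno_sd[t] for t in traits])
    factors: dict[str, np.ndarray] = {}
    fixed_values: dict[str, pd.DataFrame] = {}
    Xb = np.zeros((n, k))
    for name, n_lev in arch.fixed_effect_levels.items():
        lev = rng.integers(0, n_lev, size=n)
        vals = rng.standard_normal((n_lev, k)) * (fixed_effect_sd * p_sd)
        factors[name] = lev
        fixed_values[name] = pd.DataFrame(
            vals, index=[f"{name}_{j}" for j in range(n_lev)], columns=traits)
        Xb += vals[lev]
    dim = rng.uniform(*arch.dim_range, size=n)
    dim_sd = np.std(dim) if np.std(dim) > 0 else 1.0
    slope = rng.standard_normal(k) * (fixed_effect_sd * p_sd) / dim_sd
    Xb += np.outer(dim - dim.mean(), slope)

    mu = np.array([arch.pheno_mean[t] for t in traits])
    Y = mu + Xb + tbv + E

    pheno = pd.DataFrame(Y, columns=traits)
    pheno.insert(0, "animal_id", G.ids)
    for name in arch.fixed_effect_levels:
        pheno[name] = factors[name]
    pheno["DIM"] = dim

    n_nc = round(non_coag_rate * n)
    coag = np.ones(n, dtype=bool)
    if n_nc > 0:
        nc = rng.choice(n, size=n_nc, replace=False)
        coag[nc] = False
        cheese = arch.cheese_traits()
        pheno.loc[~coag, cheese] = np.nan
    pheno["coagulated"] = coag.astype(int)

    truth = SimulationTruth(
        causal_snps=causal_ids,
        effects=pd.DataFrame(B, index=causal_ids, columns=traits),
        tbv=pd.DataFrame(tbv, index=list(G.ids), columns=traits),
        fixed_effects=fixed_values,
        dim_slope=pd.Series(slope, index=traits),
        seed=seed,
    )
    return pheno, truth
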