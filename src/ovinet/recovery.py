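"""Parameter-recovery studies: simulate under known genetic parameters and
measure how well the REML machinery recovers them.

These studies anchor the pipeline to the published genetic parameters of the
Assaf population: a trait simulated at the published heritability should be
estimated back at that heritability (averaged over replicates), and a trait
pair simulated at a published genomic correlation should return it from the
bivariate fit.  Default problem sizes mirror the study population
(n = 1000 ewes, 2000 markers, 200 causal).
"""

from __future__ import annotations

import numpy as np

from .simulate import simulate_genotypes, simulate_phenotypes
from .traits import two_trait_architecture
from .qc_grm import compute_grm
from .varcomp import build_fixed_design, fit_univariate_reml, fit_bivariate_reml


def h2_recovery_study(h2: float, n_reps: int = 20, n: int = 1000,
                      m: int = 2000, n_causal: int = 200,
                      seed: int = 0) -> dict:
    """Mean univariate REML heritability over simulation replicates.

    Each replicate simulates a fresh population at the given true h2 (flock/
    parity/lactation fixed effects included), builds the VanRaden GRM and
    refits the mixed model; returns per-replicate estimates and their mean.
    """
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    estimates = []
    for ss in streams:
        s1, s2 = (int(x) for x in ss.generate_state(2) >> np.uint32(1))
        G = simulate_genotypes(n, m, maf_range=(0.05, 0.5), seed=s1)
        arch = two_trait_architecture("target", "companion", h2, 0.3, 0.0)
        pheno, _ = simulate_phenotypes(G, arch, n_causal=n_causal, seed=s2)
        grm = compute_grm(G)
        X = build_fixed_design(pheno)
        fit = fit_univariate_reml(pheno["target"].to_numpy(), X, grm)
        estimates.append(fit.h2)
    return {"true_h2": h2, "estimates": estimates,
            "mean": float(np.mean(estimates)), "n": n, "m": m,
            "n_reps": n_reps}


def rg_recovery_study(h2_1: float, h2_2: float, r_g: float,
                      n_reps: int = 30, n: int = 1000, m: int = 2000,
                      n_causal: int = 200, seed: int = 0) -> dict:
    """Mean bivariate REML genetic correlation over simulation replicates."""
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    estimates = []
    for ss in streams:
        s1, s2 = (int(x) for x in ss.generate_state(2) >> np.uint32(1))
        G = simulate_genotypes(n, m, maf_range=(0.05, 0.5), seed=s1)
        arch = two_trait_architecture("trait1", "trait2", h2_1, h2_2, r_g)
        pheno, _ = simulate_phenotypes(G, arch, n_causal=n_causal, seed=s2)
        grm = compute_grm(G)
        X = build_fixed_design(pheno)
        fit = fit_bivariate_reml(pheno["trait1"].to_numpy(),
                                 pheno["trait2"].to_numpy(), X, grm)
        estimates.append(fit.r_g)
    return {"true_rg": r_g, "h2": (h2_1, h2_2), "estimates": estimates,
            "mean": float(np.mean(estimates)), "n": n, "m": m,
            "n_reps": n_reps}
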