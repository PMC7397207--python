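"""Trait architecture for the 14 Assaf milk and cheese-making traits.

The default architecture carries, per trait: the published heritability and
phenotypic standard deviation, the trait group (milk vs cheese-making), and
whether the trait's GEBV scale is inverted when building the cheese-merit
z-score (traits where *smaller* is better: clotting/firming times, the
RCT/A60 ratio, somatic cell count and milk pH).  A 14x14 genomic correlation
matrix, bent to the nearest positive semi-definite matrix, defines the
multivariate genetic covariance used by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical trait order used by every results table.
TRAIT_ORDER = [
    "MY", "PP", "FP", "LP", "DE", "pH", "logSCC",
    "A30", "A60", "RCT", "logRCT_A60", "logK20", "ILCY", "ILDCY",
]

MILK_TRAITS = ["MY", "PP", "FP", "LP", "DE", "pH", "logSCC"]
CHEESE_TRAITS = ["A30", "A60", "RCT", "logRCT_A60", "logK20", "ILCY", "ILDCY"]

#: GEBV scale is flipped for these traits so that larger z means better
#: cheese-making merit (times, SCC and pH all harm coagulation when high).
INVERTED_TRAITS = ["logK20", "RCT", "logRCT_A60", "logSCC", "pH"]

# Published univariate estimates: trait -> (phenotypic mean, phenotypic SD,
# additive variance, heritability).
_UNIVARIATE = {
    "MY":         (2.8885, 1.0730, 0.1999, 0.2501),
    "PP":         (5.0535, 0.4639, 0.0546, 0.3433),
    "FP":         (5.5558, 1.0539, 0.0366, 0.0402),
    "LP":         (5.1072, 0.2396, 0.0091, 0.1802),
    "DE":         (16.6060, 1.2547, 0.2101, 0.1656),
    "pH":         (6.7276, 0.1336, 0.0049, 0.3706),
    "logSCC":     (2.1896, 0.6082, 0.0170, 0.0479),
    "A30":        (29.7650, 13.9750, 48.5430, 0.2845),
    "A60":        (40.9590, 11.2960, 19.0450, 0.1658),
    "RCT":        (29.1540, 10.5250, 19.1840, 0.2255),
    "logRCT_A60": (-0.1535, 0.2839, 0.0130, 0.1956),
    "logK20":     (0.5714, 0.2227, 0.0139, 0.3347),
    "ILCY":       (2.4938, 0.4136, 0.0519, 0.3366),
    "ILDCY":      (0.9724, 0.1758, 0.0065, 0.2593),
}

# Published genomic correlations, lower triangle, (row, col): r_g.
_GENOMIC_CORR = {
    ("RCT", "pH"): 0.63,
    ("logK20", "pH"): 0.57, ("logK20", "RCT"): 0.92,
    ("A30", "pH"): -0.44, ("A30", "RCT"): -0.97, ("A30", "logK20"): -0.86,
    ("A60", "pH"): -0.76, ("A60", "RCT"): -0.79, ("A60", "logK20"): -0.95,
    ("A60", "A30"): 0.91,
    ("ILCY", "pH"): -0.89, ("ILCY", "RCT"): 0.37, ("ILCY", "logK20"): 0.14,
    ("ILCY", "A30"): 0.11, ("ILCY", "A60"): 0.11,
    ("ILDCY", "pH"): -0.36, ("ILDCY", "RCT"): 0.23, ("ILDCY", "logK20"): -0.51,
    ("ILDCY", "A30"): 0.71, ("ILDCY", "A60"): 0.14, ("ILDCY", "ILCY"): 0.87,
    ("FP", "pH"): -0.50, ("FP", "RCT"): 0.36, ("FP", "logK20"): 0.66,
    ("FP", "A30"): -0.52, ("FP", "A60"): -0.99, ("FP", "ILCY"): 0.99,
    ("FP", "ILDCY"): 0.99,
    ("PP", "pH"): -0.11, ("PP", "RCT"): 0.30, ("PP", "logK20"): -0.11,
    ("PP", "A30"): 0.70, ("PP", "A60"): 0.16, ("PP", "ILCY"): 0.60,
    ("PP", "ILDCY"): 0.74, ("PP", "FP"): 0.65,
    ("LP", "pH"): -0.17, ("LP", "RCT"): -0.23, ("LP", "logK20"): -0.47,
    ("LP", "A30"): 0.19, ("LP", "A60"): 0.18, ("LP", "ILCY"): -0.40,
    ("LP", "ILDCY"): -0.65, ("LP", "FP"): -0.41, ("LP", "PP"): -0.24,
    ("DE", "pH"): -0.16, ("DE", "RCT"): 0.22, ("DE", "logK20"): 0.16,
    ("DE", "A30"): -0.20, ("DE", "A60"): 0.13, ("DE", "ILCY"): 0.79,
    ("DE", "ILDCY"): 0.99, ("DE", "FP"): 0.89, ("DE", "PP"): 0.84,
    ("DE", "LP"): -0.11,
    ("MY", "pH"): -0.27, ("MY", "RCT"): -0.28, ("MY", "logK20"): -0.22,
    ("MY", "A30"): -0.32, ("MY", "A60"): 0.26, ("MY", "ILCY"): -0.34,
    ("MY", "ILDCY"): -0.30, ("MY", "FP"): -0.42, ("MY", "PP"): -0.52,
    ("MY", "LP"): 0.92, ("MY", "DE"): -0.50,
    ("logSCC", "pH"): 0.58, ("logSCC", "RCT"): 0.12, ("logSCC", "logK20"): 0.26,
    ("logSCC", "A30"): 0.32, ("logSCC", "A60"): 0.83, ("logSCC", "ILCY"): 0.48,
    ("logSCC", "ILDCY"): 0.36, ("logSCC", "FP"): -0.75, ("logSCC", "PP"): 0.60,
    ("logSCC", "LP"): -0.73, ("logSCC", "DE"): -0.25, ("logSCC", "MY"): -0.97,
    ("logRCT_A60", "pH"): 0.70, ("logRCT_A60", "RCT"): 0.97,
    ("logRCT_A60", "logK20"): 0.96, ("logRCT_A60", "A30"): -0.99,
    ("logRCT_A60", "A60"): -0.92, ("logRCT_A60", "ILCY"): 0.19,
    ("logRCT_A60", "ILDCY"): 0.70, ("logRCT_A60", "FP"): 0.13,
    ("logRCT_A60", "PP"): 0.15, ("logRCT_A60", "LP"): -0.20,
    ("logRCT_A60", "DE"): 0.34, ("logRCT_A60", "MY"): -0.25,
    ("logRCT_A60", "logSCC"): 0.32,
}

# Fixed-effect structure of the mixed model: age-at-parturition x number of
# births (18 levels), flock test day (12), number of born lambs (2), plus
# days-in-milk as a covariate.
FIXED_EFFECT_LEVELS = {"AGE_NB": 18, "FTD": 12, "NBL": 2}
DIM_RANGE = (5.0, 210.0)


def bend_to_psd(corr: np.ndarray, min_eig: float = 1e-6, max_iter: int = 200,
                tol: float = 1e-10) -> tuple[np.ndarray, float]:
    """Bend a symmetric correlation matrix to the nearest PSD correlation.

    Eigenvalues below ``min_eig`` are clipped and the matrix re-normalized to
    unit diagonal; iterated because the renormalization can reintroduce tiny
    negative eigenvalues.  Returns the bent matrix and the Frobenius distance
    from the input.
    """
    C0 = np.asarray(corr, dtype=float)
    C = (C0 + C0.T) / 2.0
    for _ in range(max_iter):
        w, V = np.linalg.eigh(C)
        if w.min() >= min_eig - tol:
            break
        w = np.clip(w, min_eig, None)
        C = (V * w) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
        C = (C + C.T) / 2.0
    return C, float(np.linalg.norm(C - C0, "fro"))


@dataclass
class TraitArchitecture:
    """Genetic architecture of a set of quantitative traits.

    ``genetic_corr`` is the bent (PSD) genomic correlation matrix in the order
    of ``traits``; ``bending_adjustment`` records the Frobenius distance moved.
    """

    traits: list[str]
    h2: dict[str, float]
    pheno_sd: dict[str, float]
    pheno_mean: dict[str, float]
    genetic_corr: pd.DataFrame
    trait_group: dict[str, str]
    invert_for_zscore: dict[str, bool]
    fixed_effect_levels: dict[str, int] = field(
        default_factory=lambda: dict(FIXED_EFFECT_LEVELS))
    dim_range: tuple[float, float] = DIM_RANGE
    bending_adjustment: float = 0.0

    def __post_init__(self) -> None:
        for t in self.traits:
            if not 0.0 <= self.h2[t] <= 1.0:
                raise ValueError(f"h2 out of [0,1] for {t}")
            if self.pheno_sd[t] <= 0:
                raise ValueError(f"non-positive phenotypic SD for {t}")
        C = self.genetic_corr.loc[self.traits, self.traits].to_numpy()
        if np.abs(C).max() > 1.0 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("genetic correlation diagonal must be 1")
        w = np.linalg.eigvalsh((C + C.T) / 2.0)
        if w.min() < -1e-8:
            raise ValueError("genetic correlation matrix not PSD; bend it first")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def genetic_sd(self, trait: str) -> float:
        return float(np.sqrt(self.h2[trait]) * self.pheno_sd[trait])

    def residual_sd(self, trait: str) -> float:
        return float(np.sqrt(1.0 - self.h2[trait]) * self.pheno_sd[trait])

    def genetic_cov_matrix(self) -> np.ndarray:
        """Genetic covariance implied by h2, SDs and the correlation matrix."""
        s = np.array([self.genetic_sd(t) for t in self.traits])
        C = self.genetic_corr.loc[self.traits, self.traits].to_numpy()
        return C * np.outer(s, s)

    def cheese_traits(self) -> list[str]:
        return [t for t in self.traits if self.trait_group[t] == "cheese"]


def default_assaf_architecture() -> TraitArchitecture:
    """The 14-trait Assaf dairy-ewe architecture.

    Heritabilities, phenotypic SDs and means come from the published
    univariate estimates; the genomic correlation matrix is assembled from
    the published lower triangle and bent to the nearest PSD correlation.
    """
    k = len(TRAIT_ORDER)
    C = np.eye(k)
    idx = {t: i for i, t in enumerate(TRAIT_ORDER)}
    for (a, b), r in _GENOMIC_CORR.items():
        C[idx[a], idx[b]] = r
        C[idx[b], idx[a]] = r
    bent, adj = bend_to_psd(C)
    corr = pd.DataFrame(bent, index=TRAIT_ORDER, columns=TRAIT_ORDER)
    return TraitArchitecture(
        traits=list(TRAIT_ORDER),
        h2={t: _UNIVARIATE[t][3] for t in TRAIT_ORDER},
        pheno_sd={t: _UNIVARIATE[t][1] for t in TRAIT_ORDER},
        pheno_mean={t: _UNIVARIATE[t][0] for t in TRAIT_ORDER},
        genetic_corr=corr,
        trait_group={t: ("milk" if t in MILK_TRAITS else "cheese")
                     for t in TRAIT_ORDER},
        invert_for_zscore={t: t in INVERTED_TRAITS for t in TRAIT_ORDER},
        bending_adjustment=adj,
    )


def unbent_assaf_correlation() -> pd.DataFrame:
    """The genomic correlation matrix exactly as printed (possibly indefinite)."""
    k = len(TRAIT_ORDER)
    C = np.eye(k)
    idx = {t: i for i, t in enumerate(TRAIT_ORDER)}
    for (a, b), r in _GENOMIC_CORR.items():
        C[idx[a], idx[b]] = r
        C[idx[b], idx[a]] = r
    return pd.DataFrame(C, index=TRAIT_ORDER, columns=TRAIT_ORDER)


def two_trait_architecture(name1: str, name2: str, h2_1: float, h2_2: float,
                           r_g: float, sd1: float = 1.0, sd2: float = 1.0,
                           mean1: float = 0.0, mean2: float = 0.0,
                           group1: str = "milk", group2: str = "cheese",
                           ) -> TraitArchitecture:
    """Minimal two-trait architecture, handy for bivariate recovery studies."""
    traits = [name1, name2]
    corr = pd.DataFrame([[1.0, r_g], [r_g, 1.0]], index=traits, columns=traits)
    return TraitArchitecture(
        traits=traits,
        h2={name1: h2_1, name2: h2_2},
        pheno_sd={name1: sd1, name2: sd2},
        pheno_mean={name1: mean1, name2: mean2},
        genetic_corr=corr,
        trait_group={name1: group1, name2: group2},
        invert_for_zscore={name1: False, name2: False},
    )


def load_architecture(path) -> TraitArchitecture:
    """Read an architecture from a YAML file (same fields as the default)."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    traits = [str(t) for t in doc["traits"]]
    corr_rows = doc["genetic_corr"]
    C = pd.DataFrame(np.asarray(corr_rows, dtype=float),
                     index=traits, columns=traits)
    bent, adj = bend_to_psd(C.to_numpy())
    return TraitArchitecture(
        traits=traits,
        h2={t: float(doc["h2"][t]) for t in traits},
        pheno_sd={t: float(doc["pheno_sd"][t]) for t in traits},
        pheno_mean={t: float(doc.get("pheno_mean", {}).get(t, 0.0)) for t in traits},
        genetic_corr=pd.DataFrame(bent, index=traits, columns=traits),
        trait_group={t: doc["trait_group"][t] for t in traits},
        invert_for_zscore={t: bool(doc.get("invert_for_zscore", {}).get(t, False))
                           for t in traits},
        fixed_effect_levels=dict(doc.get("fixed_effect_levels",
                                         FIXED_EFFECT_LEVELS)),
        bending_adjustment=adj,
    )
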