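"""Core data containers shared across the pipeline.

The central object is :class:`GenotypeMatrix`, an individuals x SNPs allele
dosage matrix (0/1/2, NaN for missing) together with a SNP map giving
chromosome and 1-based physical position per marker.  All downstream stages
(QC, GRM, GWAS, stepwise selection) consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_MAP_COLUMNS = ["snp_id", "chrom", "pos", "allele_ref", "allele_alt"]


def validate_snp_map(snp_map: pd.DataFrame) -> None:
    """Check snp_id uniqueness and strictly increasing positions per chromosome."""
    missing = [c for c in SNP_MAP_COLUMNS if c not in snp_map.columns]
    if missing:
        raise ValueError(f"SNP map missing columns: {missing}")
    if snp_map["snp_id"].duplicated().any():
        raise ValueError("duplicate snp_id in SNP map")
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on chrom {chrom}")


@dataclass
class GenotypeMatrix:
    """Allele dosages for n individuals at m SNPs.

    Parameters
    ----------
    ids
        Individual identifiers, length n.
    snp_map
        DataFrame with columns snp_id, chrom, pos, allele_ref, allele_alt.
    dosage
        (n, m) float array with entries in {0, 1, 2} or NaN for missing.
    """

    ids: list[str]
    snp_map: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D")
        n, m = self.dosage.shape
        if len(self.ids) != n:
            raise ValueError("ids length does not match dosage rows")
        if len(self.snp_map) != m:
            raise ValueError("snp_map length does not match dosage columns")
        validate_snp_map(self.snp_map)
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        self.snp_map = self.snp_map.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snp_map["snp_id"].tolist()

    def allele_freq(self) -> np.ndarray:
        """Per-SNP alternate-allele frequency, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.mean(~np.isfinite(self.dosage), axis=0)

    def imputed_dosage(self) -> np.ndarray:
        """Dosage with missing calls filled by the per-SNP mean (GRM convention)."""
        X = self.dosage.copy()
        mask = ~np.isfinite(X)
        if mask.any():
            col_mean = np.nanmean(np.where(mask, np.nan, X), axis=0)
            col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
            X[mask] = np.broadcast_to(col_mean, X.shape)[mask]
        return X

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = self.snp_map.set_index("snp_id").index.get_indexer(snp_ids)
        if (idx < 0).any():
            unknown = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"unknown snp ids: {unknown[:5]}")
        order = np.sort(idx)
        return GenotypeMatrix(
            ids=list(self.ids),
            snp_map=self.snp_map.iloc[order].reset_index(drop=True),
            dosage=self.dosage[:, order],
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            ids=[self.ids[i] for i in keep],
            snp_map=self.snp_map.copy(),
            dosage=self.dosage[keep],
        )


@dataclass
class GeneAnnotation:
    """Gene intervals (1-based inclusive) with regulator class labels.

    Coordinates are 1-based inclusive on both ends, unlike canonical BED;
    the on-disk TSV uses the same convention and says so in its header.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = ["gene_id", "chrom", "start", "end", "class"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.table["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in annotation")
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("gene start > end")
        bad = set(self.table["class"].unique()) - {"TF", "CF", "other"}
        if bad:
            raise ValueError(f"unknown gene classes: {bad}")
        self.table = self.table.reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def regulators(self) -> set[str]:
        """TF plus CF gene ids ('transcription and co-transcription factors')."""
        mask = self.table["class"].isin(["TF", "CF"])
        return set(self.table.loc[mask, "gene_id"])
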