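"""Plain-text readers and writers for the pipeline's on-disk formats.

Formats: PLINK-text (.ped/.map), dosage TSV (individuals x SNPs, header of
snp_ids), phenotype/covariate TSV, GCTA-style GRM lower-triangle triplets
(i, j, n_snps, g_ij) with a companion .id file, annotation TSV (1-based
inclusive coordinates on both ends — unlike canonical BED; the header
comment says so), and QTL interval TSV in the same convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, GeneAnnotation
from .qc_grm import GRM


# ---------------------------------------------------------------------------
# genotypes

def write_dosage_tsv(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(G.dosage, index=G.ids, columns=G.snp_ids)
    df.index.name = "animal_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path, snp_map: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if snp_map is None:
        snp_map = pd.DataFrame({
            "snp_id": df.columns,
            "chrom": 1,
            "pos": np.arange(1, df.shape[1] + 1),
            "allele_ref": "A",
            "allele_alt": "B",
        })
    return GenotypeMatrix(ids=[str(i) for i in df.index], snp_map=snp_map,
                          dosage=df.to_numpy(dtype=float))


def write_plink_text(G: GenotypeMatrix, prefix) -> None:
    """PLINK .ped/.map pair.  Dosage 0/1/2 maps to AA/AB/BB; missing to 00."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for r in G.snp_map.itertuples():
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos}\n")
    code = {0.0: ("A", "A"), 1.0: ("A", "B"), 2.0: ("B", "B")}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, ind in enumerate(G.ids):
            alleles = []
            for x in G.dosage[i]:
                a, b = code.get(x, ("0", "0")) if np.isfinite(x) else ("0", "0")
                alleles.extend((a, b))
            fh.write("\t".join(["FAM", ind, "0", "0", "0", "-9"] + alleles) + "\n")


def read_plink_text(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    snp_map = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                          names=["chrom", "snp_id", "cm", "pos"])
    snp_map = snp_map[["snp_id", "chrom", "pos"]].assign(allele_ref="A",
                                                         allele_alt="B")
    ids, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            ids.append(parts[1])
            alleles = parts[6:]
            dos = []
            for j in range(0, len(alleles), 2):
                a, b = alleles[j], alleles[j + 1]
                if a == "0" or b == "0":
                    dos.append(np.nan)
                else:
                    dos.append(float((a == "B") + (b == "B")))
            rows.append(dos)
    return GenotypeMatrix(ids=ids, snp_map=snp_map,
                          dosage=np.asarray(rows, dtype=float))


# ---------------------------------------------------------------------------
# phenotypes / annotation / QTL

def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


ANNOTATION_HEADER = ("# 1-based inclusive coordinates on both ends "
                     "(not canonical BED half-open)\n")


def write_annotation(ann: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write(ANNOTATION_HEADER)
        ann.table[["chrom", "start", "end", "gene_id", "class"]].to_csv(
            fh, sep="\t", index=False)


def read_annotation(path) -> GeneAnnotation:
    tbl = pd.read_csv(path, sep="\t", comment="#")
    return GeneAnnotation(table=tbl[["gene_id", "chrom", "start", "end",
                                     "class"]])


def read_qtl_table(path) -> pd.DataFrame:
    """QTL intervals: chrom, start, end (1-based inclusive), trait, source_id."""
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# GRM triplets

def write_grm_triplets(grm: GRM, prefix) -> None:
    prefix = Path(prefix)
    with open(f"{prefix}.grm.id", "w") as fh:
        for ind in grm.ids:
            fh.write(f"FAM\t{ind}\n")
    with open(f"{prefix}.grm.txt", "w") as fh:
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.n_snps}\t"
                         f"{grm.matrix[i, j]:.10g}\n")


def read_grm_triplets(prefix) -> GRM:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id")]
    n = len(ids)
    K = np.zeros((n, n))
    n_snps = 0
    with open(f"{prefix}.grm.txt") as fh:
        for line in fh:
            i, j, m, g = line.split()
            i, j = int(i) - 1, int(j) - 1
            K[i, j] = K[j, i] = float(g)
            n_snps = int(m)
    return GRM(ids=ids, matrix=K, denominator=np.nan, n_snps=n_snps)
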