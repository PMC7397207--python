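"""End-to-end orchestration with deterministic seeding and a manifest.

``run_pipeline`` executes the stages (simulate, qc, grm, map_genes, varcomp,
gwas, pleiotropy, stepwise, network) in order, writing each stage's outputs
under a fresh run directory and recording parameters, derived seeds and a
sha256 content hash per output in ``manifest.json``.  Every random draw in
every stage traces to the master seed through ``numpy.random.SeedSequence``
spawning; a rerun with the same config reproduces the hashes of the
deterministic stages bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ovio
from .core import GenotypeMatrix, GeneAnnotation
from .traits import default_assaf_architecture, load_architecture
from .simulate import simulate_genotypes, simulate_annotation, simulate_phenotypes
from .qc_grm import qc_filter, compute_grm, relationship_edges, assign_snps_to_genes
from .varcomp import (build_fixed_design, fit_all_traits, gebv_table,
                      zscore_summary)
from .assoc import run_gwas, build_effect_matrix, pleiotropy_statistic
from .stepwise import stepwise_select, extract_subsets, random_baseline
from .network import (coassociation_matrix, pcit, build_network,
                      export_network, NETWORK_PRESETS)

_STAGES = ["simulate", "qc", "grm", "map_genes", "varcomp", "gwas",
           "pleiotropy", "stepwise", "network"]


@dataclass
class RunConfig:
    """Single configuration object driving the whole pipeline."""

    out_dir: str = "runs"
    seed: int = 0
    # simulate
    n_individuals: int = 300
    n_snps: int = 1500
    n_genes: int = 150
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    missing_rate: float = 0.0
    n_causal: int = 60
    non_coag_rate: float = 131 / 1039
    architecture: str = "assaf"       # or a YAML path
    # qc
    maf_min: float = 0.05
    hwe_p_min: float = 0.05
    # pedigromics
    edge_threshold: float = 0.20
    # gene window
    gene_window: int = 20000
    # stepwise (desk-scale defaults; published run used 50 / 1000)
    step_size: int = 10
    n_candidates: int = 100
    max_steps: int | None = None
    variance_threshold: float = 0.95
    baseline_reps: int = 20
    # network
    network_preset: str = "n374"
    stages: list[str] = field(default_factory=lambda: list(_STAGES))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        if not 0 <= cfg.maf_min < 0.5:
            raise ValueError("maf_min out of range")
        if not 0 <= cfg.hwe_p_min < 1:
            raise ValueError("hwe_p_min out of range")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, run_name: str | None = None) -> Path:
    """Execute the configured stages; returns the run directory."""
    base = Path(config.out_dir)
    name = run_name or time.strftime("run-%Y%m%d-%H%M%S")
    run_dir = base / name
    if run_dir.exists():
        raise FileExistsError(f"run directory exists: {run_dir}")
    run_dir.mkdir(parents=True)

    seeds = np.random.SeedSequence(config.seed).spawn(len(_STAGES))
    stage_seed = {s: int(seeds[i].generate_state(1)[0] & 0x7FFFFFFF)
                  for i, s in enumerate(_STAGES)}
    manifest = {"config": asdict(config), "stage_seeds": stage_seed,
                "stages": {}, "outputs": {}}

    state: dict = {}
    failed = False
    for stage in _STAGES:
        if stage not in config.stages:
            manifest["stages"][stage] = "skipped"
            continue
        if failed:
            manifest["stages"][stage] = "skipped_downstream_failure"
            continue
        try:
            _run_stage(stage, config, stage_seed[stage], run_dir, state)
            manifest["stages"][stage] = "ok"
        except Exception as exc:  # noqa: BLE001 - manifest records the failure
            manifest["stages"][stage] = f"failed: {exc}"
            failed = True
    for p in sorted(run_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(run_dir))] = _sha256(p)
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return run_dir


def _architecture(config: RunConfig):
    if config.architecture == "assaf":
        return default_assaf_architecture()
    return load_architecture(config.architecture)


def _run_stage(stage: str, cfg: RunConfig, seed: int, run_dir: Path,
               state: dict) -> None:
    arch = state.setdefault("arch", _architecture(cfg))
    if stage == "simulate":
        G = simulate_genotypes(cfg.n_individuals, cfg.n_snps,
                               maf_range=tuple(cfg.maf_range),
                               ld_rho=cfg.ld_rho,
                               missing_rate=cfg.missing_rate, seed=seed)
        chrom_len = [int(G.snp_map[G.snp_map.chrom == c]["pos"].max()) + 25000
                     for c in sorted(G.snp_map["chrom"].unique())]
        ann = simulate_annotation(cfg.n_genes, chrom_len, seed=seed + 1)
        pheno, truth = simulate_phenotypes(G, arch, n_causal=cfg.n_causal,
                                           non_coag_rate=cfg.non_coag_rate,
                                           seed=seed + 2)
        state.update(G=G, ann=ann, pheno=pheno, truth=truth)
        ovio.write_dosage_tsv(G, run_dir / "genotypes.tsv")
        ovio.write_plink_text(G, run_dir / "genotypes")
        ovio.write_annotation(ann, run_dir / "annotation.tsv")
        ovio.write_phenotypes(pheno, run_dir / "phenotypes.tsv")
        truth.tbv.to_csv(run_dir / "true_breeding_values.tsv", sep="\t")
        truth.effects.to_csv(run_dir / "true_effects.tsv", sep="\t")
    elif stage == "qc":
        G_qc, report = qc_filter(state["G"], maf_min=cfg.maf_min,
                                 hwe_p_min=cfg.hwe_p_min)
        if G_qc.n_snps == 0:
            raise RuntimeError("empty SNP set after QC")
        state["G_qc"] = G_qc
        report.to_csv(run_dir / "qc_report.tsv", sep="\t", index=False)
    elif stage == "grm":
        grm = compute_grm(state["G_qc"])
        state["grm"] = grm
        ovio.write_grm_triplets(grm, run_dir / "grm")
        edges = relationship_edges(grm, threshold=cfg.edge_threshold)
        edges.to_csv(run_dir / "pedigromics_edges.tsv", sep="\t", index=False)
    elif stage == "map_genes":
        sg = assign_snps_to_genes(state["G_qc"].snp_map, state["ann"],
                                  window=cfg.gene_window)
        state["snp_gene_map"] = sg
        sg.to_csv(run_dir / "snp_gene_map.tsv", sep="\t", index=False)
    elif stage == "varcomp":
        X = build_fixed_design(state["pheno"])
        state["X"] = X
        fits = fit_all_traits(state["pheno"], arch.traits, X, state["grm"])
        state["fits"] = fits
        rows = [{"trait": t, "sigma_a2": f.sigma_a2, "se_a2": f.se_sigma_a2,
                 "sigma_e2": f.sigma_e2, "se_e2": f.se_sigma_e2,
                 "h2": f.h2, "se_h2": f.se_h2, "loglik": f.loglik,
                 "converged": f.converged}
                for t, f in fits.items()]
        pd.DataFrame(rows).to_csv(run_dir / "varcomp.tsv", sep="\t",
                                  index=False)
        gebv = gebv_table(state["pheno"], arch.traits, X, state["grm"], fits)
        gebv.to_csv(run_dir / "gebv.tsv", sep="\t")
        z = zscore_summary(gebv, arch)
        z.to_frame().to_csv(run_dir / "zscore.tsv", sep="\t")
        state["gebv"] = gebv
    elif stage == "gwas":
        res = run_gwas(state["G_qc"], state["pheno"], arch.traits,
                       state["X"], state["grm"], fits=state["fits"])
        state["gwas"] = res
        for t, df in res.items():
            safe = t.replace("/", "_")
            df.to_csv(run_dir / f"gwas_{safe}.tsv", sep="\t", index=False)
    elif stage == "pleiotropy":
        tmat, pmat = build_effect_matrix(state["gwas"], state["snp_gene_map"],
                                         arch.traits)
        state["tmat"], state["pmat"] = tmat, pmat
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pleio = pleiotropy_statistic(tmat)
        state["pleio"] = pleio
        tmat.to_csv(run_dir / "effect_matrix_t.tsv", sep="\t")
        pmat.to_csv(run_dir / "effect_matrix_p.tsv", sep="\t")
        pleio.to_csv(run_dir / "pleiotropy.tsv", sep="\t")
    elif stage == "stepwise":
        pool = state["snp_gene_map"]["snp_id"].tolist()
        trace = stepwise_select(pool, state["G_qc"], state["pheno"],
                                arch.traits, state["X"],
                                step_size=cfg.step_size,
                                n_candidates=cfg.n_candidates, seed=seed,
                                max_steps=cfg.max_steps)
        state["trace"] = trace
        trace.write(run_dir / "stepwise")
        subsets = extract_subsets(trace, threshold=cfg.variance_threshold)
        state["subsets"] = subsets
        with open(run_dir / "stepwise" / "subsets.json", "w") as fh:
            json.dump({
                "subset_95_step": subsets.subset_95_step,
                "subset_95_size": (len(subsets.subset_95_snps)
                                   if subsets.subset_95_snps else None),
                "subset_max_step": subsets.subset_max_step,
                "subset_max_size": len(subsets.subset_max_snps),
            }, fh, indent=2)
        if cfg.baseline_reps > 0:
            base = random_baseline(pool, len(subsets.subset_max_snps),
                                   state["G_qc"], state["pheno"], arch.traits,
                                   state["X"], trace.full_sigma_a2,
                                   n_rep=cfg.baseline_reps, seed=seed + 1)
            base.to_csv(run_dir / "stepwise" / "random_baseline.tsv",
                        sep="\t", index=False)
    elif stage == "network":
        min_partners, display = NETWORK_PRESETS[cfg.network_preset]
        subset = state["subsets"].subset_max_snps
        genes = set(state["snp_gene_map"]
                    .set_index("snp_id").loc[
                        [s for s in subset
                         if s in set(state["snp_gene_map"]["snp_id"])],
                        "gene_id"])
        tmat = state["tmat"].loc[[g for g in state["tmat"].index
                                  if g in genes]]
        if len(tmat) < 3:
            tmat = state["tmat"]
        C, _ = coassociation_matrix(tmat)
        mask = pcit(C)
        net = build_network(mask, C, state["pleio"],
                            state["pmat"].loc[C.index], state["ann"],
                            arch.trait_group,
                            min_regulator_partners=min_partners,
                            edge_display_min=display)
        export_network(net, run_dir / "network")
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage}")
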