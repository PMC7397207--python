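"""PCIT co-association network inference, filtering and export.

Genes are nodes; an edge is the Pearson correlation between two genes'
signed t-value profiles across the 14 traits.  PCIT examines every trio
(x, y, z): the first-order partial correlations are computed, a trio
tolerance ``eps = mean of the three partial/marginal ratios`` is formed, and
the edge (x, y) is rejected if for some z both |r_xy| <= |eps * r_xz| and
|r_xy| <= |eps * r_yz|.  Edges never rejected by any trio are significant.

The final network keeps genes that (i) are significantly co-associated with
at least ``min_regulator_partners`` transcription/co-transcription factors
and (ii) have a nominal GWAS p < 0.05 for at least one trait; displayed
edges additionally satisfy |r| >= ``edge_display_min`` (0.80 and 0.95 for
the two published presets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import GeneAnnotation

#: Published preset -> (min TF+CF partners, edge display floor).
NETWORK_PRESETS = {"n374": (5, 0.80), "n4586": (50, 0.95)}


# ---------------------------------------------------------------------------
# correlation + PCIT

def coassociation_matrix(t_matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Gene-gene Pearson correlations of t-value rows across traits.

    Rows with zero variance get all correlations set to 0 and are returned
    in the flagged list.
    """
    if t_matrix.shape[1] < 3:
        raise ValueError("need at least 3 traits")
    T = t_matrix.to_numpy(dtype=float)
    sd = T.std(axis=1)
    flagged = [g for g, s in zip(t_matrix.index, sd) if s == 0]
    safe = np.where(sd[:, None] > 0, T, 0.0)
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(safe)
    C = np.nan_to_num(C, nan=0.0)
    zero = sd == 0
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    return pd.DataFrame(C, index=t_matrix.index, columns=t_matrix.index), flagged


def _clamp(C: np.ndarray) -> np.ndarray:
    lim = 1.0 - 1e-12
    off = ~np.eye(C.shape[0], dtype=bool)
    if np.any(np.abs(C[off]) >= lim):
        warnings.warn("off-diagonal |r| ~ 1 clamped before partials",
                      stacklevel=3)
        C = C.copy()
        C[off] = np.clip(C[off], -lim, lim)
    return C


def pcit_naive(C: np.ndarray) -> np.ndarray:
    """Reference O(n^3) triple-loop PCIT (oracle for the blocked version)."""
    C = _clamp(np.asarray(C, dtype=float))
    n = C.shape[0]
    if n < 3:
        raise ValueError("PCIT needs at least 3 genes")
    keep = np.ones((n, n), dtype=bool)
    np.fill_diagonal(keep, False)

    def partial(a, b, c):
        num = C[a, b] - C[a, c] * C[b, c]
        den = np.sqrt((1 - C[a, c] ** 2) * (1 - C[b, c] ** 2))
        return num / den

    def ratio(p, r):
        return p / r if r != 0 else 0.0

    for x in range(n):
        for y in range(x + 1, n):
            for z in range(n):
                if z == x or z == y:
                    continue
                rxy_z = partial(x, y, z)
                rxz_y = partial(x, z, y)
                ryz_x = partial(y, z, x)
                eps = (ratio(rxy_z, C[x, y]) + ratio(rxz_y, C[x, z])
                       + ratio(ryz_x, C[y, z])) / 3.0
                if (abs(C[x, y]) <= abs(eps * C[x, z])
                        and abs(C[x, y]) <= abs(eps * C[y, z])):
                    keep[x, y] = keep[y, x] = False
                    break
    return keep


def pcit(C: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Blocked PCIT significance mask, identical in output to ``pcit_naive``.

    Vectorized per conditioning gene z: all pairwise first-order partials
    given z are formed with O(n^2) array operations.
    """
    index = C.index if isinstance(C, pd.DataFrame) else None
    C = _clamp(np.asarray(C, dtype=float))
    n = C.shape[0]
    if n < 3:
        raise ValueError("PCIT needs at least 3 genes")
    keep = np.ones((n, n), dtype=bool)
    np.fill_diagonal(keep, False)
    s = np.sqrt(1.0 - C**2)  # s[i,j] = sqrt(1 - r_ij^2)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_C = lambda P, R: np.where(R != 0, P / np.where(R != 0, R, 1.0), 0.0)
        for z in range(n):
            cz = C[:, z]
            sz = s[:, z]
            # partial of (x,y) given z
            P_xy = (C - np.outer(cz, cz)) / np.outer(sz, sz)
            # partial of (x,z) given y: rows x, cols y
            P_xz = (cz[:, None] - C * cz[None, :]) / (s * sz[None, :])
            # partial of (y,z) given x = P_xz with roles swapped
            P_yz = P_xz.T
            eps = (ratio_C(P_xy, C)
                   + ratio_C(P_xz, cz[:, None] * np.ones((1, n)))
                   + ratio_C(P_yz, cz[None, :] * np.ones((n, 1)))) / 3.0
            reject = ((np.abs(C) <= np.abs(eps * cz[:, None]))
                      & (np.abs(C) <= np.abs(eps * cz[None, :])))
            reject[z, :] = False
            reject[:, z] = False
            np.fill_diagonal(reject, False)
            keep &= ~reject
    np.fill_diagonal(keep, False)
    if index is not None:
        return keep
    return keep


# ---------------------------------------------------------------------------
# trait-group classification

def classify_trait_group(p_row: pd.Series, trait_group: dict[str, str],
                         alpha: float = 0.05) -> str:
    """milk / cheese / both, from which trait groups reach nominal
    significance; genes significant nowhere are filtered upstream."""
    sig = [t for t, p in p_row.items() if p < alpha]
    groups = {trait_group[t] for t in sig}
    if groups == {"milk"}:
        return "milk"
    if groups == {"cheese"}:
        return "cheese"
    if groups:
        return "both"
    return "none"


# ---------------------------------------------------------------------------
# network assembly

@dataclass
class CoassociationNetwork:
    graph: nx.Graph
    nodes: pd.DataFrame
    edges: pd.DataFrame                   # displayed gene-gene + gene-trait
    all_significant_edges: pd.DataFrame   # pre-display-threshold edge set
    params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def build_network(mask: np.ndarray, C: pd.DataFrame,
                  pleiotropy: pd.DataFrame, p_matrix: pd.DataFrame,
                  ann: GeneAnnotation, trait_group: dict[str, str],
                  min_regulator_partners: int = 5,
                  edge_display_min: float = 0.80,
                  gwas_p: float = 0.05,
                  regulators_must_qualify: bool = True,
                  ) -> CoassociationNetwork:
    """Assemble the filtered co-association network.

    Nodes are genes significantly co-associated with at least
    ``min_regulator_partners`` TF+CF genes AND nominally GWAS-significant
    for at least one trait.  Gene-gene edges are the PCIT-significant pairs
    among kept nodes with |r| >= ``edge_display_min`` (the full significant
    edge set among kept nodes is also returned); gene-trait edges connect a
    gene to every trait with p < ``gwas_p``.
    """
    genes = list(C.index)
    regulators = ann.regulators()
    if not regulators:
        warnings.warn("no TF/CF genes in the annotation: empty network",
                      stacklevel=2)
    cls = dict(zip(ann.table["gene_id"], ann.table["class"]))
    reg_idx = np.array([g in regulators for g in genes])
    partner_counts = mask[:, reg_idx].sum(axis=1)
    min_p = p_matrix.min(axis=1)

    keep = []
    for i, g in enumerate(genes):
        n_partners = partner_counts[i]
        if g in regulators and not regulators_must_qualify:
            co_ok = True
        else:
            co_ok = n_partners >= min_regulator_partners
        gwas_ok = min_p.get(g, 1.0) < gwas_p
        if co_ok and gwas_ok:
            keep.append(i)

    kept_genes = [genes[i] for i in keep]
    node_rows = []
    for i, g in zip(keep, kept_genes):
        node_rows.append({
            "gene_id": g,
            "class": cls.get(g, "other"),
            "trait_group": classify_trait_group(p_matrix.loc[g], trait_group,
                                                alpha=gwas_p),
            "mt": float(pleiotropy["mt"].get(g, np.nan)),
            "min_p": float(min_p.get(g, np.nan)),
            "n_regulator_partners": int(partner_counts[i]),
        })
    nodes = pd.DataFrame(node_rows,
                         columns=["gene_id", "class", "trait_group", "mt",
                                  "min_p", "n_regulator_partners"])

    Cv = C.to_numpy()
    sig_rows, disp_rows = [], []
    for a_pos, i in enumerate(keep):
        for j in keep[a_pos + 1:]:
            if mask[i, j]:
                r = float(Cv[i, j])
                row = {"source": genes[i], "target": genes[j], "r": r,
                       "sign": "+" if r >= 0 else "-", "type": "coassoc"}
                sig_rows.append(row)
                if abs(r) >= edge_display_min:
                    disp_rows.append(row)
    cols = ["source", "target", "r", "sign", "type"]
    sig_edges = pd.DataFrame(sig_rows, columns=cols)
    edges = pd.DataFrame(disp_rows, columns=cols)

    gt_rows = []
    for g in kept_genes:
        for t, p in p_matrix.loc[g].items():
            if p < gwas_p:
                gt_rows.append({"source": g, "target": t, "r": np.nan,
                                "sign": "", "type": "gene_trait", "p": float(p)})
    gt_edges = pd.DataFrame(gt_rows, columns=cols + ["p"])
    edges = pd.concat([edges.assign(p=np.nan), gt_edges], ignore_index=True)

    graph = nx.Graph()
    for row in node_rows:
        graph.add_node(row["gene_id"], kind="gene", **{
            k: row[k] for k in ("class", "trait_group", "mt", "min_p")})
    for t in p_matrix.columns:
        graph.add_node(t, kind="trait")
    for _, e in edges.iterrows():
        attrs = {"type": e["type"], "sign": e["sign"]}
        if np.isfinite(e["r"]):
            attrs["r"] = float(e["r"])
        if np.isfinite(e.get("p", np.nan)):
            attrs["p"] = float(e["p"])
        graph.add_edge(e["source"], e["target"], **attrs)
    graph.remove_nodes_from([t for t in p_matrix.columns
                             if graph.degree(t) == 0])

    return CoassociationNetwork(
        graph=graph, nodes=nodes, edges=edges,
        all_significant_edges=sig_edges,
        params={"min_regulator_partners": min_regulator_partners,
                "edge_display_min": edge_display_min, "gwas_p": gwas_p,
                "regulators_must_qualify": regulators_must_qualify},
    )


# ---------------------------------------------------------------------------
# QTL overlap

def qtl_overlap(ann: GeneAnnotation, qtl: pd.DataFrame,
                window: int = 20000) -> pd.DataFrame:
    """Gene-to-QTL hits: the gene span +/- window intersects the QTL
    interval (all coordinates 1-based inclusive, closed intervals)."""
    required = {"chrom", "start", "end"}
    if not required <= set(qtl.columns):
        raise ValueError(f"QTL table needs columns {required}")
    rows = []
    for _, g in ann.table.iterrows():
        gs, ge = g["start"] - window, g["end"] + window
        hits = qtl[(qtl["chrom"] == g["chrom"])
                   & (qtl["start"] <= ge) & (qtl["end"] >= gs)]
        for _, q in hits.iterrows():
            rows.append({
                "gene_id": g["gene_id"],
                "qtl_id": q.get("source_id", f"{q['chrom']}:{q['start']}-{q['end']}"),
                "qtl_trait": q.get("trait", ""),
                "chrom": g["chrom"],
            })
    return pd.DataFrame(rows, columns=["gene_id", "qtl_id", "qtl_trait",
                                       "chrom"])


# ---------------------------------------------------------------------------
# export / import

def export_network(net: CoassociationNetwork, directory,
                   prefix: str = "network") -> dict[str, Path]:
    """Write GraphML (Cytoscape-ingestible) plus node/edge TSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "graphml": directory / f"{prefix}.graphml",
        "nodes": directory / f"{prefix}_nodes.tsv",
        "edges": directory / f"{prefix}_edges.tsv",
        "all_edges": directory / f"{prefix}_significant_edges.tsv",
    }
    g = nx.Graph()
    for node, data in net.graph.nodes(data=True):
        g.add_node(node, **{k: v for k, v in data.items()
                            if v is not None and not _is_nan(v)})
    for u, v, data in net.graph.edges(data=True):
        g.add_edge(u, v, **{k: w for k, w in data.items()
                            if w is not None and not _is_nan(w)})
    nx.write_graphml(g, paths["graphml"])
    net.nodes.to_csv(paths["nodes"], sep="\t", index=False)
    net.edges.to_csv(paths["edges"], sep="\t", index=False)
    net.all_significant_edges.to_csv(paths["all_edges"], sep="\t", index=False)
    return paths


def _is_nan(v) -> bool:
    return isinstance(v, float) and np.isnan(v)


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
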