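"""Shared helper: build a small filtered co-association network."""

import numpy as np
import pandas as pd

from ovinet.core import GeneAnnotation
from ovinet.network import coassociation_matrix, build_network


def make_network(n_genes=10, n_traits=6, n_reg=3, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    traits = [f"t{j}" for j in range(n_traits)]
    T = pd.DataFrame(rng.standard_normal((n_genes, n_traits)),
                     index=genes, columns=traits)
    C, _ = coassociation_matrix(T)
    mask = np.ones((n_genes, n_genes), dtype=bool)
    np.fill_diagonal(mask, False)
    pleio = pd.DataFrame({"mt": rng.uniform(5, 50, n_genes)}, index=genes)
    P = pd.DataFrame(rng.uniform(0, 1, (n_genes, n_traits)),
                     index=genes, columns=traits)
    P.iloc[:, 0] = 0.01
    ann = GeneAnnotation(table=pd.DataFrame({
        "gene_id": genes, "chrom": 1,
        "start": np.arange(n_genes) * 10000 + 1,
        "end": np.arange(n_genes) * 10000 + 5000,
        "class": ["TF"] * n_reg + ["other"] * (n_genes - n_reg)}))
    groups = {t: ("milk" if j < n_traits // 2 else "cheese")
              for j, t in enumerate(traits)}
    return build_network(mask, C, pleio, P, ann, groups,
                         min_regulator_partners=1, edge_display_min=0.0)
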