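import numpy as np
import pandas as pd
import pytest

import ovinet
from ovinet.traits import two_trait_architecture


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study shared by read-only tests: n=200 ewes,
    600 SNPs, annotation, two moderately heritable correlated traits."""
    G = ovinet.simulate_genotypes(200, 600, seed=7)
    chrom_len = [int(G.snp_map[G.snp_map.chrom == c]["pos"].max()) + 25000
                 for c in sorted(G.snp_map["chrom"].unique())]
    ann = ovinet.simulate_annotation(60, chrom_len, seed=8)
    arch = two_trait_architecture("T1", "T2", 0.4, 0.3, 0.5)
    pheno, truth = ovinet.simulate_phenotypes(G, arch, n_causal=60, seed=9)
    grm = ovinet.compute_grm(G)
    X = ovinet.build_fixed_design(pheno)
    return {"G": G, "ann": ann, "arch": arch, "pheno": pheno,
            "truth": truth, "grm": grm, "X": X}


@pytest.fixture(scope="session")
def assaf_arch():
    return ovinet.default_assaf_architecture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
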