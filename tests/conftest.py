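import numpy as np
import pandas as pd
import pytest

from gsel.genotypes import MISSING, GenotypeMatrix
from gsel.simulate import SimConfig, simulate_genotypes, simulate_phenotypes


def make_geno(dosages, chrom=None, pos=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain list/array of dosages."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else np.arange(m, dtype=np.int64),
            "a1": "A",
            "a2": "B",
        }
    )
    ids = np.array([f"a{i}" for i in range(n)], dtype=object)
    return GenotypeMatrix(d, ids, markers)


@pytest.fixture
def tiny_geno():
    # columns: [0,1,2,1] polymorphic; [0,0,0,0] monomorphic; [0,NA,2,1] missing
    return make_geno(
        [
            [0, 0, 0],
            [1, 0, MISSING],
            [2, 0, 2],
            [1, 0, 1],
        ]
    )


@pytest.fixture(scope="session")
def f2_population():
    """Small F2 population with a 0.5-heritability polygenic trait."""
    cfg = SimConfig(
        n_animals=300, n_markers=600, seed=11, mode="f2_cross",
        target_h2=0.5, n_qtl=20,
    )
    geno, _ = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(geno, cfg)
    return geno, pheno, truth
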