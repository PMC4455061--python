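import numpy as np
import pandas as pd
import pytest

from riboflow.containers import CountMatrix
from riboflow.sim import SimConfig, simulate_counts


def make_counts(values, strains, assay="RNA1", animals=None, genes=None):
    """Small CountMatrix builder for fixtures."""
    values = np.asarray(values)
    n_g, n_s = values.shape
    genes = genes or [f"g{i}" for i in range(n_g)]
    cols = [f"{assay}_s{i}" for i in range(n_s)]
    animals = animals or [f"a{i}" for i in range(n_s)]
    meta = pd.DataFrame(
        {"strain": strains, "tissue": "heart", "animal": animals, "assay": assay},
        index=pd.Index(cols, name="sample"),
    )
    return CountMatrix(pd.DataFrame(values, index=genes, columns=cols), meta)


@pytest.fixture(scope="session")
def small_study():
    """A 1,200-gene synthetic study shared by read-only tests."""
    cfg = SimConfig(n_genes=1200, seed=42)
    rna1, rna2, ribo, truth = simulate_counts(cfg)
    return {"config": cfg, "rna1": rna1, "rna2": rna2, "ribo": ribo, "truth": truth}
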