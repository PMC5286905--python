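import numpy as np
import pandas as pd
import pytest

import kinblend as kb


@pytest.fixture(scope="session")
def small_sim() -> kb.SimDataset:
    """A 300-individual population (60 founders + two offspring cohorts)
    with genotypes, nuisance effects, and three traits."""
    cfg = kb.SimConfig(
        n_founders=60, n_generations=2, n_sires=10, n_dams=30,
        offspring_per_mating=4, n_snps=400, n_qtl=50, seed=2024,
    )
    return kb.simulate(cfg)


@pytest.fixture(scope="session")
def small_A(small_sim) -> kb.KinshipMatrix:
    return kb.build_A(small_sim.pedigree)


@pytest.fixture(scope="session")
def small_GV(small_sim) -> kb.KinshipMatrix:
    geno = kb.impute_naive(kb.filter_snps(small_sim.genotypes))
    return kb.build_G_vanraden(geno)


@pytest.fixture(scope="session")
def small_corrected(small_sim) -> pd.DataFrame:
    spec = kb.CorrectionSpec(factors=("sex", "hatch_week", "pen"))
    return kb.precorrect(small_sim.phenotype_frame(), spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)


@pytest.fixture()
def sib_pedigree() -> kb.Pedigree:
    """Two unrelated founders with two full-sib offspring."""
    return kb.Pedigree.from_records(
        [("f1", None, None), ("f2", None, None),
         ("c1", "f1", "f2"), ("c2", "f1", "f2")]
    )
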