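"""Shared fixtures: small pedigrees and a mid-sized simulated trial."""

import warnings

import numpy as np
import pandas as pd
import pytest

from pinedrought.containers import GeneticArchitecture, Pedigree
from pinedrought.kinship import g_matrix, qc_genotypes, tune_g
from pinedrought.simulate import (
    simulate_breeding_values,
    simulate_genotypes,
    simulate_pedigree,
)


@pytest.fixture(autouse=True)
def _quiet_design_warnings():
    """The study-scale mating design intentionally overfills the usage band."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="crosses_per_parent", category=UserWarning
        )
        yield


@pytest.fixture
def trio_pedigree() -> Pedigree:
    """Two founders and three full sibs."""
    return simulate_pedigree(2, 1, (3, 3), (1, 1), seed=11)


@pytest.fixture(scope="session")
def small_trial():
    """Mid-sized trial (~300 progeny, 2k SNPs) with h2 = 0.5 phenotypes."""
    ped = simulate_pedigree(20, 60, (5, 5), (4, 8), seed=5)
    geno = simulate_genotypes(ped, 2000, (0.05, 0.5), 0.0, seed=6)
    arch = GeneticArchitecture.from_targets(["t"], [0.5], n_causal=400)
    truth = simulate_breeding_values(geno, arch, seed=7)
    G = tune_g(g_matrix(qc_genotypes(geno, 0.4, 0.01)), 0.01)
    rng = np.random.default_rng(8)
    y = pd.Series(
        truth.breeding_values[:, 0]
        + rng.normal(0.0, np.sqrt(arch.Sigma_e[0, 0]), len(geno.ids)),
        index=geno.ids,
    )
    return {"ped": ped, "geno": geno, "truth": truth, "G": G, "y": y, "arch": arch}
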