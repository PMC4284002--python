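"""Shared synthetic fixtures.

Everything is generated programmatically with fixed seeds; the session-scoped
panel is reused across modules to keep the suite fast.
"""

import numpy as np
import pandas as pd
import pytest

from grasspred import (PopulationModel, TraitModel, estimate_blups,
                       ibs_kinship, simulate_read_support,
                       simulate_structured_genotypes, simulate_trait)
from grasspred.genotypes import GenotypeTable, LOCUS_COLUMNS


def make_table(dosage, n_alleles=None, qual=None, **extra) -> GenotypeTable:
    """Build a GenotypeTable from a raw dosage array (rows = individuals)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    loci = pd.DataFrame({
        "locus": [f"L{j + 1}" for j in range(m)],
        "chrom": "1",
        "pos": np.arange(1, m + 1) * 10,
        "ref": "A",
        "alt": "C",
        "n_alleles": n_alleles if n_alleles is not None else [2] * m,
        "qual": qual if qual is not None else [np.nan] * m,
    }, columns=LOCUS_COLUMNS)
    return GenotypeTable(ids=[f"I{i + 1}" for i in range(n)], loci=loci,
                         dosage=dosage, **extra)


@pytest.fixture(scope="session")
def panel():
    """Structured two-subpopulation panel with read support."""
    model = PopulationModel(n_individuals=120, n_loci=800, n_subpops=2,
                            fst=0.05, missing_rate=0.03, seed=11)
    gt = simulate_structured_genotypes(model)
    return simulate_read_support(gt, mean_depth=30.0, error_rate=0.01, seed=12)


@pytest.fixture(scope="session")
def panel_trait(panel):
    """A moderately heritable polygenic trait on the panel, with truth."""
    return simulate_trait(panel, TraitModel(h2=0.6, n_qtl=30, seed=7))


@pytest.fixture(scope="session")
def panel_blups(panel_trait):
    return estimate_blups(panel_trait.observations)


@pytest.fixture(scope="session")
def panel_kinship(panel):
    return ibs_kinship(panel)
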