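import numpy as np
import pandas as pd
import pytest

from codonmutsel import CodonFamilyTable, GenomeCounts, MutSelParams
from codonmutsel.simulate import make_truth, simulate_counts


@pytest.fixture(scope="session")
def table():
    return CodonFamilyTable.standard()


@pytest.fixture(scope="session")
def alt_table():
    return CodonFamilyTable.alternative_yeast()


@pytest.fixture(scope="session")
def make_genome():
    """Factory: simulate a genome's codon counts with known truth."""

    def _make(n_genes=100, n_exogenous=0, length=200, sigma_phi=1.5, seed=0, params=None):
        truth = make_truth(
            n_genes=n_genes,
            n_exogenous=n_exogenous,
            length=length,
            sigma_phi=sigma_phi,
            seed=seed,
            params=params,
        )
        return truth, simulate_counts(truth)

    return _make


@pytest.fixture()
def two_codon_params(table):
    """Deterministic recentered parameter set with structure in every family."""
    rng = np.random.default_rng(42)
    dm = rng.normal(0, 0.6, table.n_codons)
    de = rng.normal(0, 0.4, table.n_codons)
    return MutSelParams(table, dm, de, "test").recenter()


def pair_params(table, dm_pairs, de_pairs=None):
    """Params whose two-codon families get given (ΔM₁, ΔM₂) values; others 0."""
    dm = np.zeros(table.n_codons)
    de = np.zeros(table.n_codons)
    for fam, vals in dm_pairs.items():
        dm[table.slice(fam)] = vals
    for fam, vals in (de_pairs or {}).items():
        de[table.slice(fam)] = vals
    return MutSelParams(table, dm, de)
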