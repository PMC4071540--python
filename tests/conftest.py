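import logging

import numpy as np
import pytest

from mimiclocus.core_io import GenotypeMatrix, VariantSite, make_morph_table
from mimiclocus.simulate import SimConfig, simulate_population

logging.getLogger("mimiclocus").setLevel(logging.ERROR)

HIERARCHY = ("hippocoonides", "cenea", "lamborni", "planemoides", "poultoni")


def make_matrix(dosage, chrom="chr1", locus="locA", individuals=None, positions=None):
    """Small GenotypeMatrix from a (n_ind, n_sites) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_ind, n_sites = dosage.shape
    individuals = individuals or [f"i{k}" for k in range(n_ind)]
    positions = positions or list(range(n_sites))
    sites = [
        VariantSite(chrom, positions[j], locus, "A", "G") for j in range(n_sites)
    ]
    return GenotypeMatrix(sites=sites, individuals=individuals, dosage=dosage)


@pytest.fixture(scope="session")
def default_population():
    """One default synthetic population shared across tests (seed 0)."""
    return simulate_population(SimConfig(seed=0))


@pytest.fixture
def small_morphs():
    morph_of = {
        "i0": "hippocoonides", "i1": "hippocoonides",
        "i2": "cenea", "i3": "cenea",
        "i4": "poultoni",
    }
    return make_morph_table(morph_of, ("hippocoonides", "cenea", "poultoni"))
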