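import numpy as np
import pytest

from cladegap import Alignment, SimConfig, SpeciesMap, simulate_library


def make_alignment(rows, locus="locus1"):
    """Build an Alignment from a list of (id, seq) or a dict."""
    if isinstance(rows, dict):
        return Alignment(locus, rows)
    return Alignment(locus, dict(rows))


@pytest.fixture
def tiny_alignment():
    return make_alignment(
        {
            "a": "ACGTACGT",
            "b": "ACGTACGT",
            "c": "ACGTTCGT",
            "d": "ACTTTCGT",
        }
    )


@pytest.fixture
def tiny_map():
    return SpeciesMap(
        {
            "a": ("sp1", "c1"),
            "b": ("sp1", "c1"),
            "c": ("sp2", "c1"),
            "d": ("sp3", "c2"),
        }
    )


#: small, fast simulation settings shared by unit tests (short loci, few
#: clades); the full-size defaults are exercised by the acceptance suite
SMALL_SIM = dict(
    n_clades=3,
    species_per_clade=3,
    individuals_per_species=(2, 3),
    locus_lengths=(400, 250, 350),
)


@pytest.fixture(scope="session")
def small_library():
    cfg = SimConfig(seed=42, n_hybrids=0, n_mislabels=0, **SMALL_SIM)
    lib, truth = simulate_library(cfg)
    return lib, truth
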