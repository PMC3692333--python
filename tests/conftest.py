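import numpy as np
import pytest

from parentsim import FrequencySet, LocusFrequencies, generate_synthetic_frequencies
from parentsim.study import ParentageSimulation


def make_locus(name, labels, freqs):
    return LocusFrequencies(name, tuple(labels), np.asarray(freqs, dtype=float))


@pytest.fixture(scope="session")
def panel():
    """A 15-locus Identifiler-style synthetic panel (fixed seed)."""
    return generate_synthetic_frequencies(n_loci=15, seed=123)


@pytest.fixture(scope="session")
def biallelic_panel():
    """One 2-allele locus, p = 0.3 / 0.7 — handy for closed-form checks."""
    return FrequencySet((make_locus("BI", ["a", "b"], [0.3, 0.7]),))


@pytest.fixture(scope="session")
def triallelic_panel():
    """One 3-allele locus with uneven frequencies."""
    return FrequencySet((make_locus("TRI", ["a", "b", "c"], [0.5, 0.3, 0.2]),))


@pytest.fixture(scope="session")
def fitted_full(panel):
    """One full-scale fit (10 000 families, all scenarios) shared by tests."""
    model = ParentageSimulation(panel, n_families=10_000)
    return model.fit(seed=2024)
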