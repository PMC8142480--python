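import numpy as np
import pytest

from speedcon.panel import build_panel
from speedcon.sim import GenomeMap, simulate_assay


@pytest.fixture(scope="session")
def assay():
    """Full synthetic assay: (panel of 1591 A + 49 X + 29 Y, 819 diagnostic ids)."""
    return simulate_assay(seed=0)


@pytest.fixture(scope="session")
def toy_gmap():
    """Small two-autosome genome for fast meiosis-level tests."""
    return GenomeMap(physical={"1": 100_000_000, "2": 50_000_000,
                               "X": 80_000_000, "Y": 10_000_000})


@pytest.fixture
def small_panel():
    return build_panel([
        ("1", 100, "m1", "A", "G"),
        ("1", 500, "m2", "C", "T"),
        ("2", 300, "m3", "G", "A"),
        ("X", 200, "mX", "T", "C"),
        ("Y", 150, "mY", "A", "C"),
    ])


def random_matrix(rng, panel, n_samples, missing_frac=0.1):
    """Random genotype matrix over a panel (helper, not a fixture)."""
    from speedcon.panel import GenotypeMatrix

    calls = rng.choice([0, 1, 2], size=(n_samples, len(panel))).astype(np.int8)
    mask = rng.random(calls.shape) < missing_frac
    calls[mask] = -1
    return GenotypeMatrix([f"s{i}" for i in range(n_samples)], panel, calls)
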