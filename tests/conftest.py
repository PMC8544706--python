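import numpy as np
import pytest

from isomirkit.reference import EnumerationBounds, HairpinRecord, MatureArm
from isomirkit.simulate import SimulationDesign, simulate_reference


@pytest.fixture(scope="session")
def bounds():
    return EnumerationBounds()


@pytest.fixture(scope="session")
def small_bounds():
    """Tighter bounds that keep brute-force oracles fast."""
    return EnumerationBounds(max_start_shift=2, max_end_shift=2, max_nta_len=2)


@pytest.fixture(scope="session")
def three_hairpins():
    """Three deterministic random hairpins (one with two arms)."""
    design = SimulationDesign(seed=20240, n_hairpins=2, arms_per_hairpin=1)
    records = list(simulate_reference(design))
    two_arm = simulate_reference(
        SimulationDesign(seed=20241, n_hairpins=1, arms_per_hairpin=2)
    )
    return records + list(two_arm)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def flat_hairpin():
    """A hand-built hairpin whose arm context is easy to reason about."""
    #            0         1         2         3         4         5
    #            0123456789012345678901234567890123456789012345678901234
    sequence = "GGCATCGAATACCGTTAGACCGTTGACTAGCATTACGGAGCCTTAAGGCTCCGTAACGG"
    return HairpinRecord(
        "hp-flat", sequence, (MatureArm("flat-miR-1-5p", 10, 32),)
    )
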