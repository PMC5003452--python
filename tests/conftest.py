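import numpy as np
import pytest

from probekit.affyio import ChipLayout, IntensityArray, ProbePair, ProbeSet
from probekit.synth import SimParams, make_layout, simulate_quad


@pytest.fixture
def toy_layout() -> ChipLayout:
    """Two probe-sets (3 + 2 pairs) on an 8x8 grid, PM above MM."""
    set_a = ProbeSet(
        "setA_at",
        [
            ProbePair((0, 0), (0, 1)),
            ProbePair((1, 0), (1, 1)),
            ProbePair((2, 0), (2, 1)),
        ],
    )
    set_b = ProbeSet(
        "setB_at",
        [ProbePair((3, 0), (3, 1)), ProbePair((4, 0), (4, 1))],
    )
    return ChipLayout("ToyChip", 8, 8, [set_a, set_b])


@pytest.fixture
def toy_array() -> IntensityArray:
    rng = np.random.default_rng(42)
    values = np.round(rng.uniform(1, 100, size=(8, 8)), 3)
    return IntensityArray("toy", 8, 8, values)


@pytest.fixture(scope="session")
def quad_sim():
    """A small four-chip simulation shared across tests (no planted SFPs)."""
    layout = make_layout(60, 11, 40, 40, seed=5)
    arrays, truth = simulate_quad(layout, SimParams(n_sfp=0, seed=5))
    return layout, arrays, truth


@pytest.fixture(scope="session")
def quad_sim_sfp():
    """Four-chip simulation with planted SFPs."""
    layout = make_layout(120, 11, 60, 60, seed=11)
    arrays, truth = simulate_quad(layout, SimParams(n_sfp=5, seed=11))
    return layout, arrays, truth
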