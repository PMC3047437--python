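import numpy as np
import pytest

from ignet import (AssignmentConfig, SegmentAssigner, SimulationConfig,
                   simulate_repertoire, synthetic_reference)
from ignet.reference import GermlineReference, GermlineSegment


@pytest.fixture(scope="session")
def default_ref():
    """The default synthetic 39V/5D/5J zebrafish-like reference."""
    return synthetic_reference()


@pytest.fixture(scope="session")
def default_assigner(default_ref):
    return SegmentAssigner(default_ref)


@pytest.fixture(scope="session")
def small_ref():
    """A small, short-segment reference for fast alignment tests."""
    return synthetic_reference(8, 3, 3, v_length=90, d_length=9,
                               j_length=48, seed=7)


@pytest.fixture
def tiny_ref():
    return GermlineReference(
        [GermlineSegment("V1", "V", "AAA")],
        [GermlineSegment("D1", "D", "CC")],
        [GermlineSegment("J1", "J", "GGG")],
    )


@pytest.fixture(scope="session")
def simulated_500(default_ref):
    """500 independently mutated reads at default rates, with truth."""
    cfg = SimulationConfig(n_sequences=500, seed=42)
    return simulate_repertoire(default_ref, cfg)
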