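"""Shared fixtures: one small genome with a designed fold-back event."""

import pytest

from foldback.analyze import SeedIndex
from foldback.genome import generate_reference
from foldback.simulate import design_foldback_event


@pytest.fixture(scope="session")
def base_genome():
    """Two-chromosome synthetic genome used across the analyzer tests."""
    return generate_reference(
        {"chrA": 3_000_000, "chrB": 2_000_000},
        seed=101,
        telomere_units=100,
    )


@pytest.fixture(scope="session")
def designed(base_genome):
    """(edited genome, event, break position) for a designed fold-back event.

    Deletion 400 kb, duplication 800 kb, spacer 2,047 bp, 4-bp microhomology
    on chrA.
    """
    genome, event, p = design_foldback_event(
        base_genome, "chrA",
        deletion=400_000, duplication=800_000, spacer=2_047, mh=4)
    return genome, event, p


@pytest.fixture(scope="session")
def designed_index(designed):
    genome, _event, _p = designed
    return SeedIndex(genome, k=20)
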