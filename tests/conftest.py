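"""Shared fixtures: small planted-family datasets with exact truth."""

from __future__ import annotations

import pytest

from satellitome.synthetic_data import (
    FamilySpec,
    LibrarySpec,
    plant_genome,
    simulate_library,
    _family_consensus,
)

SEED = 7


@pytest.fixture(scope="session")
def one_family():
    """One 36-bp family (5% divergence), error-free 100-bp reads."""
    spec = FamilySpec(
        "famA", rul=36, divergence_target=0.05, copies_female=400, n_loci_female=2
    )
    genome, truth = plant_genome([spec], 200_000, "female", SEED)
    reads = simulate_library(
        genome, LibrarySpec("libA", n_reads=20_000, seed=SEED, error_rate=0.0)
    )
    return {
        "spec": spec,
        "consensus": _family_consensus(spec, SEED),
        "genome": genome,
        "truth": truth,
        "reads": reads,
    }


@pytest.fixture(scope="session")
def two_family_reads():
    """Two unrelated families for clustering / filtering tests."""
    specs = [
        FamilySpec("famA", rul=36, divergence_target=0.02, copies_female=300, n_loci_female=2),
        FamilySpec("famB", rul=27, divergence_target=0.02, copies_female=300, n_loci_female=2),
    ]
    genome, truth = plant_genome(specs, 200_000, "female", SEED + 1)
    reads = simulate_library(
        genome, LibrarySpec("libB", n_reads=20_000, seed=SEED + 1, error_rate=0.0)
    )
    return {
        "specs": specs,
        "consensuses": {s.family_id: _family_consensus(s, SEED + 1) for s in specs},
        "truth": truth,
        "reads": reads,
    }
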