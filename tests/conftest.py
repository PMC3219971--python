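"""Shared fixtures: small seeded simulations reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from besynt.io_formats import Genome
from besynt.synthetic_data import (
    BacLibraryPlan,
    EvolutionPlan,
    simulate_bac_library,
    simulate_phylogenomes,
    simulate_repeat_landscape,
)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def small_phylo():
    """Five small genomes with default branch substitution, full retention."""
    plan = EvolutionPlan(seed=7)
    genomes, truth = simulate_phylogenomes(plan, n_blocks=6, genes_per_block=6)
    return plan, genomes, truth


@pytest.fixture(scope="session")
def repeat_landscape():
    """A 200-kb random genome with the default TE/MITE/SSR landscape."""
    rng = np.random.default_rng(42)
    base = Genome("host", {"chr1": random_dna(rng, 200_000)})
    genome, truth = simulate_repeat_landscape(base, seed=5)
    return base, genome, truth


@pytest.fixture(scope="session")
def bac_library(repeat_landscape):
    """BAC library over a ~2.4-Mb repeat-bearing genome (library defaults)."""
    rng = np.random.default_rng(43)
    base = Genome(
        "host",
        {"chr1": random_dna(rng, 900_000), "chr2": random_dna(rng, 600_000)},
    )
    genome, truth = simulate_repeat_landscape(base, seed=6)
    plan = BacLibraryPlan(seed=8, shotgun_reads=100)
    lib = simulate_bac_library(genome, plan, truth)
    return genome, truth, plan, lib
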