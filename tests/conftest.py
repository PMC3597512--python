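"""Shared fixtures: small synthetic datasets with known truth."""

import numpy as np
import pytest

from pirnakit import simulate
from pirnakit.simulate import CassetteSpec


@pytest.fixture(scope="session")
def design():
    return simulate.default_design()


@pytest.fixture(scope="session")
def planted():
    """A 120-kb genome with 24 planted cassettes covering classes, strands
    and minicluster sizes; returns (genome, truth loci)."""
    genome = simulate.generate_genome(2, [70_000, 50_000], gc_fraction=0.36, seed=11)
    rng = np.random.default_rng(12)
    specs = []
    for i in range(24):
        cls = ("male", "female", "non_enriched")[i % 3]
        specs.append(
            CassetteSpec(
                five_prime_class="CAGT"[i % 4],
                spacer_length=int(simulate.spacer_distribution(rng, 1)[0]),
                n_window_Ts=1 + i % 3,
                strand="+-"[i % 2],
                truth_class=cls,
            )
        )
    return simulate.plant_cassettes(genome, specs, seed=13)


@pytest.fixture(scope="session")
def genome(planted):
    return planted[0]


@pytest.fixture(scope="session")
def loci(planted):
    return planted[1]


@pytest.fixture(scope="session")
def pirna_loci(loci):
    return [l.to_pirna_locus() for l in loci]


@pytest.fixture(scope="session")
def counts_and_truth(loci, design):
    return simulate.simulate_counts(loci, design, seed=21)
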