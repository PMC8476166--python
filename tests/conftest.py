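"""Shared fixtures: small simulated lineages and datasets built from them.

Everything is generated at test time from fixed seeds; module-scoped
fixtures keep the suite fast by reusing bundles across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from orthocomplete import LineageSpec, simulate_lineage

# five species star tree; terminal branches 0.05 substitutions/site
STAR_TREE = "(sp1:0.05,sp2:0.05,sp3:0.05,sp4:0.05,sp5:0.05);"
# identical species (no divergence): exact-recovery fixtures
ZERO_TREE = "(sp1:0.0,sp2:0.0,sp3:0.0,sp4:0.0,sp5:0.0);"


@pytest.fixture(scope="session")
def star_bundle():
    return simulate_lineage(LineageSpec(tree=STAR_TREE, n_markers=20, seed=11))


@pytest.fixture(scope="session")
def star_dataset(star_bundle):
    # held-out split: seeds from the first four species, assess sp5
    return star_bundle.build_dataset("star_bacteria", species=star_bundle.species[:4])


@pytest.fixture(scope="session")
def zero_bundle():
    # background genes keep the gene set non-empty at exhaustive depletion
    return simulate_lineage(
        LineageSpec(tree=ZERO_TREE, n_markers=20, n_background_genes=5, seed=7)
    )


@pytest.fixture(scope="session")
def zero_dataset(zero_bundle):
    return zero_bundle.build_dataset("zero_bacteria", species=zero_bundle.species[:4])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
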