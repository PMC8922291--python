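"""Shared fixtures: small synthetic worlds reused across test modules."""

import numpy as np
import pytest

from interatlas import (
    AtlasSpec,
    EvidenceSpec,
    generate_atlas,
    generate_evidence,
    simulate_expression,
)
from interatlas.pathway_atlas import Atlas


@pytest.fixture(scope="session")
def small_atlas():
    """~36-gene, 3-pathway atlas for fast end-to-end tests."""
    return generate_atlas(
        AtlasSpec(n_pathways=3, mean_pathway_size=12, overlap_fraction=0.1,
                  mean_degree=2.5, size_dispersion=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def small_expr(small_atlas):
    return simulate_expression(small_atlas, n_test=20, n_control=20, seed=12)


@pytest.fixture(scope="session")
def small_evidence(small_atlas):
    return generate_evidence(
        small_atlas,
        EvidenceSpec(n_types=6, sensitivity=0.9, fpr=0.03,
                     nonedge_sample_factor=3.0, seed=13),
    )


@pytest.fixture(scope="session")
def two_block_atlas():
    """Two disconnected cliques of 6 genes each — a planted partition."""
    block_a = [f"a{i}" for i in range(6)]
    block_b = [f"b{i}" for i in range(6)]
    edges = set()
    for block in (block_a, block_b):
        for i, g in enumerate(block):
            for h in block[i + 1:]:
                edges.add((g, h))
    membership = {g: {"PA"} for g in block_a}
    membership.update({g: {"PB"} for g in block_b})
    return Atlas(nodes=set(block_a + block_b), edges=edges,
                 membership=membership)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
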