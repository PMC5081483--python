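"""Shared fixtures: toy networks and the standard synthetic world."""

import numpy as np
import pytest

from pdinet.network import PDINetwork, filter_baits
from pdinet.synthetic import WorldParams, generate_world


def make_network(edges, quality=None, n_tested_tfs=0, n_tested_promoters=0,
                 promoter_to_gene=None):
    """Small-network builder for toy cases."""
    tf_ids = {t for t, _ in edges}
    promoter_ids = {p for _, p in edges}
    if promoter_to_gene:
        promoter_ids |= set(promoter_to_gene)
    quality = quality or {}
    return PDINetwork(
        tf_ids=tf_ids,
        promoter_ids=promoter_ids,
        edges=set(edges),
        promoter_to_gene=promoter_to_gene or {p: p for p in promoter_ids},
        bait_quality={p: quality.get(p, "clean") for p in promoter_ids},
        n_tested_tfs=n_tested_tfs,
        n_tested_promoters=n_tested_promoters,
    )


def random_bipartite(n_tf, n_prom, n_edges, seed):
    """Uniform random bipartite network (for null-model tests)."""
    rng = np.random.default_rng(seed)
    tfs = [f"T{i}" for i in range(n_tf)]
    proms = [f"P{i}" for i in range(n_prom)]
    edges = set()
    while len(edges) < n_edges:
        edges.add((tfs[int(rng.integers(n_tf))], proms[int(rng.integers(n_prom))]))
    return make_network(edges, n_tested_tfs=n_tf, n_tested_promoters=n_prom)


@pytest.fixture(scope="session")
def standard_world():
    """The standard synthetic world (default parameters, fixed seed)."""
    return generate_world(WorldParams(seed=1))


@pytest.fixture(scope="session")
def clean_net(standard_world):
    """The quality-filtered analysis network of the standard world."""
    return filter_baits(standard_world.network, {"clean"})


@pytest.fixture(scope="session")
def coexpr_scores(standard_world):
    from pdinet.expression import build_coexpression

    return build_coexpression(standard_world.compendium)
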