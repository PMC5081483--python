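"""TF association network: shared-target similarity, essentiality, families.

Two TFs are associated when the Jaccard similarity of their bound-target
sets reaches a threshold; the resulting undirected network groups TFs
with similar DNA-binding behaviour and is a blueprint for redundancy.
If connected TFs can compensate for each other, highly connected TFs
should be less frequently essential; family-level statistics compare
association degree and essential fraction per DNA-binding-domain family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .network import PDINetwork, target_profile_similarity

logger = logging.getLogger(__name__)


@dataclass
class AssociationNetwork:
    """Undirected TF-TF graph weighted by target-profile similarity.

    Nodes carry ``family`` and ``essential`` attributes when labels were
    supplied.  Edges exist iff similarity >= the construction threshold
    (inclusive); no self-edges.
    """

    graph: nx.Graph
    similarity_threshold: float
    min_out_degree: int

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def degree(self, tf: str) -> int:
        return self.graph.degree[tf]

    def degrees(self) -> dict[str, int]:
        return {t: self.graph.degree[t] for t in self.graph.nodes}

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"tf_a": min(a, b), "tf_b": max(a, b), "similarity": d["similarity"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["tf_a", "tf_b", "similarity"]).sort_values(
            ["tf_a", "tf_b"]
        ).reset_index(drop=True)

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "tf": t,
                "degree": self.graph.degree[t],
                "family": self.graph.nodes[t].get("family"),
                "essential": self.graph.nodes[t].get("essential"),
            }
            for t in self.nodes
        ]
        return pd.DataFrame(rows)


def build_association_network(
    net: PDINetwork,
    min_out_degree: int = 3,
    similarity_threshold: float = 0.2,
    family: dict[str, str] | None = None,
    essential: dict[str, bool] | None = None,
) -> AssociationNetwork:
    """Build the TF association network from shared eY1H targets.

    Nodes are TFs with out-degree >= ``min_out_degree``; an edge connects
    two TFs when the Jaccard index of their bound-promoter sets is >=
    ``similarity_threshold`` (inclusive).
    """
    if not net.edges:
        raise ValueError("cannot build association network from empty PDI network")
    g = nx.Graph()
    tfs = sorted(t for t in net.tf_ids if len(net.targets_of(t)) >= min_out_degree)
    for t in tfs:
        g.add_node(
            t,
            family=(family or {}).get(t),
            essential=(essential or {}).get(t),
        )
    targets = {t: net.targets_of(t) for t in tfs}
    for i, a in enumerate(tfs):
        for b in tfs[i + 1:]:
            union = targets[a] | targets[b]
            sim = len(targets[a] & targets[b]) / len(union)
            if sim >= similarity_threshold:
                g.add_edge(a, b, similarity=sim)
    return AssociationNetwork(
        graph=g,
        similarity_threshold=similarity_threshold,
        min_out_degree=min_out_degree,
    )


def essentiality_connectivity(
    assoc: AssociationNetwork, high_degree_cut: int = 1
) -> dict:
    """Compare association-network connectivity of essential vs non-essential TFs.

    The headline statistic is a pooled two-proportion z-test on the
    fraction of TFs at or above ``high_degree_cut`` association degree
    (default: connected vs isolated) in the two groups; the full degree
    distributions are returned for inspection.
    """
    degrees = assoc.degrees()
    ess = [t for t in assoc.nodes if assoc.graph.nodes[t].get("essential") is True]
    non = [t for t in assoc.nodes if assoc.graph.nodes[t].get("essential") is False]
    result = {
        "essential_degrees": np.array([degrees[t] for t in ess]),
        "non_essential_degrees": np.array([degrees[t] for t in non]),
        "high_degree_cut": high_degree_cut,
        "z": None,
        "p": None,
    }
    if not ess or not non:
        logger.info("one essentiality class empty; descriptive output only")
        return result
    k = [
        int((result["non_essential_degrees"] >= high_degree_cut).sum()),
        int((result["essential_degrees"] >= high_degree_cut).sum()),
    ]
    n = [len(non), len(ess)]
    if 0 < sum(k) < sum(n):
        z, p = proportions_ztest(k, n)
        z, p = float(z), float(p)
    else:  # pooled proportion 0 or 1: no variation to test
        z, p = 0.0, 1.0
    # exact variant alongside the pooled z, for small counts
    table = [[k[0], n[0] - k[0]], [k[1], n[1] - k[1]]]
    _, p_fisher = stats.fisher_exact(table)
    result.update(
        z=z,
        p=p,
        p_fisher=float(p_fisher),
        fraction_high_non_essential=k[0] / n[0],
        fraction_high_essential=k[1] / n[1],
    )
    return result


def family_stats(assoc: AssociationNetwork, min_family_size: int = 3) -> pd.DataFrame:
    """Per-family association-degree and essentiality comparisons.

    Each family is compared against all other TFs: Mann-Whitney U on
    association degree, and a pooled two-proportion z-test on the
    essential fraction.  Families with fewer than ``min_family_size``
    members are skipped (logged).
    """
    degrees = assoc.degrees()
    families: dict[str, list[str]] = {}
    for t in assoc.nodes:
        fam = assoc.graph.nodes[t].get("family")
        if fam is not None:
            families.setdefault(fam, []).append(t)
    rows = []
    for fam, members in sorted(families.items()):
        if len(members) < min_family_size:
            logger.info("family %s has < %d members; skipped", fam, min_family_size)
            continue
        rest = [t for t in assoc.nodes if t not in set(members)]
        if not rest:
            continue
        deg_f = np.array([degrees[t] for t in members])
        deg_r = np.array([degrees[t] for t in rest])
        try:
            _, p_deg = stats.mannwhitneyu(deg_f, deg_r, alternative="two-sided")
        except ValueError:  # all values identical
            p_deg = 1.0
        ess_f = [assoc.graph.nodes[t].get("essential") for t in members]
        ess_r = [assoc.graph.nodes[t].get("essential") for t in rest]
        row = {
            "family": fam,
            "n": len(members),
            "median_degree": float(np.median(deg_f)),
            "median_degree_rest": float(np.median(deg_r)),
            "p_degree": float(p_deg),
            "essential_fraction": np.nan,
            "essential_fraction_rest": np.nan,
            "p_essential": np.nan,
        }
        if all(e is not None for e in ess_f) and all(e is not None for e in ess_r):
            k = [sum(ess_f), sum(ess_r)]
            n = [len(ess_f), len(ess_r)]
            row["essential_fraction"] = k[0] / n[0]
            row["essential_fraction_rest"] = k[1] / n[1]
            if 0 < k[0] + k[1] < n[0] + n[1]:
                _, p_ess = proportions_ztest(k, n)
                row["p_essential"] = float(p_ess)
        rows.append(row)
    return pd.DataFrame(rows)


def save_association_network(assoc: AssociationNetwork, edge_path, node_path) -> None:
    assoc.edge_table().to_csv(edge_path, sep="\t", index=False)
    assoc.node_table().to_csv(node_path, sep="\t", index=False)


def brute_force_degrees(
    net: PDINetwork, min_out_degree: int, similarity_threshold: float
) -> dict[str, int]:
    """Independent recomputation of association degrees by pairwise Jaccard."""
    tfs = sorted(t for t in net.tf_ids if len(net.targets_of(t)) >= min_out_degree)
    out = {t: 0 for t in tfs}
    for a in tfs:
        for b in tfs:
            if a >= b:
                continue
            sim = target_profile_similarity(net, a, b)
            if sim is not None and sim >= similarity_threshold:
                out[a] += 1
                out[b] += 1
    return out
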