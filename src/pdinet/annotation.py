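"""Cofactor-based regulatory-sign classification and TF-GO association scan.

Transcriptional activation is typically mediated through co-activators
(mediator subunits, TAFs, histone acetyltransferases) and repression
through co-repressors (Groucho-like factors, histone deacetylases), so a
TF's protein-protein interaction partners carry information about its
regulatory sign even when it has few or no mapped DNA targets.

The GO association scan asks which TFs preferentially bind promoters of
genes in a biological-process term: TFs with very low or very high
out-degree are removed, terms with too few or too many annotated network
targets are removed, duplicate terms (identical target annotation) are
deduplicated by a seeded draw, and each surviving (TF, term) pair gets a
one-sided Fisher exact test over the network gene universe.  The count
of associations below the p cutoff is compared with the count on
degree-preserving randomized networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import PDINetwork
from .randomize import RandomizationConfig, edge_switch

logger = logging.getLogger(__name__)

COFACTOR_ROLES = ("co-activator", "co-repressor", "other")


@dataclass
class CofactorPPI:
    """TF-cofactor protein-protein interactions with cofactor role labels."""

    edges: set[tuple[str, str]]  # (tf_id, cofactor_id)
    roles: dict[str, str]

    def __post_init__(self) -> None:
        for _, cof in self.edges:
            role = self.roles.get(cof)
            if role is None:
                raise ValueError(f"cofactor {cof!r} has no role label")
            if role not in COFACTOR_ROLES:
                raise ValueError(f"unknown cofactor role {role!r} for {cof!r}")

    def partners_of(self, tf: str) -> set[str]:
        return {c for t, c in self.edges if t == tf}

    @property
    def tf_ids(self) -> set[str]:
        return {t for t, _ in self.edges}


@dataclass
class GOAnnotation:
    """Biological-process term -> annotated gene sets (flat, no propagation)."""

    term_genes: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [t for t, g in self.term_genes.items() if not g]
        if empty:
            raise ValueError(f"terms with empty gene sets: {sorted(empty)[:5]}")


def load_cofactor_ppi(path) -> CofactorPPI:
    """Read TF-cofactor PPIs from TSV (tf_id, cofactor_id, role)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    edges = set(zip(df["tf_id"], df["cofactor_id"]))
    roles = dict(zip(df["cofactor_id"], df["role"]))
    return CofactorPPI(edges=edges, roles=roles)


def load_go_annotations(path) -> GOAnnotation:
    """Read term -> gene annotations from a two-column TSV or a GAF 2.x file."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("!gaf-version"):
        df = pd.read_csv(path, sep="\t", comment="!", header=None, dtype=str)
        # GAF columns: 2 = gene symbol, 4 = GO id, 8 = aspect (P = process)
        df = df[df[8] == "P"]
        pairs = zip(df[4], df[2])
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        pairs = zip(df["term_id"], df["gene_id"])
    term_genes: dict[str, set[str]] = {}
    for term, gene in pairs:
        term_genes.setdefault(term, set()).add(gene)
    return GOAnnotation(term_genes=term_genes)


# -- cofactor-based sign classification -----------------------------------


def classify_by_cofactors(ppi: CofactorPPI, tf: str) -> str:
    """activator / repressor / bifunctional / unclassified from PPI partners.

    A TF interacting only with co-activators is a predicted activator,
    only with co-repressors a repressor, with both bifunctional, with
    neither unclassified.
    """
    partners = ppi.partners_of(tf)
    has_act = any(ppi.roles[c] == "co-activator" for c in partners)
    has_rep = any(ppi.roles[c] == "co-repressor" for c in partners)
    if has_act and has_rep:
        return "bifunctional"
    if has_act:
        return "activator"
    if has_rep:
        return "repressor"
    return "unclassified"


def classify_all_by_cofactors(ppi: CofactorPPI) -> dict[str, str]:
    return {tf: classify_by_cofactors(ppi, tf) for tf in sorted(ppi.tf_ids)}


def cofactor_fraction_stats(
    ppi: CofactorPPI, sign_by_tf: dict[str, str]
) -> dict:
    """Per-TF cofactor-PPI fractions, compared between activators and repressors.

    For each TF with at least one cofactor PPI, the fraction of its PPIs
    that involve co-activators (and co-repressors); the activator and
    repressor groups are compared with an unpaired two-tailed t-test on
    the co-activator fraction.
    """
    rows = []
    for tf, sign in sorted(sign_by_tf.items()):
        partners = ppi.partners_of(tf)
        if not partners:
            continue
        n = len(partners)
        f_act = sum(ppi.roles[c] == "co-activator" for c in partners) / n
        f_rep = sum(ppi.roles[c] == "co-repressor" for c in partners) / n
        rows.append(
            {"tf": tf, "sign": sign, "n_ppis": n,
             "coactivator_fraction": f_act, "corepressor_fraction": f_rep}
        )
    table = pd.DataFrame(rows)
    result = {"table": table, "p_coactivator": None, "p_corepressor": None}
    if not table.empty:
        act = table[table["sign"] == "activator"]
        rep = table[table["sign"] == "repressor"]
        if len(act) >= 2 and len(rep) >= 2:
            for col, key in (
                ("coactivator_fraction", "p_coactivator"),
                ("corepressor_fraction", "p_corepressor"),
            ):
                _, p = stats.ttest_ind(act[col], rep[col], equal_var=True)
                if np.isnan(p):  # both groups constant: no variance to test
                    p = 1.0 if act[col].mean() == rep[col].mean() else 0.0
                result[key] = float(p)
    return result


# -- evidence concordance -------------------------------------------------


@dataclass
class EvidenceTable:
    """Per-TF regulatory-sign evidence from multiple sources.

    ``evidence[tf]`` maps a source name (coexpression, cofactor,
    literature, ...) to a sign in {activator, repressor, bifunctional}.
    """

    evidence: dict[str, dict[str, str]]

    def tfs_with_multiple_sources(self) -> list[str]:
        return sorted(t for t, ev in self.evidence.items() if len(ev) >= 2)


def concordance(evidence: EvidenceTable) -> dict:
    """Fraction of multi-source TFs whose sign evidence does not conflict.

    Two sources conflict only when one says activator and another says
    repressor; bifunctional is compatible with either sign.
    """
    multi = evidence.tfs_with_multiple_sources()
    if not multi:
        raise ValueError("no TF has evidence from >= 2 sources")
    rows = []
    n_concordant = 0
    for tf in multi:
        signs = set(evidence.evidence[tf].values())
        discordant = "activator" in signs and "repressor" in signs
        if not discordant:
            n_concordant += 1
        rows.append({"tf": tf, "sources": dict(evidence.evidence[tf]),
                     "concordant": not discordant})
    return {
        "fraction_concordant": n_concordant / len(multi),
        "n_multi_source": len(multi),
        "per_tf": rows,
    }


# -- TF-GO association scan -----------------------------------------------


def tf_go_enrichment(
    net: PDINetwork, annotations: GOAnnotation, tf: str, term: str
) -> tuple[float, float]:
    """One-sided Fisher exact p and fold enrichment for one (TF, term) pair.

    The 2x2 universe is the genes of all promoters in the network: target
    of the TF vs not, annotated to the term vs not.  The upper-tail
    hypergeometric p is the probability of at least the observed overlap.
    """
    universe = net.genes
    if term not in annotations.term_genes:
        raise KeyError(f"unknown term {term!r}")
    term_set = annotations.term_genes[term] & universe
    if not term_set:
        raise ValueError(f"term {term!r} annotates no gene in the network universe")
    targets = net.target_genes_of(tf) & universe
    overlap = len(targets & term_set)
    M, n, N = len(universe), len(term_set), len(targets)
    p = float(stats.hypergeom.sf(overlap - 1, M, n, N))
    expected = n * N / M
    fold = overlap / expected if expected > 0 else np.nan
    return p, float(fold)


def _dedup_terms(
    net: PDINetwork, annotations: GOAnnotation, candidate_terms: list[str],
    rng: np.random.Generator,
) -> list[str]:
    """Among terms annotating identical network target sets keep one at random."""
    by_set: dict[frozenset, list[str]] = {}
    universe = net.genes
    for term in candidate_terms:
        key = frozenset(annotations.term_genes[term] & universe)
        by_set.setdefault(key, []).append(term)
    kept = []
    for _, terms in sorted(by_set.items(), key=lambda kv: sorted(kv[1])[0]):
        terms = sorted(terms)
        kept.append(terms[int(rng.integers(len(terms)))] if len(terms) > 1 else terms[0])
    return sorted(kept)


def association_scan(
    net: PDINetwork,
    annotations: GOAnnotation,
    min_out_degree: int = 10,
    max_out_degree: int = 150,
    min_term_targets: int = 10,
    max_term_targets: int = 200,
    p_cutoff: float = 0.001,
    n_randomizations: int = 0,
    seed: int = 0,
    swap_attempts_factor: int = 100,
) -> dict:
    """Scan all surviving (TF, term) pairs for target-set GO enrichment.

    Filter cascade, in order: TFs with out-degree < ``min_out_degree``
    (unlikely to reach significance) or > ``max_out_degree`` (non-specific
    hubs) are dropped; terms with fewer than ``min_term_targets`` or more
    than ``max_term_targets`` annotated network genes are dropped;
    duplicate terms are deduplicated by a seeded draw.  Associations with
    p < ``p_cutoff`` are reported, with BH-adjusted p alongside.  When
    ``n_randomizations`` > 0, the scan is repeated on edge-switched
    networks and the null distribution of association counts is returned.
    """
    rng = np.random.default_rng(seed)
    universe = net.genes

    def _scan_one(network: PDINetwork, terms: list[str]) -> pd.DataFrame:
        tfs = sorted(
            t
            for t in network.tf_ids
            if min_out_degree <= len(network.targets_of(t)) <= max_out_degree
        )
        rows = []
        term_sets = {t: annotations.term_genes[t] & universe for t in terms}
        M = len(universe)
        for tf in tfs:
            targets = network.target_genes_of(tf) & universe
            N = len(targets)
            for term in terms:
                term_set = term_sets[term]
                overlap = len(targets & term_set)
                n = len(term_set)
                p = float(stats.hypergeom.sf(overlap - 1, M, n, N))
                rows.append(
                    {"tf": tf, "term": term, "overlap": overlap,
                     "n_targets": N, "term_size": n,
                     "fold": overlap / (n * N / M), "p": p}
                )
        return pd.DataFrame(
            rows, columns=["tf", "term", "overlap", "n_targets",
                           "term_size", "fold", "p"]
        )

    candidate = sorted(
        term
        for term, genes in annotations.term_genes.items()
        if min_term_targets <= len(genes & universe) <= max_term_targets
    )
    terms = _dedup_terms(net, annotations, candidate, rng)

    table = _scan_one(net, terms)
    if not table.empty:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(table["p"], method="fdr_bh")
        table = table.assign(p_adj=p_adj)
        associations = table[table["p"] < p_cutoff].reset_index(drop=True)
    else:
        logger.info("GO scan: no surviving (TF, term) pairs")
        associations = table.assign(p_adj=pd.Series(dtype=float))

    result = {
        "n_terms_evaluated": len(terms),
        "associations": associations,
        "n_associations": len(associations),
        "n_tfs_with_association": associations["tf"].nunique()
        if not associations.empty else 0,
        "all_pairs": table,
    }

    if n_randomizations > 0:
        null_counts = np.zeros(n_randomizations, dtype=int)
        for kk in range(n_randomizations):
            cfg = RandomizationConfig(
                n_randomizations=1,
                swap_attempts_factor=swap_attempts_factor,
                seed=int(rng.integers(2**31 - 1)),
            )
            rnd = edge_switch(net, cfg)
            t = _scan_one(rnd, terms)
            null_counts[kk] = 0 if t.empty else int((t["p"] < p_cutoff).sum())
        sd = null_counts.std(ddof=1) if n_randomizations > 1 else 0.0
        result["null_counts"] = null_counts
        result["null_mean"] = float(null_counts.mean())
        result["null_sd"] = float(sd)
        diff = len(associations) - null_counts.mean()
        if sd > 0:
            result["z"] = float(diff / sd)
        else:
            # null spread is zero: any excess is beyond the null entirely
            result["z"] = float(np.inf * np.sign(diff)) if diff != 0 else 0.0
    return result


def gene_set_enrichment(
    net: PDINetwork, tf: str, gene_set: set[str]
) -> tuple[float, float]:
    """Fisher enrichment of a TF's targets in an arbitrary gene family set.

    Same machinery as the GO test, for user-supplied families (e.g.,
    detoxifying-enzyme classes) over the network gene universe.
    """
    universe = net.genes
    fam = gene_set & universe
    if not fam:
        raise ValueError("gene set has no members in the network universe")
    targets = net.target_genes_of(tf) & universe
    overlap = len(targets & fam)
    M, n, N = len(universe), len(fam), len(targets)
    p = float(stats.hypergeom.sf(overlap - 1, M, n, N))
    expected = n * N / M
    return p, (overlap / expected if expected > 0 else np.nan)


def family_composition_test(
    tfs_enriched: set[str], family_members: set[str], all_tfs: set[str]
) -> dict:
    """Two-proportion comparison of a TF family among enriched vs all TFs."""
    from statsmodels.stats.proportion import proportions_ztest

    n_enr = len(tfs_enriched)
    n_all = len(all_tfs)
    k_enr = len(tfs_enriched & family_members)
    k_all = len(all_tfs & family_members)
    if n_enr == 0 or n_all == 0:
        raise ValueError("empty TF sets")
    z, p = proportions_ztest([k_enr, k_all], [n_enr, n_all])
    return {
        "fraction_enriched": k_enr / n_enr,
        "fraction_all": k_all / n_all,
        "z": float(z),
        "p": float(p),
    }
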