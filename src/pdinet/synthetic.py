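"""Seeded generator of a complete synthetic screen with known ground truth.

The generated "world" emulates the statistical structure of a
gene-centered PDI screen: a bipartite TF -> promoter network with a
heavy-tailed TF out-degree, bait-quality artifacts (high-background
baits with spurious interactions), promoter sequences carrying planted
binding motifs for their true regulators, an expression compendium with
planted positive (activator) and negative (repressor) TF-target
correlations, tissue-stage profiles, cofactor PPIs consistent with the
planted signs, GO terms that over-sample planted TFs' targets, and
paralogous TF pairs that share perturbed copies of one motif, share
targets, and are non-essential.

Every dataset is derived from a single root seed (fanned out to
per-component child seeds), so regeneration is bit-identical and each
stage of the analysis pipeline can be validated against the planted
truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import CofactorPPI, GOAnnotation
from .expression import ExpressionCompendium, ExpressionDataset, TissueExpression
from .motifs import PWM, BASES
from .network import PDINetwork, save_edge_list

TISSUE_CONDITIONS = (
    "embryo_intestine", "embryo_neurons", "embryo_pharyngeal_muscle",
    "embryo_body_wall_muscle", "embryo_coelomocytes", "embryo_hypodermis",
    "larval_intestine", "larval_neurons", "larval_body_wall_muscle",
    "larval_coelomocytes", "larval_hypodermis",
)


@dataclass
class WorldParams:
    """Parameters of the synthetic world (defaults are the study conditions).

    Sizes are desk-scale; the planted effect sizes follow the standard
    conditions used throughout the analyses: activator/repressor
    co-expression effect 0.5 across 50 high-confidence datasets, 30
    targets per signed TF, and a >= 8-bit motif inserted in 90% of a
    60-target TF's promoters.
    """

    # counts
    n_tfs: int = 60
    n_promoters: int = 600
    n_datasets: int = 55            # 50 high-confidence + 5 below the cutoff
    n_low_confidence: int = 5
    n_samples: int = 8              # experiments per high-confidence dataset
    n_samples_low: int = 3

    # motif parameters
    motif_length: int = 8
    motif_dominance: float = 0.95   # consensus-base probability per position
    insertion_rate: float = 0.9

    # network parameters
    n_hub_tfs: int = 6
    hub_out_degree_range: tuple[int, int] = (140, 157)
    sign_target_count: int = 30
    background_out_degree_range: tuple[int, int] = (2, 5)
    false_positive_rate: float = 0.03
    dropout_rate: float = 0.1
    high_background_fraction: float = 0.06
    moderate_background_fraction: float = 0.10
    spurious_in_degree: int = 5

    # sign parameters
    activator_fraction: float = 0.13
    repressor_fraction: float = 0.08
    effect_correlation: float = 0.5
    tissue_correlation: float = 0.5
    cofactor_fidelity: float = 0.9

    # GO parameters
    n_go_terms: int = 25
    n_coherent_tfs: int = 5
    coherent_term_target_overlap: int = 25
    go_background_size_range: tuple[int, int] = (12, 60)

    # redundancy / family parameters
    n_paralog_pairs: int = 4
    paralog_out_degree: int = 12
    paralog_shared_fraction: float = 0.7
    expanded_family_size: int = 14
    expanded_family_pool: int = 90  # promoter pool shared by the expanded family
    base_essential_rate: float = 0.5
    expanded_family_essential_rate: float = 0.2

    # sequence / expression parameters
    promoter_length_range: tuple[int, int] = (600, 1200)
    dataset_gene_presence: float = 0.92
    n_sparse_genes: int = 12        # genes failing the dataset-coverage rule
    n_dim_genes: int = 20           # genes stuck in the bottom expression decile
    expression_mu: float = 6.5
    expression_mu_sd: float = 0.8

    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        if self.activator_fraction + self.repressor_fraction > 1:
            problems.append("activator_fraction + repressor_fraction > 1")
        for name in ("insertion_rate", "dropout_rate", "false_positive_rate",
                     "cofactor_fidelity", "effect_correlation",
                     "tissue_correlation", "motif_dominance"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                problems.append(f"{name} must be in [0, 1], got {v}")
        if self.n_tfs < 10 or self.n_promoters < 50:
            problems.append("world too small to be testable (n_tfs>=10, n_promoters>=50)")
        if self.n_low_confidence >= self.n_datasets:
            problems.append("n_low_confidence must be < n_datasets")
        if self.sign_target_count < 10:
            problems.append("sign_target_count must be >= 10 for sign calls")
        if not (4 <= self.motif_length <= 12):
            problems.append("motif_length must be in [4, 12]")
        return problems


@dataclass
class SyntheticWorld:
    """Ground truth plus all emitted datasets for one seeded world."""

    params: WorldParams
    # ground truth
    tf_ids: list[str]
    promoter_ids: list[str]
    promoter_to_gene: dict[str, str]
    pwms: dict[str, PWM]
    signs: dict[str, str]                  # activator | repressor | none
    families: dict[str, str]
    essential: dict[str, bool]
    paralog_pairs: list[tuple[str, str]]
    true_edges: set[tuple[str, str]]       # intended regulator -> promoter
    motif_truth_edges: set[tuple[str, str]]  # edges with a planted motif
    planted_associations: list[tuple[str, str]]  # (tf, go term)
    # emitted datasets
    network: PDINetwork = field(repr=False, default=None)
    promoter_sequences: dict[str, str] = field(repr=False, default=None)
    compendium: ExpressionCompendium = field(repr=False, default=None)
    tissue: TissueExpression = field(repr=False, default=None)
    cofactor_ppi: CofactorPPI = field(repr=False, default=None)
    go_annotations: GOAnnotation = field(repr=False, default=None)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _random_pwm(rng: np.random.Generator, length: int, dominance: float,
                motif_id: str, tf_id: str) -> PWM:
    consensus = rng.integers(0, 4, size=length)
    mat = np.full((4, length), (1 - dominance) / 3)
    mat[consensus, np.arange(length)] = dominance
    return PWM(motif_id=motif_id, tf_id=tf_id, matrix=mat)


def _perturb_pwm(rng: np.random.Generator, pwm: PWM, n_positions: int,
                 motif_id: str, tf_id: str) -> PWM:
    """Copy a PWM, re-drawing the consensus base at a few positions."""
    mat = pwm.matrix.copy()
    dominance = float(mat.max(axis=0).mean())
    pos = rng.choice(pwm.length, size=min(n_positions, pwm.length), replace=False)
    for j in pos:
        new_base = int(rng.integers(0, 4))
        col = np.full(4, (1 - dominance) / 3)
        col[new_base] = dominance
        mat[:, j] = col
    return PWM(motif_id=motif_id, tf_id=tf_id, matrix=mat)


def _sample_consensus(rng: np.random.Generator, pwm: PWM) -> str:
    """Draw a word from the PWM (mostly the consensus at high dominance)."""
    return "".join(
        BASES[rng.choice(4, p=pwm.matrix[:, j])] for j in range(pwm.length)
    )


def generate_world(params: WorldParams) -> SyntheticWorld:
    """Generate the full synthetic world from validated parameters."""
    problems = params.validate()
    if problems:
        raise ValueError("invalid WorldParams: " + "; ".join(problems))

    seeds = _child_seeds(params.seed, 8)
    rng_net = np.random.default_rng(seeds[0])
    rng_seq = np.random.default_rng(seeds[1])
    rng_expr = np.random.default_rng(seeds[2])
    rng_tissue = np.random.default_rng(seeds[3])
    rng_cof = np.random.default_rng(seeds[4])
    rng_go = np.random.default_rng(seeds[5])
    rng_labels = np.random.default_rng(seeds[6])

    tf_ids = [f"TF{i:03d}" for i in range(params.n_tfs)]
    promoter_ids = [f"P{i:04d}" for i in range(params.n_promoters)]
    promoter_to_gene = {p: p.replace("P", "G", 1) for p in promoter_ids}

    # --- roles: hubs, signed TFs, paralog pairs, families -----------------
    order = list(rng_labels.permutation(params.n_tfs))
    hubs = [tf_ids[i] for i in order[: params.n_hub_tfs]]
    n_act = round(params.activator_fraction * params.n_tfs)
    n_rep = round(params.repressor_fraction * params.n_tfs)
    signed = [tf_ids[i] for i in order[params.n_hub_tfs: params.n_hub_tfs + n_act + n_rep]]
    signs = {t: "none" for t in tf_ids}
    for t in signed[:n_act]:
        signs[t] = "activator"
    for t in signed[n_act:]:
        signs[t] = "repressor"

    remaining = [tf_ids[i] for i in order[params.n_hub_tfs + n_act + n_rep:]]
    paralog_pairs = []
    pool = list(remaining)
    for _ in range(params.n_paralog_pairs):
        if len(pool) < 2:
            break
        a = pool.pop(0)
        b = pool.pop(0)
        paralog_pairs.append((a, b))

    # families: one expanded family (shared promoter pool, low essentiality),
    # one diverse family, the rest split among small families
    families = {}
    fam_order = list(rng_labels.permutation(tf_ids))
    paralog_tfs = [t for pair in paralog_pairs for t in pair]
    expanded = paralog_tfs + [
        t for t in fam_order if t not in paralog_tfs
    ][: max(0, params.expanded_family_size - len(paralog_tfs))]
    expanded = expanded[: params.expanded_family_size]
    rest = [t for t in fam_order if t not in set(expanded)]
    n_zf = max(3, len(rest) // 3)
    zf = rest[:n_zf]
    for t in tf_ids:
        if t in set(expanded):
            families[t] = "NHR-like"
        elif t in set(zf):
            families[t] = "ZF-like"
        else:
            families[t] = ("HD-like", "bHLH-like", "bZIP-like")[
                rest.index(t) % 3 if t in rest else 0
            ]

    # --- PWMs: family prototype for the expanded family; paralogs share --
    pwms: dict[str, PWM] = {}
    prototype = _random_pwm(rng_seq, params.motif_length, params.motif_dominance,
                            "proto_NHR", "proto")
    for t in tf_ids:
        if t in set(expanded):
            pwms[t] = _perturb_pwm(rng_seq, prototype, 2, f"motif_{t}", t)
        else:
            pwms[t] = _random_pwm(rng_seq, params.motif_length,
                                  params.motif_dominance, f"motif_{t}", t)
    for a, b in paralog_pairs:
        pwms[b] = _perturb_pwm(rng_seq, pwms[a], 1, f"motif_{b}", b)

    # --- intended target sets (true regulatory edges) ---------------------
    lo, hi = params.background_out_degree_range
    out_degree = {t: int(rng_net.integers(lo, hi + 1)) for t in tf_ids}
    for t in signed:
        out_degree[t] = params.sign_target_count
    for a, b in paralog_pairs:
        out_degree[a] = params.paralog_out_degree
        out_degree[b] = params.paralog_out_degree
    h_lo, h_hi = params.hub_out_degree_range
    for t in hubs:
        out_degree[t] = int(rng_net.integers(h_lo, h_hi + 1))

    family_pool = list(rng_net.choice(promoter_ids,
                                      size=min(params.expanded_family_pool,
                                               params.n_promoters),
                                      replace=False))
    true_targets: dict[str, list[str]] = {}
    for t in tf_ids:
        k = min(out_degree[t], params.n_promoters)
        if families[t] == "NHR-like":
            src = family_pool if k <= len(family_pool) else promoter_ids
            true_targets[t] = list(rng_net.choice(src, size=k, replace=False))
        else:
            true_targets[t] = list(rng_net.choice(promoter_ids, size=k,
                                                  replace=False))
    for a, b in paralog_pairs:
        k = out_degree[b]
        n_shared = min(int(round(params.paralog_shared_fraction * k)),
                       len(true_targets[a]))
        shared = list(rng_net.choice(true_targets[a], size=n_shared, replace=False))
        others = [p for p in promoter_ids if p not in set(shared)]
        extra = list(rng_net.choice(others, size=k - n_shared, replace=False))
        true_targets[b] = shared + extra

    true_edges = {(t, p) for t, ps in true_targets.items() for p in ps}

    # --- promoter sequences with planted motifs (slotted, no overwrites) --
    L = params.motif_length
    plen_lo, plen_hi = params.promoter_length_range
    lengths = {p: int(rng_seq.integers(plen_lo, plen_hi + 1)) for p in promoter_ids}
    seqs = {
        p: list("".join(rng_seq.choice(list(BASES), size=lengths[p])))
        for p in promoter_ids
    }
    window = 500
    free_slots = {
        p: list(rng_seq.permutation(min(window, lengths[p]) // L))
        for p in promoter_ids
    }
    motif_truth_edges: set[tuple[str, str]] = set()
    # plant hub/signed TF motifs last so high-value motifs never lose a slot
    plant_order = sorted(tf_ids, key=lambda t: (t in set(signed + hubs), t))
    for t in plant_order:
        for p in true_targets[t]:
            if rng_seq.random() > params.insertion_rate:
                continue
            if not free_slots[p]:
                continue
            slot = free_slots[p].pop()
            start = lengths[p] - min(window, lengths[p]) + slot * L
            word = _sample_consensus(rng_seq, pwms[t])
            seqs[p][start: start + L] = list(word)
            motif_truth_edges.add((t, p))
    promoter_sequences = {p: "".join(s) for p, s in seqs.items()}

    # --- emitted screen network: dropout, false positives, bait artifacts -
    # iterate in sorted order: set order is process-dependent and random
    # draws during iteration must be reproducible across processes
    edges = {
        e for e in sorted(motif_truth_edges)
        if rng_net.random() > params.dropout_rate
    }
    n_fp = int(round(params.false_positive_rate * len(edges)))
    all_pairs_rng = rng_net
    added = 0
    while added < n_fp:
        t = tf_ids[int(all_pairs_rng.integers(params.n_tfs))]
        p = promoter_ids[int(all_pairs_rng.integers(params.n_promoters))]
        if (t, p) not in edges:
            edges.add((t, p))
            added += 1

    n_high = int(round(params.high_background_fraction * params.n_promoters))
    n_mod = int(round(params.moderate_background_fraction * params.n_promoters))
    qual_order = list(rng_net.permutation(promoter_ids))
    high_bg = set(qual_order[:n_high])
    mod_bg = set(qual_order[n_high: n_high + n_mod])
    for p in sorted(high_bg):
        spurious = rng_net.choice(tf_ids, size=params.spurious_in_degree,
                                  replace=False)
        for t in spurious:
            edges.add((str(t), p))

    bait_quality = {}
    proms_with_edges = {p for _, p in edges}
    for p in promoter_ids:
        if p in high_bg:
            bait_quality[p] = "high_background"
        elif p in mod_bg:
            bait_quality[p] = "moderate_background"
        elif p in proms_with_edges:
            bait_quality[p] = "clean"
        else:
            bait_quality[p] = "no_interactions"

    network = PDINetwork(
        tf_ids=set(tf_ids),
        promoter_ids=set(promoter_ids),
        edges=edges,
        promoter_to_gene=dict(promoter_to_gene),
        bait_quality=bait_quality,
        n_tested_tfs=params.n_tfs,
        n_tested_promoters=params.n_promoters,
    )

    # --- expression compendium with planted sign structure ----------------
    genes = [promoter_to_gene[p] for p in promoter_ids]
    all_expr_ids = tf_ids + genes
    mu = {
        g: float(rng_expr.normal(params.expression_mu, params.expression_mu_sd))
        for g in all_expr_ids
    }
    gene_list = list(rng_expr.permutation(genes))
    # planted signal genes (TFs and driven targets) stay clear of the
    # bottom expression decile so the noise filter acts only on noise
    expr_floor = params.expression_mu - params.expression_mu_sd
    # sparse genes miss the dataset-coverage rule; dim genes sit in the
    # bottom expression decile; keep planted targets out of both sets
    driven_genes: dict[str, tuple[str, float]] = {}
    for t in signed:
        beta = (params.effect_correlation if signs[t] == "activator"
                else -params.effect_correlation)
        for p in true_targets[t]:
            g = promoter_to_gene[p]
            if g not in driven_genes:
                driven_genes[g] = (t, beta)
    for g in list(driven_genes) + tf_ids:
        mu[g] = max(mu[g], expr_floor)
    undriven = [g for g in gene_list if g not in driven_genes]
    sparse_genes = set(undriven[: params.n_sparse_genes])
    dim_genes = set(undriven[params.n_sparse_genes:
                             params.n_sparse_genes + params.n_dim_genes])
    for g in dim_genes:
        mu[g] = 1.0

    datasets = []
    for d in range(params.n_datasets):
        low_conf = d >= params.n_datasets - params.n_low_confidence
        n_samp = params.n_samples_low if low_conf else params.n_samples
        present = [
            g for g in all_expr_ids
            if (g in tf_ids)
            or (g in sparse_genes and rng_expr.random() < 0.3)
            or (g not in sparse_genes
                and rng_expr.random() < params.dataset_gene_presence)
        ]
        z_tf = {t: rng_expr.normal(size=n_samp) for t in tf_ids}
        rows = {}
        for g in present:
            if g in z_tf:
                z = z_tf[g]
            elif g in driven_genes:
                t, beta = driven_genes[g]
                noise = rng_expr.normal(size=n_samp)
                z = beta * z_tf[t] + np.sqrt(1 - beta**2) * noise
            else:
                z = rng_expr.normal(size=n_samp)
            rows[g] = np.power(2.0, mu[g] + z)
        table = pd.DataFrame.from_dict(
            rows, orient="index",
            columns=[f"s{j}" for j in range(n_samp)],
        )
        datasets.append(
            ExpressionDataset(dataset_id=f"DS{d:03d}", table=table,
                              n_experiments=n_samp)
        )
    compendium = ExpressionCompendium(datasets)

    # --- tissue-stage expression matrix -----------------------------------
    n_cond = len(TISSUE_CONDITIONS)
    tf_profiles = {t: rng_tissue.normal(size=n_cond) for t in tf_ids}
    rows = {}
    for t in tf_ids:
        rows[t] = tf_profiles[t]
    for p in promoter_ids:
        g = promoter_to_gene[p]
        if g in driven_genes:
            t, beta = driven_genes[g]
            rho = params.tissue_correlation * np.sign(beta)
            noise = rng_tissue.normal(size=n_cond)
            rows[g] = rho * tf_profiles[t] + np.sqrt(1 - rho**2) * noise
        else:
            rows[g] = rng_tissue.normal(size=n_cond)
    tissue = TissueExpression(
        pd.DataFrame.from_dict(rows, orient="index",
                               columns=list(TISSUE_CONDITIONS))
    )

    # --- cofactor PPIs consistent with planted signs ----------------------
    n_coact, n_corep, n_other = 12, 12, 6
    coact = [f"COA{i:02d}" for i in range(n_coact)]
    corep = [f"COR{i:02d}" for i in range(n_corep)]
    other = [f"COF{i:02d}" for i in range(n_other)]
    roles = {c: "co-activator" for c in coact}
    roles.update({c: "co-repressor" for c in corep})
    roles.update({c: "other" for c in other})
    ppi_edges = set()
    for t in tf_ids:
        n_partners = int(rng_cof.integers(1, 4))
        for _ in range(n_partners):
            if signs[t] == "activator":
                src = coact if rng_cof.random() < params.cofactor_fidelity else corep
            elif signs[t] == "repressor":
                src = corep if rng_cof.random() < params.cofactor_fidelity else coact
            else:
                src = other
            ppi_edges.add((t, str(rng_cof.choice(src))))
    cofactor_ppi = CofactorPPI(edges=ppi_edges, roles=roles)

    # --- GO annotations over-sampling planted TFs' targets ----------------
    coherent_candidates = [t for t in signed + hubs
                           if 10 <= len(true_targets[t]) <= 150]
    coherent = list(rng_go.choice(coherent_candidates,
                                  size=min(params.n_coherent_tfs,
                                           len(coherent_candidates)),
                                  replace=False))
    term_genes: dict[str, set[str]] = {}
    planted_associations = []
    for i, t in enumerate(coherent):
        term = f"GO:{9000000 + i}"
        tgt_genes = [promoter_to_gene[p] for p in true_targets[t]]
        k = min(params.coherent_term_target_overlap, len(tgt_genes))
        members = set(rng_go.choice(tgt_genes, size=k, replace=False))
        extras = rng_go.choice(genes, size=10, replace=False)
        term_genes[term] = members | set(extras)
        planted_associations.append((t, term))
    g_lo, g_hi = params.go_background_size_range
    for i in range(params.n_go_terms - len(coherent)):
        term = f"GO:{8000000 + i}"
        size = int(rng_go.integers(g_lo, g_hi + 1))
        term_genes[term] = set(rng_go.choice(genes, size=size, replace=False))
    go_annotations = GOAnnotation(term_genes=term_genes)

    # --- essentiality anti-correlated with planted redundancy -------------
    essential = {}
    for t in tf_ids:
        if t in set(paralog_tfs):
            essential[t] = False
        elif families[t] == "NHR-like":
            essential[t] = bool(rng_labels.random()
                                < params.expanded_family_essential_rate)
        else:
            essential[t] = bool(rng_labels.random() < params.base_essential_rate)

    return SyntheticWorld(
        params=params,
        tf_ids=tf_ids,
        promoter_ids=promoter_ids,
        promoter_to_gene=promoter_to_gene,
        pwms=pwms,
        signs=signs,
        families=families,
        essential=essential,
        paralog_pairs=paralog_pairs,
        true_edges=true_edges,
        motif_truth_edges=motif_truth_edges,
        planted_associations=planted_associations,
        network=network,
        promoter_sequences=promoter_sequences,
        compendium=compendium,
        tissue=tissue,
        cofactor_ppi=cofactor_ppi,
        go_annotations=go_annotations,
    )


def emit_datasets(world: SyntheticWorld, directory) -> dict[str, str]:
    """Write all standard-format inputs plus a ground-truth manifest.

    Returns a manifest mapping dataset names to file paths; every file is
    re-loadable by the corresponding loader without loss.
    """
    from .motifs import write_meme

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _register(name: str, path: Path) -> Path:
        manifest[name] = str(path.relative_to(directory))
        return path

    save_edge_list(world.network, _register("edge_list", directory / "network.tsv"))

    with open(_register("promoters_fasta", directory / "promoters.fasta"), "w") as fh:
        for p in world.promoter_ids:
            fh.write(f">{p}\n{world.promoter_sequences[p]}\n")

    # motifs are named by TF id so a re-loaded file maps onto the network
    write_meme(
        [PWM(motif_id=t, tf_id=t, matrix=world.pwms[t].matrix)
         for t in world.tf_ids],
        _register("truth_motifs", directory / "truth_motifs.meme"),
    )

    comp_dir = directory / "compendium"
    comp_dir.mkdir(exist_ok=True)
    rows = []
    for ds in world.compendium.datasets:
        fname = f"{ds.dataset_id}.tsv"
        ds.table.to_csv(comp_dir / fname, sep="\t")
        rows.append({"dataset_id": ds.dataset_id,
                     "n_experiments": ds.n_experiments,
                     "path": fname})
    pd.DataFrame(rows).to_csv(
        _register("compendium_manifest", comp_dir / "manifest.tsv"),
        sep="\t", index=False,
    )

    world.tissue.table.to_csv(
        _register("tissue", directory / "tissue.tsv"), sep="\t"
    )

    ppi_rows = sorted(world.cofactor_ppi.edges)
    pd.DataFrame(
        {"tf_id": [t for t, _ in ppi_rows],
         "cofactor_id": [c for _, c in ppi_rows],
         "role": [world.cofactor_ppi.roles[c] for _, c in ppi_rows]}
    ).to_csv(_register("cofactor_ppi", directory / "cofactor_ppi.tsv"),
             sep="\t", index=False)

    go_rows = sorted(
        (term, gene)
        for term, gs in world.go_annotations.term_genes.items()
        for gene in gs
    )
    pd.DataFrame({"term_id": [t for t, _ in go_rows],
                  "gene_id": [g for _, g in go_rows]}).to_csv(
        _register("go_annotations", directory / "go_annotations.tsv"),
        sep="\t", index=False,
    )

    pd.DataFrame(
        {"tf_id": world.tf_ids,
         "family": [world.families[t] for t in world.tf_ids],
         "essential": [int(world.essential[t]) for t in world.tf_ids],
         "sign_truth": [world.signs[t] for t in world.tf_ids]}
    ).to_csv(_register("tf_labels", directory / "tf_labels.tsv"),
             sep="\t", index=False)

    truth = {
        "params": asdict(world.params),
        "paralog_pairs": world.paralog_pairs,
        "planted_associations": world.planted_associations,
        "true_edges": sorted(world.true_edges),
        "motif_truth_edges": sorted(world.motif_truth_edges),
    }
    with open(_register("ground_truth", directory / "ground_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=0, sort_keys=True)

    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
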