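"""Pipeline orchestration: configuration, staged execution, run report.

``run_pipeline`` executes the analysis stages in dependency order
(network -> randomization overlap -> motif scan/discovery -> sign
inference -> GO associations -> TF association network), either on
supplied input files or on a freshly generated synthetic world.  Stage
failures are recorded and downstream stages whose inputs are satisfied
still run.  Reports are regenerable bit-identically from the same
configuration and inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import expression as expr_mod
from . import motifs as motif_mod
from . import network as net_mod
from . import randomize as rand_mod
from . import annotation as annot_mod
from .synthetic import WorldParams, generate_world

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis framework, with their standard defaults.

    Defaults are the constants used throughout the analyses: PWM score
    threshold 0.09 on the (0, 0.5] energy scale, 500-bp proximal window,
    50% non-specific rule, >= 10 targets and alpha 0.05 for sign calls,
    GO out-degree bounds [10, 150] and term-size bounds [10, 200] with
    p < 0.001, association-network similarity 0.2 with eY1H out-degree
    >= 3, 75th-percentile spatiotemporal cutoff, and 20,000 / 1,000
    randomizations for overlap / GO-and-sign nulls.
    """

    # input paths (None = stage skipped unless synthetic mode)
    edge_list: str | None = None
    promoter_fasta: str | None = None
    motif_file: str | None = None
    compendium_manifest: str | None = None
    tissue_table: str | None = None
    cofactor_ppi: str | None = None
    go_annotations: str | None = None
    tf_labels: str | None = None

    # thresholds (standard defaults)
    scan_threshold: float = 0.09
    proximal_window: int = 500
    non_specific_fraction: float = 0.5
    min_targets: int = 10
    sign_alpha: float = 0.05
    go_out_degree_bounds: tuple[int, int] = (10, 150)
    go_term_size_bounds: tuple[int, int] = (10, 200)
    go_p_cutoff: float = 0.001
    association_similarity: float = 0.2
    association_min_out_degree: int = 3
    overlap_percentile: float = 75.0
    n_randomizations_overlap: int = 20000
    n_randomizations_null: int = 1000
    swap_attempts_factor: int = 100

    # execution
    seed: int = 0
    synthetic: bool = False
    world_params: WorldParams | None = None

    def validate(self) -> list[str]:
        """Return the list of violations (empty iff the config is legal)."""
        v = []
        if not (0 < self.scan_threshold <= 0.5):
            v.append(f"scan_threshold {self.scan_threshold} not in (0, 0.5]")
        if self.proximal_window < 1:
            v.append("proximal_window must be >= 1")
        if not (0 < self.non_specific_fraction <= 1):
            v.append("non_specific_fraction must be in (0, 1]")
        if self.min_targets < 1:
            v.append("min_targets must be >= 1")
        if not (0 < self.sign_alpha < 1):
            v.append("sign_alpha must be in (0, 1)")
        if not (0 < self.go_p_cutoff < 1):
            v.append("go_p_cutoff must be in (0, 1)")
        lo, hi = self.go_out_degree_bounds
        if not (0 < lo <= hi):
            v.append("go_out_degree_bounds must satisfy 0 < lo <= hi")
        lo, hi = self.go_term_size_bounds
        if not (0 < lo <= hi):
            v.append("go_term_size_bounds must satisfy 0 < lo <= hi")
        if not (0 <= self.association_similarity <= 1):
            v.append("association_similarity must be in [0, 1]")
        if self.association_min_out_degree < 1:
            v.append("association_min_out_degree must be >= 1")
        if not (0 < self.overlap_percentile < 100):
            v.append("overlap_percentile must be in (0, 100)")
        if self.n_randomizations_overlap < 1 or self.n_randomizations_null < 1:
            v.append("randomization counts must be >= 1")
        if self.swap_attempts_factor < 1:
            v.append("swap_attempts_factor must be >= 1")
        return v


def validate_config(config: PipelineConfig) -> list[str]:
    return config.validate()


@dataclass
class RunReport:
    """Per-stage summaries plus provenance for one pipeline run."""

    config_hash: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def stage_ok(self, name: str) -> bool:
        return self.stages.get(name, {}).get("status") == "ok"

    def report_hash(self) -> str:
        """Deterministic digest of the report content."""
        payload = json.dumps(
            {"config": self.config_hash, "seed": self.seed,
             "stages": _jsonable(self.stages), "warnings": self.warnings},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def _config_hash(config: PipelineConfig) -> str:
    d = asdict(config)
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir=None) -> RunReport:
    """Execute all stages whose inputs are available; never raise per-stage.

    In synthetic mode all inputs come from a generated world (whose
    parameters default to the standard conditions); otherwise stages with
    missing input files are skipped with a warning.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=_config_hash(config), seed=config.seed)
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]

    world = None
    inputs: dict = {}
    if config.synthetic:
        params = config.world_params or WorldParams(seed=config.seed)
        world = generate_world(params)
        inputs = {
            "network": world.network,
            "promoters": world.promoter_sequences,
            "pwms": [world.pwms[t] for t in world.tf_ids],
            "compendium": world.compendium,
            "tissue": world.tissue,
            "cofactor_ppi": world.cofactor_ppi,
            "go": world.go_annotations,
            "families": world.families,
            "essential": world.essential,
        }
    else:
        inputs = _load_inputs(config, report)

    # --- stage: network ---------------------------------------------------
    net_filtered = None
    try:
        net = inputs.get("network")
        if net is None:
            raise FileNotFoundError("no edge list supplied")
        net_filtered = net_mod.filter_baits(net, {"clean"})
        summary = net_mod.degree_summary(net_filtered)
        dens = net_mod.density_matrix(net_filtered)
        report.stages["network"] = {
            "status": "ok",
            "n_edges": net_filtered.n_edges(),
            "n_tfs": len(net_filtered.tf_ids),
            "n_promoters": len(net_filtered.promoter_ids),
            "n_genes": len(net_filtered.genes),
            "mean_in_degree": summary.mean_in_degree,
            "median_in_degree": summary.median_in_degree,
            "mean_out_degree_fraction": summary.mean_out_degree_fraction,
            "density_edge_total": float(dens["edge_counts"].sum()),
        }
        if out_dir is not None:
            net_mod.save_edge_list(net_filtered, out_dir / "network_filtered.tsv")
    except Exception as exc:  # noqa: BLE001 - stage isolation by design
        report.stages["network"] = {"status": "failed", "error": str(exc)}
        report.warnings.append(f"network stage failed: {exc}")

    # --- stage: motif scan + predicted-network overlap --------------------
    predicted = None
    try:
        pwms = inputs.get("pwms")
        promoters = inputs.get("promoters")
        if not pwms or not promoters:
            raise FileNotFoundError("no motif file / promoter FASTA supplied")
        scan_cfg = motif_mod.ScanConfig(
            threshold=config.scan_threshold,
            window=config.proximal_window,
            non_specific_fraction=config.non_specific_fraction,
        )
        p2g = net_filtered.promoter_to_gene if net_filtered else None
        predicted, removed = motif_mod.predicted_network(
            pwms, promoters, scan_cfg, promoter_to_gene=p2g
        )
        report.stages["scan"] = {
            "status": "ok",
            "n_predicted_edges": predicted.n_edges(),
            "n_retained_tfs": len(predicted.tf_ids),
            "n_non_specific_removed": len(removed),
        }
    except Exception as exc:  # noqa: BLE001
        report.stages["scan"] = {"status": "failed", "error": str(exc)}
        report.warnings.append(f"scan stage failed: {exc}")

    try:
        if net_filtered is None or predicted is None:
            raise RuntimeError("needs network and predicted-network stages")
        cfg = rand_mod.RandomizationConfig(
            n_randomizations=config.n_randomizations_overlap,
            swap_attempts_factor=config.swap_attempts_factor,
            seed=stage_seeds[0],
        )
        ov = rand_mod.overlap_significance(net_filtered, predicted, cfg)
        report.stages["randomize"] = {
            "status": "ok",
            "observed_overlap": ov.observed,
            "null_mean": ov.null_mean,
            "null_sd": ov.null_sd,
            "z": ov.z,
            "p_normal": ov.p_normal,
            "p_empirical": ov.p_empirical,
        }
        if out_dir is not None:
            ov.to_frame().to_csv(out_dir / "overlap.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        report.stages["randomize"] = {"status": "failed", "error": str(exc)}
        report.warnings.append(f"randomize stage failed: {exc}")

    # --- stage: motif discovery ------------------------------------------
    try:
        if net_filtered is None or not inputs.get("promoters"):
            raise RuntimeError("needs network and promoter sequences")
        promoters = inputs["promoters"]
        eligible = [
            t for t in sorted(net_filtered.tf_ids)
            if len(net_filtered.targets_of(t)) >= 50
        ]
        n_motifs = {}
        for tf in eligible:
            targets = net_filtered.targets_of(tf)
            pos = [promoters[p] for p in sorted(targets) if p in promoters]
            neg = [promoters[p] for p in sorted(set(promoters) - targets)]
            found = motif_mod.discover_motifs(
                pos, neg, window=config.proximal_window
            )
            n_motifs[tf] = len(found)
        report.stages["motifs"] = {
            "status": "ok",
            "n_tfs_eligible": len(eligible),
            "n_motifs_per_tf": n_motifs,
        }
    except Exception as exc:  # noqa: BLE001
        report.stages["motifs"] = {"status": "failed", "error": str(exc)}
        report.warnings.append(f"motifs stage failed: {exc}")

    # --- stage: sign inference --------------------------------------------
    try:
        comp = inputs.get("compendium")
        if net_filtered is None or comp is None:
            raise RuntimeError("needs network and expression compendium")
        scores = expr_mod.build_coexpression(comp)
        preds = expr_mod.predict_all_signs(
            net_filtered, scores,
            min_targets=config.min_targets, alpha=config.sign_alpha,
        )
        n_act = sum(p.call == "activator" for p in preds)
        n_rep = sum(p.call == "repressor" for p in preds)
        report.stages["signs"] = {
            "status": "ok",
            "n_activators": n_act,
            "n_repressors": n_rep,
            "n_called": n_act + n_rep,
            "n_evaluated": sum(p.p_value is not None for p in preds),
        }
        if out_dir is not None:
            expr_mod.predictions_table(preds).to_csv(
                out_dir / "sign_predictions.tsv", sep="\t", index=False
            )
        tissue = inputs.get("tissue")
        if tissue is not None:
            st = expr_mod.spatiotemporal_overlap(
                net_filtered, tissue, percentile=config.overlap_percentile
            )
            report.stages["signs"]["spatiotemporal_cutoff"] = st["cutoff"]
            report.stages["signs"]["spatiotemporal_odds_ratio"] = st["odds_ratio"]
            report.stages["signs"]["spatiotemporal_p"] = st["p"]
    except Exception as exc:  # noqa: BLE001
        report.stages["signs"] = {"status": "failed", "error": str(exc)}
        report.warnings.append(f"signs stage failed: {exc}")

    # --- stage: GO associations -------------------------------------------
    try:
        go = inputs.get("go")
        if net_filtered is None or go is None:
            raise RuntimeError("needs network and GO annotations")
        scan = annot_mod.association_scan(
            net_filtered, go,
            min_out_degree=config.go_out_degree_bounds[0],
            max_out_degree=config.go_out_degree_bounds[1],
            min_term_targets=config.go_term_size_bounds[0],
            max_term_targets=config.go_term_size_bounds[1],
            p_cutoff=config.go_p_cutoff,
            n_randomizations=0,
            seed=stage_seeds[1],
        )
        report.stages["go"] = {
            "status": "ok",
            "n_terms_evaluated": scan["n_terms_evaluated"],
            "n_associations": scan["n_associations"],
            "n_tfs_with_association": scan["n_tfs_with_association"],
        }
        if out_dir is not None:
            scan["associations"].to_csv(
                out_dir / "go_associations.tsv", sep="\t", index=False
            )
    except Exception as exc:  # noqa: BLE001
        report.stages["go"] = {"status": "failed", "error": str(exc)}
        report.warnings.append(f"go stage failed: {exc}")

    # --- stage: TF association network ------------------------------------
    try:
        if net_filtered is None:
            raise RuntimeError("needs network stage")
        an = assoc_mod.build_association_network(
            net_filtered,
            min_out_degree=config.association_min_out_degree,
            similarity_threshold=config.association_similarity,
            family=inputs.get("families"),
            essential=inputs.get("essential"),
        )
        report.stages["assoc"] = {
            "status": "ok",
            "n_nodes": len(an.nodes),
            "n_edges": an.graph.number_of_edges(),
        }
        if inputs.get("essential"):
            ec = assoc_mod.essentiality_connectivity(an)
            report.stages["assoc"]["essentiality_z"] = ec["z"]
            report.stages["assoc"]["essentiality_p"] = ec["p"]
        if out_dir is not None:
            assoc_mod.save_association_network(
                an, out_dir / "association_edges.tsv",
                out_dir / "association_nodes.tsv",
            )
    except Exception as exc:  # noqa: BLE001
        report.stages["assoc"] = {"status": "failed", "error": str(exc)}
        report.warnings.append(f"assoc stage failed: {exc}")

    if out_dir is not None:
        with open(out_dir / "run_report.json", "w") as fh:
            json.dump(
                {"config_hash": report.config_hash, "seed": report.seed,
                 "report_hash": report.report_hash(),
                 "stages": _jsonable(report.stages),
                 "warnings": report.warnings},
                fh, indent=2, sort_keys=True, default=str,
            )
    return report


def _load_inputs(config: PipelineConfig, report: RunReport) -> dict:
    inputs: dict = {}
    if config.edge_list and Path(config.edge_list).exists():
        inputs["network"] = net_mod.load_edge_list(config.edge_list)
    if config.promoter_fasta and Path(config.promoter_fasta).exists():
        from Bio import SeqIO

        inputs["promoters"] = {
            rec.id: str(rec.seq)
            for rec in SeqIO.parse(config.promoter_fasta, "fasta")
        }
    if config.motif_file and Path(config.motif_file).exists():
        inputs["pwms"] = motif_mod.read_meme(config.motif_file)
    if config.compendium_manifest and Path(config.compendium_manifest).exists():
        inputs["compendium"] = expr_mod.load_compendium(config.compendium_manifest)
    if config.tissue_table and Path(config.tissue_table).exists():
        inputs["tissue"] = expr_mod.TissueExpression(
            pd.read_csv(config.tissue_table, sep="\t", index_col=0)
        )
    if config.cofactor_ppi and Path(config.cofactor_ppi).exists():
        inputs["cofactor_ppi"] = annot_mod.load_cofactor_ppi(config.cofactor_ppi)
    if config.go_annotations and Path(config.go_annotations).exists():
        inputs["go"] = annot_mod.load_go_annotations(config.go_annotations)
    if config.tf_labels and Path(config.tf_labels).exists():
        labels = pd.read_csv(config.tf_labels, sep="\t", dtype={"tf_id": str})
        inputs["families"] = dict(zip(labels["tf_id"], labels["family"]))
        inputs["essential"] = dict(
            zip(labels["tf_id"], labels["essential"].astype(bool))
        )
    for key, path in (
        ("network", config.edge_list),
        ("promoters", config.promoter_fasta),
        ("pwms", config.motif_file),
        ("compendium", config.compendium_manifest),
        ("go", config.go_annotations),
    ):
        if path and key not in inputs:
            report.warnings.append(f"input file missing: {path}")
    return inputs


# -- reproduction hooks ----------------------------------------------------


def network_headline_stats(edge_list_path, n_tested_promoters: int = 0) -> dict:
    """Headline counts for a screen edge list: the reproduction hook.

    Loads an edge list, restricts to clean baits, and recomputes the
    counts a screen summary reports: edge/TF/gene totals, mean and median
    promoter in-degree, the out-degree leaders, and the most-overlapping
    TF pair (shared targets / union, Jaccard).
    """
    net = net_mod.load_edge_list(
        edge_list_path, n_tested_promoters=n_tested_promoters
    )
    filtered = net_mod.filter_baits(net, {"clean"})
    summary = net_mod.degree_summary(filtered)
    out_sorted = sorted(
        summary.out_degree.items(), key=lambda kv: (-kv[1], kv[0])
    )
    best_pair = None
    tfs = [t for t, d in out_sorted if d >= 3]
    for i, a in enumerate(tfs):
        ta = filtered.targets_of(a)
        for b in tfs[i + 1:]:
            tb = filtered.targets_of(b)
            shared = len(ta & tb)
            union = len(ta | tb)
            sim = shared / union if union else 0.0
            if best_pair is None or shared > best_pair["shared"]:
                best_pair = {"tf_a": a, "tf_b": b, "shared": shared,
                             "union": union, "similarity": sim}
    return {
        "n_edges": filtered.n_edges(),
        "n_tfs": len(filtered.tf_ids),
        "n_genes": len(filtered.genes),
        "n_promoters": len(filtered.promoter_ids),
        "mean_in_degree": summary.mean_in_degree,
        "median_in_degree": summary.median_in_degree,
        "top_out_degree": dict(out_sorted[:5]),
        "n_tfs_with_50_targets": sum(1 for _, d in out_sorted if d >= 50),
        "most_shared_pair": best_pair,
    }


def tested_combinations(n_tfs_screened: int, n_promoters_screened: int) -> int:
    """Number of pairwise TF x promoter combinations a screen interrogates."""
    return n_tfs_screened * n_promoters_screened
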