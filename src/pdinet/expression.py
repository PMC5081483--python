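"""Co-expression integration, activator/repressor inference, and
spatiotemporal overlap statistics.

A compendium of expression profiling datasets is reduced to gene-pair
co-expression scores: per-dataset Pearson correlation on log2(x+1)
expression, combined across high-confidence datasets (>= 4 experiments)
by a Fisher-z average weighted by (n_experiments - 3).  Genes covered by
too few high-confidence datasets, or stuck in the lowest expression
decile in most of them, are dropped as noise.

A TF is called an activator when its co-expression scores with its bound
targets are significantly higher than with non-targets (Mann-Whitney U),
and a repressor in the opposite direction; a per-TF score shuffle gives
the expected number of calls by chance.  Tissue-level profiles support an
odds-ratio test of spatiotemporal overlap between TFs and their targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .network import PDINetwork

logger = logging.getLogger(__name__)

#: Datasets with at least this many experiments are high-confidence.
HIGH_CONFIDENCE_MIN_EXPERIMENTS = 4
#: Genes must appear in at least this many high-confidence datasets.
MIN_DATASET_COVERAGE = 25
#: Bottom expression decile used by the noise filter.
LOW_EXPRESSION_QUANTILE = 0.10


@dataclass
class ExpressionDataset:
    dataset_id: str
    table: pd.DataFrame  # genes x samples
    n_experiments: int

    @property
    def high_confidence(self) -> bool:
        return self.n_experiments >= HIGH_CONFIDENCE_MIN_EXPERIMENTS


@dataclass
class ExpressionCompendium:
    datasets: list[ExpressionDataset]

    @property
    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for ds in self.datasets:
            out.update(ds.table.index)
        return out

    def high_confidence_datasets(self) -> list[ExpressionDataset]:
        return [ds for ds in self.datasets if ds.high_confidence]


@dataclass
class CoexpressionScores:
    """Symmetric gene x gene co-expression score matrix.

    ``matrix[i, j]`` is NaN when the pair never co-occurs in a
    high-confidence dataset.
    """

    genes: list[str]
    matrix: np.ndarray = field(repr=False)
    coverage: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[self._index[a], self._index[b]])

    def scores_with(self, gene: str, others: list[str]) -> np.ndarray:
        i = self._index[gene]
        idx = [self._index[o] for o in others]
        return self.matrix[i, idx]


@dataclass
class SignPrediction:
    tf_id: str
    call: str  # activator | repressor | none
    p_value: float | None
    median_ratio: float | None
    n_targets: int
    reason: str = ""


@dataclass
class TissueExpression:
    """Gene x condition matrix over tissue-stage conditions."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.isnull().any().any():
            raise ValueError("tissue expression matrix contains missing values")

    @property
    def conditions(self) -> list[str]:
        return list(self.table.columns)


# -- compendium I/O ------------------------------------------------------


def load_compendium(manifest_path) -> ExpressionCompendium:
    """Load a compendium from a manifest TSV (dataset_id, n_experiments, path).

    Paths are resolved relative to the manifest's directory; each dataset
    file is a genes x samples TSV with gene ids in the first column.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t", dtype={"dataset_id": str})
    datasets = []
    for row in manifest.itertuples(index=False):
        table = pd.read_csv(
            manifest_path.parent / row.path, sep="\t", index_col=0
        )
        datasets.append(
            ExpressionDataset(
                dataset_id=row.dataset_id,
                table=table,
                n_experiments=int(row.n_experiments),
            )
        )
    return ExpressionCompendium(datasets)


# -- co-expression scores ------------------------------------------------


def _retained_genes(compendium: ExpressionCompendium,
                    min_coverage: int,
                    low_quantile: float) -> tuple[list[str], dict[str, int]]:
    hc = compendium.high_confidence_datasets()
    coverage: dict[str, int] = {}
    low_rank: dict[str, int] = {}
    for ds in hc:
        mean_expr = ds.table.mean(axis=1)
        # lowest decile by rank: strictly fewer than low_quantile * n genes
        n_low = int(low_quantile * len(mean_expr))
        low = set(mean_expr.nsmallest(n_low).index)
        for g in ds.table.index:
            coverage[g] = coverage.get(g, 0) + 1
            if g in low:
                low_rank[g] = low_rank.get(g, 0) + 1
    retained = [
        g
        for g in sorted(coverage)
        if coverage[g] >= min_coverage
        and low_rank.get(g, 0) <= coverage[g] / 2
    ]
    return retained, coverage


def build_coexpression(
    compendium: ExpressionCompendium,
    min_coverage: int = MIN_DATASET_COVERAGE,
    low_quantile: float = LOW_EXPRESSION_QUANTILE,
) -> CoexpressionScores:
    """Integrate the compendium into gene-pair co-expression scores.

    Per high-confidence dataset, Pearson correlation of log2(x+1)
    expression between all retained genes present; pair score is the
    Fisher-z back-transformed average across datasets containing both
    genes, weighted by (n_experiments - 3).
    """
    hc = compendium.high_confidence_datasets()
    if not hc:
        raise ValueError("compendium has no high-confidence datasets")
    genes, coverage = _retained_genes(compendium, min_coverage, low_quantile)
    if not genes:
        raise ValueError("no genes pass the coverage and expression filters")
    gi = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    zsum = np.zeros((n, n))
    wsum = np.zeros((n, n))
    for ds in hc:
        present = [g for g in genes if g in ds.table.index]
        if len(present) < 2:
            continue
        x = np.log2(ds.table.loc[present].to_numpy(dtype=float) + 1.0)
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(x)
        r = np.nan_to_num(r, nan=0.0)  # zero-variance genes contribute 0
        np.clip(r, -0.999999, 0.999999, out=r)
        z = np.arctanh(r)
        w = max(ds.n_experiments - 3, 1)
        idx = np.array([gi[g] for g in present])
        zsum[np.ix_(idx, idx)] += w * z
        wsum[np.ix_(idx, idx)] += w
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.tanh(zsum / wsum)
    scores[wsum == 0] = np.nan
    np.fill_diagonal(scores, 1.0)
    return CoexpressionScores(genes=genes, matrix=scores,
                              coverage={g: coverage[g] for g in genes})


# -- activator / repressor inference -------------------------------------


def _tf_target_split(
    net: PDINetwork, scores: CoexpressionScores, tf: str
) -> tuple[list[str], list[str]]:
    """Scored targets and non-targets of a TF.

    The non-target universe is the set of scored genes that map to network
    promoters, minus the TF itself.
    """
    target_genes = net.target_genes_of(tf)
    universe = [
        g for g in (set(scores.genes) & net.genes) if g != tf
    ]
    targets = sorted(g for g in universe if g in target_genes)
    non_targets = sorted(g for g in universe if g not in target_genes)
    return targets, non_targets


def predict_sign(
    net: PDINetwork,
    scores: CoexpressionScores,
    tf: str,
    min_targets: int = 10,
    alpha: float = 0.05,
) -> SignPrediction:
    """Call a TF activator/repressor from target vs non-target co-expression.

    Two-sided Mann-Whitney U on the TF's co-expression scores with its
    bound targets vs all other scored network genes; the direction of the
    shift picks the sign.  TFs without co-expression data or with fewer
    than ``min_targets`` scored targets are not called.
    """
    if tf not in scores:
        return SignPrediction(tf, "none", None, None, 0, reason="tf not scored")
    targets, non_targets = _tf_target_split(net, scores, tf)
    t_scores = scores.scores_with(tf, targets)
    n_scores = scores.scores_with(tf, non_targets)
    t_scores = t_scores[~np.isnan(t_scores)]
    n_scores = n_scores[~np.isnan(n_scores)]
    if len(t_scores) < min_targets:
        return SignPrediction(
            tf, "none", None, None, len(t_scores), reason="below minimum targets"
        )
    if len(n_scores) == 0:
        return SignPrediction(tf, "none", None, None, len(t_scores),
                              reason="no scored non-targets")
    return _call_from_scores(tf, t_scores, n_scores, alpha)


def _call_from_scores(
    tf: str, t_scores: np.ndarray, n_scores: np.ndarray, alpha: float
) -> SignPrediction:
    u_stat, p = stats.mannwhitneyu(t_scores, n_scores, alternative="two-sided")
    ratio = median_ratio_from_scores(t_scores, n_scores)
    call = "none"
    if p < alpha:
        # direction from the rank-sum: U above its null mean means targets higher
        higher = u_stat > len(t_scores) * len(n_scores) / 2.0
        call = "activator" if higher else "repressor"
    return SignPrediction(tf, call, float(p), ratio, len(t_scores))


def median_ratio_from_scores(
    t_scores: np.ndarray, n_scores: np.ndarray
) -> float | None:
    med_n = float(np.median(n_scores))
    if med_n == 0:
        return None
    return float(np.median(t_scores)) / med_n


def median_ratio(
    net: PDINetwork, scores: CoexpressionScores, tf: str
) -> float | None:
    """Ratio of the TF's median target co-expression to median non-target."""
    targets, non_targets = _tf_target_split(net, scores, tf)
    t = scores.scores_with(tf, targets)
    nt = scores.scores_with(tf, non_targets)
    t = t[~np.isnan(t)]
    nt = nt[~np.isnan(nt)]
    if len(t) == 0 or len(nt) == 0:
        return None
    return median_ratio_from_scores(t, nt)


def predict_all_signs(
    net: PDINetwork,
    scores: CoexpressionScores,
    min_targets: int = 10,
    alpha: float = 0.05,
) -> list[SignPrediction]:
    return [
        predict_sign(net, scores, tf, min_targets=min_targets, alpha=alpha)
        for tf in sorted(net.tf_ids)
    ]


def shuffle_null(
    net: PDINetwork,
    scores: CoexpressionScores,
    n_randomizations: int = 1000,
    seed: int = 0,
    min_targets: int = 10,
    alpha: float = 0.05,
) -> dict:
    """Expected activator/repressor counts under per-TF score shuffling.

    Each repetition permutes every TF's co-expression score vector over
    the gene universe (breaking the link between scores and target
    status) and re-runs the sign calls.  Returns observed counts, null
    count distributions, and z-scores of the observed counts.
    """
    rng = np.random.default_rng(seed)
    eligible = []
    for tf in sorted(net.tf_ids):
        if tf not in scores:
            continue
        targets, non_targets = _tf_target_split(net, scores, tf)
        t = scores.scores_with(tf, targets)
        nt = scores.scores_with(tf, non_targets)
        t = t[~np.isnan(t)]
        nt = nt[~np.isnan(nt)]
        if len(t) >= min_targets and len(nt) > 0:
            eligible.append((tf, t, nt))

    observed = {"activator": 0, "repressor": 0}
    for tf, t, nt in eligible:
        call = _call_from_scores(tf, t, nt, alpha).call
        if call in observed:
            observed[call] += 1

    null_act = np.zeros(n_randomizations, dtype=int)
    null_rep = np.zeros(n_randomizations, dtype=int)
    for k in range(n_randomizations):
        for tf, t, nt in eligible:
            pooled = np.concatenate([t, nt])
            perm = rng.permutation(pooled)
            call = _call_from_scores(tf, perm[: len(t)], perm[len(t):], alpha).call
            if call == "activator":
                null_act[k] += 1
            elif call == "repressor":
                null_rep[k] += 1

    def _z(obs: int, null: np.ndarray) -> float | None:
        sd = null.std(ddof=1) if len(null) > 1 else 0.0
        if sd == 0:
            return None
        return float((obs - null.mean()) / sd)

    return {
        "n_eligible_tfs": len(eligible),
        "observed": observed,
        "null_activators": null_act,
        "null_repressors": null_rep,
        "z_activators": _z(observed["activator"], null_act),
        "z_repressors": _z(observed["repressor"], null_rep),
        "degenerate": n_randomizations < 2
        or (null_act.std(ddof=1) == 0 and null_rep.std(ddof=1) == 0),
    }


def calibrate_null_calls(
    n_tfs: int = 500,
    n_targets: int = 30,
    n_non_targets: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """False-call rate of the sign test under the global null.

    Simulates TFs whose target and non-target co-expression scores are
    drawn from the same distribution and runs the exact call path used by
    :func:`predict_sign`; the fraction of activator/repressor calls
    estimates the two-sided type-I error at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    n_called = 0
    for i in range(n_tfs):
        t = rng.normal(size=n_targets)
        nt = rng.normal(size=n_non_targets)
        if _call_from_scores(f"tf{i}", t, nt, alpha).call != "none":
            n_called += 1
    return {"n_tfs": n_tfs, "n_called": n_called,
            "false_call_rate": n_called / n_tfs, "alpha": alpha}


# -- co-expression enrichment by shared TF profiles -----------------------


def shared_tf_coexpression_enrichment(
    net: PDINetwork,
    scores: CoexpressionScores,
    jaccard_thresholds: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4),
    top_fractions: tuple[float, ...] = (0.01, 0.05, 0.10),
    min_in_degree: int = 3,
    max_out_degree_fraction: float = 0.05,
) -> pd.DataFrame:
    """Fold-enrichment of top co-expressed pairs among high TF-profile pairs.

    Eligible promoters are bound by >= ``min_in_degree`` TFs, counting
    only TFs that bind fewer than ``max_out_degree_fraction`` of tested
    promoters (hub TFs would dominate profile similarity).  For each
    Jaccard threshold and each top co-expression fraction, the enrichment
    is P(pair in top fraction | similarity >= threshold) / P(pair in top
    fraction over all eligible pairs), with a Fisher exact p-value.
    """
    specific_tfs = {
        tf
        for tf in net.tf_ids
        if len(net.targets_of(tf)) < max_out_degree_fraction * net.n_tested_promoters
    }
    eligible_proms = sorted(
        p
        for p in net.promoter_ids
        if len(net.binders_of(p) & specific_tfs) >= min_in_degree
        and net.promoter_to_gene[p] in scores
    )
    profiles = {p: frozenset(net.binders_of(p) & specific_tfs) for p in eligible_proms}

    sims = []
    coexpr = []
    for i, pa in enumerate(eligible_proms):
        for pb in eligible_proms[i + 1:]:
            ga, gb = net.promoter_to_gene[pa], net.promoter_to_gene[pb]
            if ga == gb:
                continue
            c = scores.score(ga, gb)
            if np.isnan(c):
                continue
            a, b = profiles[pa], profiles[pb]
            sims.append(len(a & b) / len(a | b))
            coexpr.append(c)
    sims = np.array(sims)
    coexpr = np.array(coexpr)
    rows = []
    n_all = len(coexpr)
    for frac in top_fractions:
        cutoff = np.quantile(coexpr, 1 - frac) if n_all else np.nan
        in_top = coexpr >= cutoff
        for thr in jaccard_thresholds:
            high = sims >= thr
            n_high = int(high.sum())
            if n_high == 0:
                rows.append(
                    {"jaccard_threshold": thr, "top_fraction": frac,
                     "n_pairs": 0, "enrichment": np.nan, "p": np.nan,
                     "flagged_empty": True}
                )
                continue
            k = int((high & in_top).sum())
            base_rate = in_top.mean()
            enrichment = (k / n_high) / base_rate if base_rate > 0 else np.nan
            table = [
                [k, n_high - k],
                [int(in_top.sum()) - k, n_all - n_high - int(in_top.sum()) + k],
            ]
            _, p = stats.fisher_exact(table, alternative="greater")
            rows.append(
                {"jaccard_threshold": thr, "top_fraction": frac,
                 "n_pairs": n_high, "enrichment": enrichment, "p": p,
                 "flagged_empty": False}
            )
    return pd.DataFrame(rows)


# -- spatiotemporal overlap ----------------------------------------------


def _pairwise_pcc(tissue: TissueExpression, tfs: list[str],
                  genes: list[str]) -> pd.DataFrame:
    x = tissue.table.loc[tfs].to_numpy(dtype=float)
    y = tissue.table.loc[genes].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc ** 2).sum(axis=1))
    ys = np.sqrt((yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = (xc @ yc.T) / np.outer(xs, ys)
    return pd.DataFrame(pcc, index=tfs, columns=genes)


def spatiotemporal_overlap(
    net: PDINetwork,
    tissue: TissueExpression,
    percentile: float = 75.0,
) -> dict:
    """Expression-pattern overlap between interacting vs non-interacting pairs.

    Per TF-gene pair, the Pearson correlation across tissue-stage
    conditions; a pair overlaps when its PCC reaches the given percentile
    of all pair PCCs (the cutoff is recomputed from the supplied data).
    Returns the cutoff, the 2x2 classification, odds ratio, and chi-square
    p (no continuity correction).  Zero-variance profiles are skipped and
    counted.
    """
    tfs = sorted(t for t in net.tf_ids if t in tissue.table.index)
    genes = sorted(g for g in net.genes if g in tissue.table.index)
    if not tfs or not genes:
        raise ValueError("no TFs or genes with tissue expression data")
    pcc = _pairwise_pcc(tissue, tfs, genes)
    gene_targets = {t: net.target_genes_of(t) for t in tfs}
    vals = pcc.to_numpy().ravel()
    skipped = int(np.isnan(vals).sum())
    cutoff = float(np.nanpercentile(vals, percentile))
    table = np.zeros((2, 2), dtype=int)  # rows: interacting?; cols: overlap?
    for t in tfs:
        row = pcc.loc[t]
        for g in genes:
            v = row[g]
            if np.isnan(v) or g == t:
                continue
            interacting = g in gene_targets[t]
            overlap = v >= cutoff
            table[0 if interacting else 1, 0 if overlap else 1] += 1
    odds_ratio = _odds_ratio(table)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "cutoff": cutoff,
        "percentile": percentile,
        "table": table,
        "odds_ratio": odds_ratio,
        "chi2": float(chi2),
        "p": float(p),
        "n_skipped": skipped,
    }


def _odds_ratio(table: np.ndarray, haldane: bool = False) -> float:
    t = table.astype(float)
    flagged = (t == 0).any()
    if flagged and haldane:
        t = t + 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        return float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))


def per_tf_overlap_class(
    net: PDINetwork,
    tissue: TissueExpression,
    tf: str,
    percentile: float = 75.0,
    cutoff: float | None = None,
) -> dict:
    """Per-TF overlap label: does the TF overlap more with targets or not.

    The odds ratio compares overlap among the TF's targets vs its
    non-targets; OR > 1 labels the TF targets-overlap, OR < 1
    non-targets-overlap.  Zero cells get the Haldane-Anscombe 0.5
    correction (flagged).  A global ``cutoff`` may be supplied to reuse
    the network-wide percentile threshold.
    """
    if tf not in tissue.table.index:
        raise ValueError(f"TF {tf!r} has no tissue expression data")
    genes = sorted(g for g in net.genes if g in tissue.table.index and g != tf)
    targets = net.target_genes_of(tf)
    if not (set(genes) & targets):
        raise ValueError(f"TF {tf!r} has no targets with tissue data")
    pcc = _pairwise_pcc(tissue, [tf], genes).iloc[0]
    if cutoff is None:
        cutoff = float(np.nanpercentile(pcc.to_numpy(), percentile))
    table = np.zeros((2, 2), dtype=int)
    for g in genes:
        v = pcc[g]
        if np.isnan(v):
            continue
        table[0 if g in targets else 1, 0 if v >= cutoff else 1] += 1
    corrected = (table == 0).any()
    odds = _odds_ratio(table, haldane=True)
    if odds > 1:
        label = "targets-overlap"
    elif odds < 1:
        label = "non-targets-overlap"
    else:
        label = "withheld"
    return {
        "tf": tf,
        "label": label,
        "odds_ratio": odds,
        "table": table,
        "haldane_corrected": bool(corrected),
        "cutoff": cutoff,
    }


def predictions_table(predictions: list[SignPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tf": p.tf_id,
                "call": p.call,
                "p": p.p_value,
                "median_ratio": p.median_ratio,
                "n_targets": p.n_targets,
                "reason": p.reason,
            }
            for p in predictions
        ]
    )
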