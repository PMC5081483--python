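"""Bipartite protein-DNA interaction (PDI) network model and statistics.

A PDI network records binary TF -> promoter interactions from a
gene-centered screen (e.g., enhanced yeast one-hybrid).  Promoter baits
carry a quality label describing background reporter activity in yeast;
high-quality analyses are restricted to clean baits.  This module holds
the data model, edge-list I/O, bait filtering, degree statistics, the
log2-binned density matrix, Jaccard interaction-profile similarities,
and midpoint-based assignment of ChIP-style peaks to promoters.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed bait-quality labels.  Unknown labels are rejected, not coerced.
QUALITY_LABELS = frozenset(
    {"clean", "moderate_background", "high_background", "no_interactions"}
)

#: Default edge-list column names (TSV header).
EDGE_COLUMNS = ("tf_id", "promoter_id", "gene_id", "bait_quality")


class NetworkFormatError(ValueError):
    """Raised for malformed edge lists or peak/interval tables."""


class EmptyNetworkError(ValueError):
    """Raised when an operation requires a non-empty network."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    sequence_id: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise NetworkFormatError(
                f"invalid interval {self.sequence_id}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def midpoint(self) -> int:
        """Floor of the interval mean; deterministic boundary rule."""
        return (self.start + self.end) // 2

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass
class PDINetwork:
    """Binary bipartite TF -> promoter interaction network.

    ``n_tested_tfs`` / ``n_tested_promoters`` record the screen dimensions
    (how many preys/baits were assayed), which can exceed the number of
    nodes with detected interactions; out-degree fractions are expressed
    relative to promoters *tested*.
    """

    tf_ids: set[str]
    promoter_ids: set[str]
    edges: set[tuple[str, str]]
    promoter_to_gene: dict[str, str]
    bait_quality: dict[str, str]
    n_tested_tfs: int = 0
    n_tested_promoters: int = 0

    _targets: dict[str, set[str]] | None = field(
        default=None, repr=False, compare=False
    )
    _binders: dict[str, set[str]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.n_tested_tfs = max(self.n_tested_tfs, len(self.tf_ids))
        self.n_tested_promoters = max(self.n_tested_promoters, len(self.promoter_ids))
        self.validate()

    def validate(self) -> None:
        for tf, prom in self.edges:
            if tf not in self.tf_ids:
                raise NetworkFormatError(f"edge references unknown TF {tf!r}")
            if prom not in self.promoter_ids:
                raise NetworkFormatError(f"edge references unknown promoter {prom!r}")
        for prom in self.promoter_ids:
            q = self.bait_quality.get(prom)
            if q is None:
                raise NetworkFormatError(f"promoter {prom!r} has no bait-quality label")
            if q not in QUALITY_LABELS:
                raise NetworkFormatError(
                    f"unknown bait-quality label {q!r} for promoter {prom!r}"
                )

    # -- adjacency ---------------------------------------------------------

    def _build_adjacency(self) -> None:
        targets: dict[str, set[str]] = defaultdict(set)
        binders: dict[str, set[str]] = defaultdict(set)
        for tf, prom in self.edges:
            targets[tf].add(prom)
            binders[prom].add(tf)
        self._targets = dict(targets)
        self._binders = dict(binders)

    def targets_of(self, tf: str) -> set[str]:
        """Promoters bound by ``tf`` (its eY1H targets)."""
        if tf not in self.tf_ids:
            raise KeyError(f"unknown TF {tf!r}")
        if self._targets is None:
            self._build_adjacency()
        return set(self._targets.get(tf, set()))  # type: ignore[union-attr]

    def binders_of(self, promoter: str) -> set[str]:
        """TFs bound to ``promoter``."""
        if promoter not in self.promoter_ids:
            raise KeyError(f"unknown promoter {promoter!r}")
        if self._binders is None:
            self._build_adjacency()
        return set(self._binders.get(promoter, set()))  # type: ignore[union-attr]

    def target_genes_of(self, tf: str) -> set[str]:
        """Genes whose promoters are bound by ``tf``."""
        return {self.promoter_to_gene[p] for p in self.targets_of(tf)}

    @property
    def genes(self) -> set[str]:
        return {self.promoter_to_gene[p] for p in self.promoter_ids}

    def n_edges(self) -> int:
        return len(self.edges)

    def copy(self) -> "PDINetwork":
        return PDINetwork(
            tf_ids=set(self.tf_ids),
            promoter_ids=set(self.promoter_ids),
            edges=set(self.edges),
            promoter_to_gene=dict(self.promoter_to_gene),
            bait_quality=dict(self.bait_quality),
            n_tested_tfs=self.n_tested_tfs,
            n_tested_promoters=self.n_tested_promoters,
        )


@dataclass
class DegreeSummary:
    """Degree statistics of a PDI network.

    Out-degree fractions are relative to ``n_tested_promoters``.
    """

    in_degree: dict[str, int]
    out_degree: dict[str, int]
    mean_in_degree: float
    median_in_degree: float
    mean_out_degree_fraction: float
    median_out_degree_fraction: float
    fraction_tfs_below: float
    below_threshold: float


def load_edge_list(
    path,
    dialect: Mapping[str, str] | None = None,
    n_tested_tfs: int = 0,
    n_tested_promoters: int = 0,
) -> PDINetwork:
    """Read a TSV edge list into a :class:`PDINetwork`.

    ``dialect`` maps the canonical column names (``tf_id``, ``promoter_id``,
    ``gene_id``, ``bait_quality``) onto the file's actual column names.
    Duplicate edges are collapsed (interactions are binary); the number of
    collapsed rows is logged.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyNetworkError(f"empty edge-list file: {path}") from exc
    if df.empty:
        raise EmptyNetworkError(f"edge-list file has no rows: {path}")
    rename = {v: k for k, v in (dialect or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise NetworkFormatError(
            f"edge list {path} is missing columns {missing}; found {list(df.columns)}"
        )
    bad = df.loc[~df["bait_quality"].isin(QUALITY_LABELS)]
    if not bad.empty:
        row = bad.index[0]
        raise NetworkFormatError(
            f"unknown bait-quality label {bad['bait_quality'].iloc[0]!r} "
            f"at row {row} of {path}"
        )

    edges = set(zip(df["tf_id"], df["promoter_id"]))
    n_collapsed = len(df) - len(edges)
    if n_collapsed:
        logger.info("collapsed %d duplicate edge rows from %s", n_collapsed, path)

    promoter_to_gene = dict(zip(df["promoter_id"], df["gene_id"]))
    bait_quality = dict(zip(df["promoter_id"], df["bait_quality"]))
    net = PDINetwork(
        tf_ids=set(df["tf_id"]),
        promoter_ids=set(df["promoter_id"]),
        edges=edges,
        promoter_to_gene=promoter_to_gene,
        bait_quality=bait_quality,
        n_tested_tfs=n_tested_tfs,
        n_tested_promoters=n_tested_promoters,
    )
    net.n_collapsed = n_collapsed  # type: ignore[attr-defined]
    return net


def save_edge_list(net: PDINetwork, path) -> None:
    """Write the network as a canonical four-column TSV edge list."""
    rows = sorted(net.edges)
    df = pd.DataFrame(
        {
            "tf_id": [t for t, _ in rows],
            "promoter_id": [p for _, p in rows],
            "gene_id": [net.promoter_to_gene[p] for _, p in rows],
            "bait_quality": [net.bait_quality[p] for _, p in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def filter_baits(net: PDINetwork, allowed: Iterable[str]) -> PDINetwork:
    """Restrict the network to promoters whose bait quality is in ``allowed``.

    TFs and promoters left without edges are pruned.  Screen dimensions
    (``n_tested_*``) are carried over unchanged: filtering changes what is
    kept, not what was assayed.
    """
    allowed = set(allowed)
    if not allowed:
        raise ValueError("allowed quality set must be non-empty")
    unknown = allowed - QUALITY_LABELS
    if unknown:
        raise ValueError(f"unknown quality labels {sorted(unknown)}")
    keep_prom = {p for p in net.promoter_ids if net.bait_quality[p] in allowed}
    edges = {(t, p) for (t, p) in net.edges if p in keep_prom}
    tf_ids = {t for t, _ in edges}
    promoter_ids = {p for _, p in edges}
    return PDINetwork(
        tf_ids=tf_ids,
        promoter_ids=promoter_ids,
        edges=edges,
        promoter_to_gene={p: net.promoter_to_gene[p] for p in promoter_ids},
        bait_quality={p: net.bait_quality[p] for p in promoter_ids},
        n_tested_tfs=net.n_tested_tfs,
        n_tested_promoters=net.n_tested_promoters,
    )


def degree_summary(net: PDINetwork, below_threshold: float = 0.01) -> DegreeSummary:
    """Per-node degree maps and the headline degree statistics.

    ``fraction_tfs_below`` is the fraction of (detected) TFs whose
    out-degree is below ``below_threshold`` of promoters tested.
    """
    if not net.edges:
        raise EmptyNetworkError("degree_summary requires a non-empty network")
    in_deg = {p: len(net.binders_of(p)) for p in net.promoter_ids}
    out_deg = {t: len(net.targets_of(t)) for t in net.tf_ids}
    in_vals = np.array(sorted(in_deg.values()))
    out_frac = np.array(sorted(out_deg.values())) / net.n_tested_promoters
    return DegreeSummary(
        in_degree=in_deg,
        out_degree=out_deg,
        mean_in_degree=float(in_vals.mean()),
        median_in_degree=float(np.median(in_vals)),
        mean_out_degree_fraction=float(out_frac.mean()),
        median_out_degree_fraction=float(np.median(out_frac)),
        fraction_tfs_below=float(np.mean(out_frac < below_threshold)),
        below_threshold=below_threshold,
    )


def _log2_bin(value: int) -> int:
    """log2 bin index: degree d falls in bin floor(log2(d)) (d >= 1)."""
    return int(math.floor(math.log2(value)))


def density_matrix(net: PDINetwork) -> dict:
    """Density of PDIs in a log2-binned out-degree x in-degree matrix.

    Each cell holds (# edges between TFs in the out-degree bin and
    promoters in the in-degree bin) / (#TFs in bin x #promoters in bin),
    i.e., the fraction of possible interactions in the bin that occur.
    Marginals count the nodes in each bin.
    """
    if not net.edges:
        raise EmptyNetworkError("density_matrix requires a non-empty network")
    out_deg = {t: len(net.targets_of(t)) for t in net.tf_ids}
    in_deg = {p: len(net.binders_of(p)) for p in net.promoter_ids}
    tf_bin = {t: _log2_bin(d) for t, d in out_deg.items() if d > 0}
    prom_bin = {p: _log2_bin(d) for p, d in in_deg.items() if d > 0}
    tf_bins = sorted(set(tf_bin.values()))
    prom_bins = sorted(set(prom_bin.values()))
    ti = {b: i for i, b in enumerate(tf_bins)}
    pi = {b: i for i, b in enumerate(prom_bins)}

    counts = np.zeros((len(tf_bins), len(prom_bins)))
    for tf, prom in net.edges:
        counts[ti[tf_bin[tf]], pi[prom_bin[prom]]] += 1
    n_tf = np.zeros(len(tf_bins))
    for b in tf_bin.values():
        n_tf[ti[b]] += 1
    n_prom = np.zeros(len(prom_bins))
    for b in prom_bin.values():
        n_prom[pi[b]] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        density = counts / np.outer(n_tf, n_prom)
    return {
        "tf_bins": tf_bins,
        "promoter_bins": prom_bins,
        "edge_counts": counts,
        "density": density,
        "n_tfs_per_bin": n_tf,
        "n_promoters_per_bin": n_prom,
    }


def _jaccard(a: set, b: set) -> float | None:
    union = a | b
    if not union:
        return None
    return len(a & b) / len(union)


def target_profile_similarity(net: PDINetwork, tf_a: str, tf_b: str) -> float | None:
    """Jaccard index of two TFs' bound-promoter (bait) sets.

    Returns ``None`` when both TFs have zero targets (undefined).
    """
    return _jaccard(net.targets_of(tf_a), net.targets_of(tf_b))


def tf_profile_similarity(net: PDINetwork, prom_x: str, prom_y: str) -> float | None:
    """Jaccard index of two promoters' bound-TF sets."""
    return _jaccard(net.binders_of(prom_x), net.binders_of(prom_y))


def assign_peaks(
    peaks: Sequence[tuple[GenomicInterval, str]],
    promoters: Mapping[str, GenomicInterval],
    promoter_to_gene: Mapping[str, str] | None = None,
) -> PDINetwork:
    """Assign peaks (e.g., ChIP peaks) to promoters by peak midpoint.

    A peak is assigned to a promoter iff its midpoint (floor of the
    interval mean) lies within the promoter interval (half-open) on the
    same sequence.  Multiple peaks of one TF on one promoter collapse to a
    single binary interaction.
    """
    edges: set[tuple[str, str]] = set()
    for interval, tf in peaks:
        mid = interval.midpoint
        for prom_id, prom_iv in promoters.items():
            if prom_iv.sequence_id == interval.sequence_id and prom_iv.contains(mid):
                edges.add((tf, prom_id))
    tf_ids = {t for t, _ in edges}
    promoter_ids = {p for _, p in edges}
    p2g = {
        p: (promoter_to_gene[p] if promoter_to_gene else p) for p in promoter_ids
    }
    return PDINetwork(
        tf_ids=tf_ids,
        promoter_ids=promoter_ids,
        edges=edges,
        promoter_to_gene=p2g,
        bait_quality={p: "clean" for p in promoter_ids},
    )


def load_peaks(path) -> list[tuple[GenomicInterval, str]]:
    """Read BED 3+1 peaks (chrom, start, end, tf_id); no header."""
    peaks = []
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "tf_id"],
        dtype={"chrom": str, "tf_id": str},
    )
    for row in df.itertuples(index=False):
        peaks.append((GenomicInterval(row.chrom, int(row.start), int(row.end)), row.tf_id))
    return peaks


def load_promoter_intervals(path) -> dict[str, GenomicInterval]:
    """Read a promoter interval TSV (promoter_id, chrom, start, end, strand)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        out[row.promoter_id] = GenomicInterval(
            row.chrom, int(row.start), int(row.end), getattr(row, "strand", None)
        )
    return out
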