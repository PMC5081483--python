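"""Energy-based PWM scanning and elementary-motif discovery.

Scoring follows an energy scheme: for a k-mer w and a PWM, the mismatch
energy is dE(w) = sum_i [ln p_i,max - ln p_i,w_i] >= 0, and the reported
score is 1 / (1 + exp(dE)), which lies in (0, 0.5] with the consensus
word scoring exactly 0.5.  A promoter is called bound when any word in
its proximal window reaches the score threshold (binary interaction
semantics: multiple matches collapse to one).

Elementary-motif discovery compares k-mer presence between promoters
bound by a TF and promoters not bound, retaining words that pass a
one-sided hypergeometric test after Benjamini-Hochberg correction and a
fold-enrichment cutoff, then greedily stacks alignable words into
positional probability matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import PDINetwork

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AmbiguousBaseError(ValueError):
    """Raised when a k-mer contains characters outside {A,C,G,T}."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Positional base-probability matrix (4 x L, rows A,C,G,T)."""

    motif_id: str
    tf_id: str
    matrix: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (A,C,G,T)")
        if self.length < 4:
            raise ValueError("PWM must have length >= 4")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def with_pseudocount(self, pseudocount: float) -> "PWM":
        """Add a per-cell pseudocount and renormalize columns."""
        m = self.matrix + pseudocount
        m = m / m.sum(axis=0, keepdims=True)
        return PWM(self.motif_id, self.tf_id, m, pseudocount=pseudocount)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def information_content(self) -> float:
        """Total information content in bits (uniform background)."""
        p = np.clip(self.matrix, 1e-12, 1.0)
        return float((2.0 + (p * np.log2(p)).sum(axis=0)).sum())


@dataclass
class ScanConfig:
    """Promoter-scanning parameters.

    The score threshold lives in (0, 0.5] (0.5 is a perfect match); the
    proximal window is measured from the 3' end of the supplied promoter
    sequence (promoters conventionally end at the start codon / TSS).
    TFs whose motif hits more than ``non_specific_fraction`` of promoters
    are treated as non-specific.
    """

    threshold: float = 0.09
    window: int = 500
    non_specific_fraction: float = 0.5
    both_strands: bool = True
    pseudocount: float = 0.001

    def __post_init__(self) -> None:
        if not (0 < self.threshold <= 0.5):
            raise ValueError("threshold must be in (0, 0.5]")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0 < self.non_specific_fraction <= 1):
            raise ValueError("non_specific_fraction must be in (0, 1]")


@dataclass
class ElementaryMotif:
    """A k-mer enriched among bound vs unbound promoters."""

    consensus: str
    positive_frequency: float
    negative_frequency: float
    enrichment: float
    fdr: float
    matrix: np.ndarray = field(repr=False)
    members: list[str] = field(default_factory=list)

    def as_pwm(self, tf_id: str = "") -> PWM:
        return PWM(motif_id=f"em_{self.consensus}", tf_id=tf_id, matrix=self.matrix)


def _encode_seq(seq: str) -> np.ndarray:
    seq = seq.upper()
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(codes.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[codes == ord(b)] = i
    return out


def pwm_energy_score(pwm: PWM, kmer: str) -> float:
    """Score a single k-mer against a PWM; consensus scores exactly 0.5."""
    if len(kmer) != pwm.length:
        raise ValueError(f"k-mer length {len(kmer)} != PWM length {pwm.length}")
    idx = _encode_seq(kmer)
    if (idx < 0).any():
        raise AmbiguousBaseError(f"ambiguous base in k-mer {kmer!r}")
    logp = np.log(pwm.matrix)
    d_e = float((logp.max(axis=0) - logp[idx, np.arange(pwm.length)]).sum())
    return 1.0 / (1.0 + np.exp(d_e))


def _window_scores(pwm: PWM, encoded: np.ndarray) -> np.ndarray:
    """Energy scores of all windows of an encoded sequence (vectorized)."""
    L = pwm.length
    n = encoded.size - L + 1
    if n <= 0:
        return np.empty(0)
    logp = np.log(pwm.matrix)
    penalty = logp.max(axis=0)[None, :] - logp  # 4 x L mismatch energies
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    valid = (windows >= 0).all(axis=1)
    d_e = np.full(n, np.inf)
    if valid.any():
        w = windows[valid]
        d_e[valid] = penalty[w, np.arange(L)[None, :]].sum(axis=1)
    return 1.0 / (1.0 + np.exp(d_e))


def scan_promoter(pwm: PWM, promoter: str, config: ScanConfig) -> dict:
    """Scan the proximal window of a promoter with one PWM.

    Returns ``{"bound": bool, "best_score": float, "hits": [(pos, strand)]}``
    with positions relative to the window start.  The bound flag is binary
    regardless of the number of matches.
    """
    pw = pwm.with_pseudocount(config.pseudocount) if config.pseudocount else pwm
    window_seq = promoter[-config.window:] if len(promoter) > config.window else promoter
    if len(window_seq) < pw.length:
        logger.warning(
            "promoter window shorter than motif (%d < %d); not bound",
            len(window_seq), pw.length,
        )
        return {"bound": False, "best_score": 0.0, "hits": []}
    enc = _encode_seq(window_seq)
    scores_fwd = _window_scores(pw, enc)
    hits = [(int(i), "+") for i in np.nonzero(scores_fwd >= config.threshold)[0]]
    best = float(scores_fwd.max()) if scores_fwd.size else 0.0
    if config.both_strands:
        enc_rc = _encode_seq(reverse_complement(window_seq))
        scores_rev = _window_scores(pw, enc_rc)
        n = len(window_seq) - pw.length
        hits += [(int(n - i), "-") for i in np.nonzero(scores_rev >= config.threshold)[0]]
        if scores_rev.size:
            best = max(best, float(scores_rev.max()))
    return {"bound": bool(hits), "best_score": best, "hits": sorted(hits)}


def predicted_network(
    pwms: list[PWM],
    promoters: dict[str, str],
    config: ScanConfig,
    promoter_to_gene: dict[str, str] | None = None,
) -> tuple[PDINetwork, list[str]]:
    """Motif-predicted PDI network over retained (specific) TFs.

    TFs whose motif hits more than ``config.non_specific_fraction`` of the
    promoter set are removed as non-specific and reported separately.
    """
    if not pwms or not promoters:
        raise ValueError("need at least one PWM and one promoter")
    prom_ids = sorted(promoters)
    hits_by_tf: dict[str, set[str]] = {}
    for pwm in pwms:
        bound = {
            pid for pid in prom_ids
            if scan_promoter(pwm, promoters[pid], config)["bound"]
        }
        # one TF may carry several motifs; union their hits
        hits_by_tf.setdefault(pwm.tf_id, set()).update(bound)
    removed = [
        tf for tf, hit in sorted(hits_by_tf.items())
        if len(hit) > config.non_specific_fraction * len(prom_ids)
    ]
    edges = {
        (tf, pid)
        for tf, hit in hits_by_tf.items()
        if tf not in removed
        for pid in hit
    }
    tf_ids = {t for t, _ in edges}
    promoter_ids = {p for _, p in edges}
    net = PDINetwork(
        tf_ids=tf_ids,
        promoter_ids=promoter_ids,
        edges=edges,
        promoter_to_gene={
            p: (promoter_to_gene.get(p, p) if promoter_to_gene else p)
            for p in promoter_ids
        },
        bait_quality={p: "clean" for p in promoter_ids},
    )
    return net, removed


# -- elementary-motif discovery ------------------------------------------


def _present_kmers(seq: str, k: int, both_strands: bool) -> set[str]:
    """Canonical k-mer presence set for one sequence."""
    seq = seq.upper()
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(c not in _BASE_INDEX for c in w):
            continue
        out.add(w)
        if both_strands:
            out.add(reverse_complement(w))
    return out


def _align_offset(seed: str, other: str, min_overlap: int) -> tuple[int, str] | None:
    """Best ungapped alignment of ``other`` (either strand) onto ``seed``.

    Returns (offset, oriented_word) for the offset with the longest exact
    overlap >= ``min_overlap``, or None if no orientation/offset qualifies.
    """
    k = len(seed)
    best: tuple[int, int, str] | None = None  # (overlap, offset, word)
    for word in (other, reverse_complement(other)):
        for off in range(-(k - min_overlap), k - min_overlap + 1):
            lo = max(0, off)
            hi = min(k, off + k)
            if hi - lo < min_overlap:
                continue
            if all(seed[i] == word[i - off] for i in range(lo, hi)):
                overlap = hi - lo
                if best is None or overlap > best[0]:
                    best = (overlap, off, word)
    if best is None:
        return None
    return best[1], best[2]


def _stack_matrix(seed: str, members: list[tuple[int, str, float]]) -> np.ndarray:
    """Weighted base-count matrix over the seed span from aligned members."""
    k = len(seed)
    counts = np.zeros((4, k))
    for off, word, weight in members:
        for i in range(k):
            j = i - off
            if 0 <= j < len(word):
                counts[_BASE_INDEX[word[j]], i] += weight
    counts += 0.25  # pseudocount keeps probabilities positive
    return counts / counts.sum(axis=0, keepdims=True)


def discover_motifs(
    positives: list[str],
    negatives: list[str],
    k: int = 8,
    fdr_cutoff: float = 0.05,
    enr_cutoff: float = 2.0,
    min_positives: int = 50,
    window: int = 500,
    both_strands: bool = True,
) -> list[ElementaryMotif]:
    """Discover elementary motifs enriched in bound vs unbound promoters.

    Presence/absence of each k-mer per proximal promoter window is tested
    with a one-sided hypergeometric test (positives as draws), corrected
    by Benjamini-Hochberg; words with FDR < ``fdr_cutoff`` and fold
    enrichment > ``enr_cutoff`` are retained and greedily clustered
    (exact ungapped overlap >= k-2) into probability matrices.  Requires
    at least ``min_positives`` bound promoters to avoid low-quality motifs.
    """
    if not (6 <= k <= 10):
        raise ValueError("k must be in [6, 10]")
    if len(positives) < min_positives:
        raise ValueError(
            f"need >= {min_positives} bound promoters, got {len(positives)}"
        )
    pos_sets = [_present_kmers(s[-window:], k, both_strands) for s in positives]
    neg_sets = [_present_kmers(s[-window:], k, both_strands) for s in negatives]
    n_pos, n_neg = len(pos_sets), len(neg_sets)

    pos_count: dict[str, int] = {}
    for s in pos_sets:
        for w in s:
            pos_count[w] = pos_count.get(w, 0) + 1
    neg_count: dict[str, int] = {}
    for s in neg_sets:
        for w in s:
            neg_count[w] = neg_count.get(w, 0) + 1

    words = sorted(w for w, c in pos_count.items() if c >= 2)
    if not words:
        return []
    cp = np.array([pos_count[w] for w in words])
    cn = np.array([neg_count.get(w, 0) for w in words])
    # hypergeometric upper tail: of n_pos draws from n_pos+n_neg promoters
    # with cp+cn carrying the word, observing >= cp carriers among positives
    pvals = stats.hypergeom.sf(cp - 1, n_pos + n_neg, cp + cn, n_pos)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    pos_freq = cp / n_pos
    neg_freq = cn / n_neg
    # pseudo-frequency guard: one phantom carrier in the unbound set
    enrichment = pos_freq / np.maximum(neg_freq, 1.0 / (n_neg + 1))

    keep = (fdr < fdr_cutoff) & (enrichment > enr_cutoff)
    retained = sorted(
        (
            (words[i], pos_freq[i], neg_freq[i], enrichment[i], fdr[i], pvals[i])
            for i in np.nonzero(keep)[0]
        ),
        key=lambda r: (r[5], -r[3], r[0]),
    )

    motifs: list[ElementaryMotif] = []
    unassigned = list(retained)
    while unassigned:
        seed = unassigned.pop(0)
        members = [(0, seed[0], seed[1])]
        member_words = [seed[0]]
        rest = []
        for cand in unassigned:
            aligned = _align_offset(seed[0], cand[0], k - 2)
            if aligned is not None:
                off, word = aligned
                members.append((off, word, cand[1]))
                member_words.append(cand[0])
            else:
                rest.append(cand)
        unassigned = rest
        motifs.append(
            ElementaryMotif(
                consensus=seed[0],
                positive_frequency=float(seed[1]),
                negative_frequency=float(seed[2]),
                enrichment=float(seed[3]),
                fdr=float(seed[4]),
                matrix=_stack_matrix(seed[0], members),
                members=member_words,
            )
        )
    return motifs


# -- MEME minimal motif format I/O ---------------------------------------


def read_meme(path) -> list[PWM]:
    """Read PWMs from a MEME minimal motif file (Bio.motifs parser)."""
    from Bio import motifs as bio_motifs

    with open(path) as handle:
        records = bio_motifs.parse(handle, "minimal")
    out = []
    for rec in records:
        mat = np.array([rec.pwm[b] for b in BASES])
        mat = mat / mat.sum(axis=0, keepdims=True)
        name = rec.name or rec.consensus
        out.append(PWM(motif_id=str(name), tf_id=str(name), matrix=mat))
    return out


def write_meme(pwms: list[PWM], path) -> None:
    """Write PWMs in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            # large nsites keeps parsers that convert probabilities to
            # integer counts from destroying precision on the round trip
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                f"nsites= 1000000 E= 0\n"
            )
            for col in pwm.matrix.T:
                fh.write(" " + " ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def motif_summary_table(motifs: list[ElementaryMotif]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "consensus": m.consensus,
                "positive_frequency": m.positive_frequency,
                "negative_frequency": m.negative_frequency,
                "enrichment": m.enrichment,
                "fdr": m.fdr,
                "n_members": len(m.members),
            }
            for m in motifs
        ]
    )
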