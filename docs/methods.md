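# Methods

This note records the models, parameter choices, numerical conventions,
and known limitations of `pdinet`. It documents what the code computes
and why each open design point was resolved the way it was; every number
quoted as an outcome here is produced by the test suite or by
`scripts/acceptance.py`, not asserted independently.

## The PDI network model

A gene-centered screen yields binary TF → promoter interactions. The
network object stores, besides nodes and edges, the screen dimensions
(`n_tested_tfs`, `n_tested_promoters`): TF out-degree *fractions* are
expressed relative to promoters **tested**, not promoters with detected
interactions, because a TF's reach is a property of the assay space.
Repeated detections collapse to one binary edge; the loader logs the
number of collapsed duplicates.

Bait quality takes one of four fixed labels (`clean`,
`moderate_background`, `high_background`, `no_interactions`); unknown
labels are rejected rather than coerced, since a silent coercion would
contaminate the high-quality network. High-quality analyses restrict to
clean baits: background-prone baits produce spurious reporter activity
and inflate in-degree, which is exactly what the synthetic generator
plants on its `high_background` baits so that filtering has a measurable
effect.

Genomic coordinates are 0-based half-open. A peak is assigned to a
promoter iff its midpoint — `floor((start+end)/2)` — lies inside the
promoter interval; the floor-and-half-open convention is arbitrary but
deterministic and testable, and multiple peaks of one TF on one promoter
collapse to a single interaction, matching the binary edge semantics.

Interaction-profile similarity is the Jaccard index — of bound-promoter
sets for two TFs (the basis of the redundancy network) or of bound-TF
sets for two promoters (the basis of the co-expression enrichment
analysis). Comparing two nodes that both have zero edges is undefined
and returns a designated no-value rather than 0 or 1.

## Degree-preserving randomization

The null model for "is this overlap larger than degree structure alone
explains?" is edge switching: repeatedly draw two edges (t₁,p₁), (t₂,p₂)
uniformly and rewire to (t₁,p₂), (t₂,p₁) iff neither rewired edge exists.
Every TF keeps its out-degree and every promoter its in-degree exactly —
asserted on every randomization in the tests. The number of attempts per
randomization is `swap_attempts_factor × |E|` with default factor 100;
the mixing schedule is not a property of the method being emulated, so
it is configurable, and the default was chosen for practical mixing on
networks of 10²–10⁴ edges (the acceptance calibration uses factors
15–20 on small networks, where mixing is faster).

Overlap significance reports the observed shared-edge count on the
common node sets, the null mean/sd over the randomized ensemble, the
z-score with a one-sided upper-tail normal p (the enrichment direction
is the scientific claim), and an empirical p
`(1 + #{null ≥ obs})/(1 + n)` that remains valid when the normal
approximation is doubtful. A zero-variance null is flagged degenerate
instead of producing an infinite z. Calibration: when the scanned
network is itself a degree-matched random draw independent of the
reference, the empirical p rejects at 3.8–4.2% at nominal 5% over 500
repetitions (slightly conservative because overlap counts are discrete).

## Energy-based PWM scanning

A k-mer w is scored against a 4×L probability matrix by the mismatch
energy ΔE(w) = Σᵢ [ln pᵢ,max − ln pᵢ,wᵢ] ≥ 0 and reported as the logistic
transform s = 1/(1+e^ΔE) ∈ (0, 0.5], so the consensus word scores exactly
0.5 and the score decreases monotonically as positions move to
lower-probability bases. This reproduces the published score range and
semantics of energy-based scanners; a fitted chemical-potential variant
is *not* reproduced (no binding data to fit), so numerical identity with
any particular external implementation is not claimed, and counts that
depend on it (e.g., how many TFs a 50% non-specific rule removes on real
data) are treated as data-dependent.

Conventions: promoter sequences follow the promoterome orientation
(5'→3', ending at the ATG/TSS), so the proximal window is the 3'-most
500 bp. Both strands are scanned by default (configurable); binding is
binary — any window word at or above the 0.09 threshold marks the
promoter bound. A pseudocount of 0.001 per matrix cell (renormalized)
prevents −∞ energies on zero entries and is negligible elsewhere. TFs
whose motif hits more than 50% of the supplied promoters are removed as
non-specific.

## Elementary-motif discovery

For a TF with ≥ 50 bound promoters, each 8-mer's **presence** (either
strand) in the proximal windows of bound vs unbound promoters is tested
with a one-sided hypergeometric test and BH-corrected; words with
FDR < 0.05 and fold enrichment > 2 (with a one-phantom-carrier guard on
the unbound frequency) are retained. Presence/absence rather than
occurrence counts matches the binary interaction semantics and is a
deliberate simplification of seed-and-extend motif finders; retained
words are greedily clustered (exact ungapped overlap ≥ k−2, either
strand, best offset) and stacked into probability matrices weighted by
bound-set frequency. The ≥ 50-positives rule guards against low-quality
motifs from small positive sets and is enforced with a refusal, not a
warning. `k` defaults to 8 (the elementary word length of seed-based
motif finders) and is configurable in [6, 10].

## Co-expression integration and sign inference

The compendium-integration formula is a documented stand-in chosen where
the emulated procedure defers to prior work without equations: within
each high-confidence dataset (≥ 4 experiments), Pearson correlation of
log2(x+1) expression; across datasets, a Fisher-z average weighted by
(n_experiments − 3), back-transformed. The interface isolates this
scorer so an alternative can be swapped. Noise filters: genes in fewer
than 25 high-confidence datasets are dropped, as are genes ranked in the
lowest expression decile (rank-based: the ⌊0.1·n⌋ lowest mean-expression
genes of a dataset) in more than half of the high-confidence datasets
that contain them.

Sign calls use a two-sided Mann–Whitney U comparing the TF's scores with
its bound targets vs all other scored network genes (the "non-target"
universe is the scored genes mapping to network promoters — the
assayed space — minus the TF itself), direction read from the rank-sum.
Two-sided was chosen because the procedure claims significance in either
direction; the exact-vs-midrank tie handling follows scipy, and the
implementation is checked against full permutation enumeration for
group sizes ≤ 8. TFs need ≥ 10 scored targets and compendium coverage to
be called. Bifunctional TFs are structurally uncallable by this
comparison (their positive and negative targets cancel); the call set is
{activator, repressor, none}. The chance-level call count comes from
shuffling each TF's score vector over genes (1,000 repetitions in the
emulated design; desk-scale runs use 100–500) and the observed counts
are summarized as z-scores against that null.

Spatiotemporal overlap: per TF–gene pair, Pearson correlation across the
11 tissue–stage conditions; a pair "overlaps" when its PCC reaches the
75th percentile of all pair PCCs. The cutoff is always recomputed from
the supplied data (on the study's own inputs it would be a data value,
≈ 0.29 there; on the synthetic world it comes out ≈ 0.23) — it is never
hard-coded. The interacting-vs-non-interacting contingency is tested by
chi-square without continuity correction; per-TF labels use the odds
ratio with Haldane–Anscombe 0.5 correction (flagged) on zero cells.

## Cofactor signs, concordance, GO scan

Cofactor classification is rule-based: only co-activator partners →
activator; only co-repressor partners → repressor; both → bifunctional;
neither → unclassified. Group statistics compare per-TF cofactor-PPI
fractions between predicted activators and repressors with an unpaired
two-tailed t-test (identical constant groups yield p = 1 by convention
rather than NaN). Concordance over TFs with ≥ 2 evidence sources counts
a TF discordant only when sources assert strictly opposite signs;
bifunctional is compatible with either.

GO associations use a flat term → gene-set model (no graph propagation).
The filter cascade runs in order: TFs with out-degree < 10 (underpowered)
or > 150 (non-specific hubs) out; terms with < 10 or > 200 annotated
network targets out; among terms annotating identical target sets one is
kept by a seeded draw (the dedup choice cannot change the association
count, since identical target sets give identical p — asserted in a
test). The test universe is the genes of all promoters in the filtered
network, not the genome: enrichment should be judged against what the
screen could have found, and this avoids annotation-coverage bias. The
headline multiple-testing control is the hard p < 0.001 cutoff plus the
randomized-network null (the emulated design's rule); a BH-adjusted
column is emitted alongside. The detox-enzyme-style analysis is exposed
as a generic gene-set membership enrichment plus a two-proportion family
composition test.

## TF association network

Nodes are TFs with ≥ 3 targets; edges connect pairs with target-profile
Jaccard ≥ 0.2, threshold inclusive (a pair at exactly 0.2 is connected).
The "proportion comparison test" for essentiality vs connectivity is
interpreted as a pooled two-proportion z-test on the fraction of
connected (degree ≥ 1) vs isolated TFs in each group — the cut is
configurable because the emulated analysis plots a distribution without
stating one, and connected-vs-isolated is the least arbitrary reading; a
Fisher exact variant is emitted alongside for small counts. Family
statistics compare each family against all other TFs (Mann–Whitney on
degree; two-proportion z on essential fraction), skipping families with
fewer than 3 members.

## The synthetic world

The generator emulates the statistical structure the analyses rely on,
not any real genome. Defaults are the standard conditions used by every
test: 60 TFs × 600 promoters; TF out-degree mixes ~10% hubs (140–157
intended targets), signed TFs at exactly 30 targets, paralogs at 12, and
a 2–5 background — after bait filtering the top decile of TFs carries
more than half of all edges (heavy tail); planted 8-bp motifs with
consensus-base probability 0.95 (information content ≈ 13 bits)
inserted at rate 0.9 into non-overlapping slots of the proximal window
of each intended target (slotting avoids overwrites, so motif presence
is exactly Bernoulli(0.9) per intended edge); the emitted screen is the
motif-placement network minus 10% dropout plus 3% false-positive edges,
plus 5 spurious interactions on each of the 6% high-background baits.
Expression: 55 datasets (50 high-confidence with 8 experiments, 5 with
3), activator targets generated as ρ·TF + √(1−ρ²)·noise with ρ = 0.5 on
log scale (repressors −0.5), per-gene baseline log2-expression
N(6.5, 0.8); planted signal genes are floored one sd below the mean so
the decile noise filter acts only on the planted dim genes; sparse and
dim gene sets exercise the coverage and noise filters. Tissue profiles
use the same ±0.5 coupling over 11 labelled conditions. Cofactor
partners match planted signs with fidelity 0.9; GO terms over-sample
25 of a coherent TF's targets plus 10 random genes; 4 paralog pairs
share 70% of targets and a 1-position-perturbed copy of one PWM, are
non-essential, and sit inside an expanded low-essentiality family that
draws targets from a shared promoter pool — essentiality is
anti-correlated with planted redundancy by construction.

A single root seed fans out through `numpy.random.SeedSequence` to
per-component child seeds, so components can be regenerated
independently and the whole world is bit-identical across processes
(random draws never iterate unordered sets). Background sequence is
order-0 uniform — adequate for presence/absence motif statistics; it
does not emulate real base composition, promoter length distributions,
or the correlation structure of real expression compendia, so passing
tests demonstrate the machinery's correctness and calibration, not
performance on real screens (where effect sizes are smaller and noise
is structured).

## Problem sizes and numerical choices

Desk-scale runs use reduced ensembles chosen as the package's own
defaults for development-scale data: 100–500 edge-switch randomizations
for overlap nulls (the full design uses 20,000), 200 randomized networks
for the GO null (vs 1,000), 100–500 score shuffles (vs 1,000). The
statistics these ensembles feed are z-scores of effects that sit tens of
standard deviations from their nulls on planted data, so ensemble size
affects precision of the null mean, not any conclusion. Ties in rank
tests use midranks with tie-corrected normal approximation (scipy);
Fisher tests use the exact hypergeometric tail; correlations of
zero-variance vectors contribute 0 (co-expression) or are skipped and
counted (tissue PCC). Fisher-z values are clipped at |r| ≤ 0.999999
before averaging.

## Known limitations

- The energy scanner matches the published score *description* exactly
  but not necessarily any particular binary's internals; thresholds like
  "45 of 121 TFs removed as non-specific" are data- and
  implementation-dependent and are not reproduced.
- Elementary-motif discovery implements the elementary (seed) stage
  only — no extension, clustering across TFs, or motif–motif comparison.
- The co-expression scorer is a principled stand-in, not a reproduction
  of any specific compendium's published scores.
- Bifunctional TFs cannot be called from co-expression; only the
  cofactor route can label them.
- GO terms are flat sets; no ancestor closure is applied, so term
  granularity follows the supplied annotation exactly.
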