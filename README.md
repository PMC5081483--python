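# pdinet — gene-centered protein–DNA interaction network analysis

`pdinet` implements the analysis framework behind gene-centered
protein–DNA interaction (PDI) mapping, where a library of transcription
factors (TFs) is screened against a library of gene-promoter "baits"
(as in enhanced yeast one-hybrid screens) to produce a binary bipartite
TF → promoter network. The package takes such a network — together with
promoter sequences, position weight matrices (PWMs), an expression
compendium, tissue expression profiles, TF–cofactor protein interactions,
GO annotations, and essentiality/family labels — and derives the
downstream biology:

- **Network quality and structure** — bait-quality filtering, in/out-degree
  statistics, a log2-binned PDI density matrix, and Jaccard interaction-profile
  similarities between TFs (shared targets) or promoters (shared binders).
- **Degree-preserving nulls** — edge-switching randomization that preserves
  every node's degree exactly, and z-score significance of the overlap
  between the screen network and a reference interaction set (motif-predicted
  or ChIP-derived networks).
- **Motif machinery** — energy-based PWM scanning of proximal promoter
  windows (score `s = 1/(1+e^{ΔE})` with mismatch energy
  `ΔE = Σᵢ [ln pᵢ,max − ln pᵢ,wᵢ]`, so a perfect match scores exactly 0.5;
  bound iff any window word reaches the 0.09 threshold within the proximal
  500 bp), and de-novo elementary-motif discovery: 8-mers enriched in bound
  vs unbound promoters (hypergeometric test, BH-FDR < 0.05, enrichment > 2,
  ≥ 50 target promoters required).
- **Activator/repressor inference** — gene-pair co-expression scores from a
  compendium of expression datasets (per-dataset Pearson on log2 scale,
  Fisher-z average weighted by n−3 across high-confidence datasets); a TF
  whose co-expression with its bound targets is significantly higher
  (two-sided Mann–Whitney U, α = 0.05, ≥ 10 scored targets) than with
  non-targets is called an activator, lower a repressor; expected chance
  calls come from a per-TF score-shuffle null.
- **Cofactor-based signs and concordance** — a TF interacting only with
  co-activators (mediator subunits, TAFs) is a predicted activator, only
  with co-repressors (Groucho-like factors, HDACs) a repressor, with both
  bifunctional; cross-source concordance is reported for TFs with evidence
  from two or more sources.
- **TF–GO associations** — a Fisher-exact scan over (TF, biological-process
  term) pairs after a filter cascade (TF out-degree in [10, 150], term size
  in [10, 200] network targets, duplicate terms deduplicated), associations
  at p < 0.001, and an edge-switched-network null for the expected count.
- **TF redundancy** — an association network connecting TFs whose
  target-profile Jaccard similarity is ≥ 0.2 (nodes: TFs with ≥ 3 targets),
  with essentiality-vs-connectivity and per-family statistics.

Because real screen data are large and external, the package ships a
first-class **synthetic-data generator** (`pdinet.synthetic`): a seeded
world with a heavy-tailed out-degree distribution, bait-quality artifacts,
planted binding motifs, planted activator/repressor correlations, planted
GO-coherent TFs, sign-consistent cofactor interactions, and non-essential
paralog pairs — so every stage of the pipeline is verifiable against known
ground truth.

## Worked example

Generate the standard world and run the analysis sequence:

```bash
python analysis/01_simulate_world.py      # emit all inputs to results/world/
python analysis/02_network_statistics.py  # degrees, density matrix
python analysis/03_overlap_significance.py
python analysis/05_sign_inference.py
```

which prints (seed 1):

```
screen edges 1413 -> clean-bait network 1037 edges, 58 TFs, 447 genes
mean in-degree 2.32 (median 2)
top decile of TFs carries 56.0% of edges

predicted network: 1498 edges over 60 TFs (0 non-specific removed)
observed overlap 664 vs null 142.6 +/- 8.8  (z = 59.2, p_normal = 0)

calls: 8 activators, 5 repressors (of 20 testable TFs)
shuffle null: activators z = 10.8, repressors z = 6.0
spatiotemporal overlap: cutoff PCC >= 0.23 (75th percentile), OR = 1.49
```

Reading: after removing background-prone baits the screen network keeps a
heavy-tailed TF out-degree (a few hub TFs carry most interactions); the
motif-predicted network overlaps the screen network ~4.7× above the
degree-preserving null (z ≈ 59), and the co-expression sign calls recover
exactly the planted 8 activators and 5 repressors, far above the
score-shuffle expectation. Scripts `04`–`08` continue with motif
discovery, cofactor signs, GO associations, and the redundancy network.

The same stages are available as a library (`import pdinet`), through the
orchestrated pipeline (`pdinet.pipeline.run_pipeline`), or from the shell:

```bash
pdinet --out-dir out report --synthetic --seed 1 --overlap-randomizations 500
```

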