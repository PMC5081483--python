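#!/usr/bin/env python
"""Activator/repressor inference from TF-target co-expression.

Builds the weighted Fisher-z co-expression scores from the emitted
compendium, calls each eligible TF activator or repressor by comparing
its co-expression with targets vs non-targets (two-sided rank test,
alpha 0.05, >= 10 scored targets), contrasts the observed call counts
with the per-TF score-shuffle null, and adds the tissue-level
spatiotemporal overlap statistics.
"""

from pathlib import Path

import pandas as pd

from pdinet.expression import (
    TissueExpression,
    build_coexpression,
    load_compendium,
    predict_all_signs,
    predictions_table,
    shuffle_null,
    spatiotemporal_overlap,
)
from pdinet.network import filter_baits, load_edge_list

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    net = load_edge_list(ROOT / "world" / "network.tsv", n_tested_promoters=600)
    clean = filter_baits(net, {"clean"})
    compendium = load_compendium(ROOT / "world" / "compendium" / "manifest.tsv")
    scores = build_coexpression(compendium)
    print(f"co-expression scores for {len(scores.genes)} genes "
          f"({sum(ds.high_confidence for ds in compendium.datasets)} "
          "high-confidence datasets)")

    preds = predict_all_signs(clean, scores)
    n_act = sum(p.call == "activator" for p in preds)
    n_rep = sum(p.call == "repressor" for p in preds)
    print(f"calls: {n_act} activators, {n_rep} repressors "
          f"(of {sum(p.p_value is not None for p in preds)} testable TFs)")
    predictions_table(preds).to_csv(ROOT / "sign_predictions.tsv",
                                    sep="\t", index=False)

    null = shuffle_null(clean, scores, n_randomizations=500, seed=21)
    print(f"shuffle null: activators z = {null['z_activators']:.1f}, "
          f"repressors z = {null['z_repressors']:.1f} "
          f"(null means {null['null_activators'].mean():.1f} / "
          f"{null['null_repressors'].mean():.1f})")

    tissue = TissueExpression(
        pd.read_csv(ROOT / "world" / "tissue.tsv", sep="\t", index_col=0)
    )
    st = spatiotemporal_overlap(clean, tissue)
    print(f"spatiotemporal overlap: cutoff PCC >= {st['cutoff']:.2f} "
          f"(75th percentile), OR = {st['odds_ratio']:.2f}, "
          f"chi-square p = {st['p']:.2g}")


if __name__ == "__main__":
    main()
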