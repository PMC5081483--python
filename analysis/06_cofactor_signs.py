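#!/usr/bin/env python
"""Regulatory-sign classification from TF-cofactor protein interactions.

Classifies each TF by its cofactor partners (only co-activators ->
activator; only co-repressors -> repressor; both -> bifunctional),
compares cofactor-PPI fractions between the co-expression-predicted
activator and repressor groups, and reports cross-source concordance.
"""

from pathlib import Path

import pandas as pd

from pdinet.annotation import (
    EvidenceTable,
    classify_all_by_cofactors,
    cofactor_fraction_stats,
    concordance,
    load_cofactor_ppi,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ppi = load_cofactor_ppi(ROOT / "world" / "cofactor_ppi.tsv")
    labels = classify_all_by_cofactors(ppi)
    counts = pd.Series(labels).value_counts()
    print("cofactor-based classification:", dict(counts))
    pd.DataFrame(sorted(labels.items()), columns=["tf", "cofactor_call"]).to_csv(
        ROOT / "cofactor_calls.tsv", sep="\t", index=False
    )

    sign_preds = pd.read_csv(ROOT / "sign_predictions.tsv", sep="\t")
    sign_by_tf = dict(zip(sign_preds["tf"], sign_preds["call"]))
    stats = cofactor_fraction_stats(ppi, sign_by_tf)
    t = stats["table"]
    for group in ("activator", "repressor"):
        sub = t[t["sign"] == group]
        if not sub.empty:
            print(f"{group}s: mean co-activator PPI fraction "
                  f"{sub['coactivator_fraction'].mean():.2f}, "
                  f"co-repressor {sub['corepressor_fraction'].mean():.2f}")
    print(f"activators vs repressors, co-activator fraction: "
          f"t-test p = {stats['p_coactivator']:.2g}")

    evidence = {}
    for tf, cof in labels.items():
        ev = {}
        if cof != "unclassified":
            ev["cofactor"] = cof
        coex = sign_by_tf.get(tf, "none")
        if coex not in ("none", float("nan")) and isinstance(coex, str):
            ev["coexpression"] = coex
        if ev:
            evidence[tf] = ev
    conc = concordance(EvidenceTable(evidence))
    print(f"concordance across sources: "
          f"{100 * conc['fraction_concordant']:.0f}% of "
          f"{conc['n_multi_source']} multi-source TFs")


if __name__ == "__main__":
    main()
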