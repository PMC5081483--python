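#!/usr/bin/env python
"""TF association (redundancy) network and its essentiality/family structure.

Connects TFs whose target-profile Jaccard similarity is >= 0.2 (nodes:
TFs with >= 3 clean-bait targets), then asks whether non-essential TFs
are more connected than essential TFs (redundancy masking loss of one
member) and how connectivity and essentiality differ across families.
"""

from pathlib import Path

import pandas as pd

from pdinet.association import (
    build_association_network,
    essentiality_connectivity,
    family_stats,
    save_association_network,
)
from pdinet.network import filter_baits, load_edge_list

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    net = load_edge_list(ROOT / "world" / "network.tsv", n_tested_promoters=600)
    clean = filter_baits(net, {"clean"})
    labels = pd.read_csv(ROOT / "world" / "tf_labels.tsv", sep="\t")
    family = dict(zip(labels["tf_id"], labels["family"]))
    essential = dict(zip(labels["tf_id"], labels["essential"].astype(bool)))

    assoc = build_association_network(clean, family=family, essential=essential)
    print(f"association network: {len(assoc.nodes)} TFs, "
          f"{assoc.graph.number_of_edges()} edges (similarity >= 0.2)")

    ec = essentiality_connectivity(assoc)
    print(f"connected fraction: non-essential "
          f"{ec['fraction_high_non_essential']:.2f} vs essential "
          f"{ec['fraction_high_essential']:.2f} "
          f"(two-proportion z = {ec['z']:.2f}, p = {ec['p']:.3g}; "
          f"Fisher p = {ec['p_fisher']:.3g})")

    fam = family_stats(assoc)
    print(fam.to_string(index=False))
    fam.to_csv(ROOT / "family_stats.tsv", sep="\t", index=False)
    save_association_network(assoc, ROOT / "association_edges.tsv",
                             ROOT / "association_nodes.tsv")


if __name__ == "__main__":
    main()
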