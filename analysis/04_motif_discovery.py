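#!/usr/bin/env python
"""De novo elementary-motif discovery from each well-connected TF's targets.

For every TF with >= 50 clean-bait targets, compares 8-mer presence in
its target promoters' proximal windows against unbound promoters and
reports the enriched elementary motifs, checking the top consensus
against the planted truth motif.
"""

from pathlib import Path

from Bio import SeqIO

from pdinet.motifs import discover_motifs, motif_summary_table, read_meme, \
    reverse_complement, write_meme
from pdinet.network import filter_baits, load_edge_list

ROOT = Path(__file__).resolve().parent.parent / "results"


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def main() -> None:
    net = load_edge_list(ROOT / "world" / "network.tsv", n_tested_promoters=600)
    clean = filter_baits(net, {"clean"})
    promoters = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(ROOT / "world" / "promoters.fasta", "fasta")
    }
    truth = {p.tf_id: p for p in read_meme(ROOT / "world" / "truth_motifs.meme")}

    rows = []
    discovered = []
    for tf in sorted(clean.tf_ids):
        targets = clean.targets_of(tf)
        if len(targets) < 50:
            continue
        pos = [promoters[p] for p in sorted(targets)]
        neg = [promoters[p] for p in sorted(set(promoters) - targets)]
        motifs = discover_motifs(pos, neg, k=8)
        if not motifs:
            print(f"{tf}: no elementary motif (n={len(pos)})")
            continue
        top = motifs[0]
        true_cons = truth[tf].consensus
        dist = min(hamming(top.consensus, true_cons),
                   hamming(reverse_complement(top.consensus), true_cons))
        print(f"{tf}: top motif {top.consensus} "
              f"(enrichment {top.enrichment:.1f}, FDR {top.fdr:.2g}, "
              f"Hamming to truth = {dist})")
        table = motif_summary_table(motifs).assign(tf=tf)
        rows.append(table)
        m = top.as_pwm(tf)
        m.motif_id = f"discovered_{tf}"
        discovered.append(m)

    if rows:
        import pandas as pd

        pd.concat(rows).to_csv(ROOT / "discovered_motifs.tsv",
                               sep="\t", index=False)
    write_meme(discovered, ROOT / "discovered_motifs.meme")


if __name__ == "__main__":
    main()
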