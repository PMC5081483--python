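#!/usr/bin/env python
"""Overlap between the screen network and the motif-predicted network.

Scans the proximal 500 bp of every promoter with each TF's PWM (energy
score threshold 0.09, non-specific TFs removed), builds the predicted
binary network, and tests the overlap with the screen network against
the degree-preserving edge-switch null.
"""

from pathlib import Path

from Bio import SeqIO

from pdinet.motifs import ScanConfig, predicted_network, read_meme
from pdinet.network import filter_baits, load_edge_list
from pdinet.randomize import RandomizationConfig, overlap_significance, save_null_samples

ROOT = Path(__file__).resolve().parent.parent / "results"
N_RANDOMIZATIONS = 500  # desk-scale stand-in for an exhaustive ensemble


def main() -> None:
    net = load_edge_list(ROOT / "world" / "network.tsv", n_tested_promoters=600)
    clean = filter_baits(net, {"clean"})
    promoters = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(ROOT / "world" / "promoters.fasta", "fasta")
    }
    pwms = read_meme(ROOT / "world" / "truth_motifs.meme")

    predicted, removed = predicted_network(pwms, promoters, ScanConfig())
    print(f"predicted network: {predicted.n_edges()} edges over "
          f"{len(predicted.tf_ids)} TFs ({len(removed)} non-specific removed)")

    cfg = RandomizationConfig(n_randomizations=N_RANDOMIZATIONS,
                              swap_attempts_factor=50, seed=11)
    res = overlap_significance(clean, predicted, cfg)
    print(f"observed overlap {res.observed} vs null "
          f"{res.null_mean:.1f} +/- {res.null_sd:.1f}  "
          f"(z = {res.z:.1f}, p_normal = {res.p_normal:.3g})")
    res.to_frame().to_csv(ROOT / "overlap_significance.tsv", sep="\t", index=False)
    save_null_samples(res, ROOT / "overlap_null_samples.tsv")


if __name__ == "__main__":
    main()
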