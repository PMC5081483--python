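#!/usr/bin/env python
"""Generate the standard synthetic screen and emit all its input datasets.

Writes the complete set of standard-format inputs (edge list, promoter
FASTA, truth motifs, expression compendium, tissue matrix, cofactor PPIs,
GO annotations, TF labels, ground-truth manifest) under results/world/,
and prints the world's headline composition.
"""

from pathlib import Path

from pdinet.synthetic import WorldParams, emit_datasets, generate_world

OUT = Path(__file__).resolve().parent.parent / "results" / "world"
SEED = 1


def main() -> None:
    params = WorldParams(seed=SEED)
    world = generate_world(params)
    manifest = emit_datasets(world, OUT)

    n_signed = sum(1 for s in world.signs.values() if s != "none")
    print(f"world seed {SEED}: {params.n_tfs} TFs x {params.n_promoters} promoters")
    print(f"  emitted screen edges : {world.network.n_edges()}")
    print(f"  motif-truth edges    : {len(world.motif_truth_edges)}")
    print(f"  signed TFs (act/rep) : {n_signed} "
          f"({sum(1 for s in world.signs.values() if s == 'activator')}/"
          f"{sum(1 for s in world.signs.values() if s == 'repressor')})")
    print(f"  paralog pairs        : {len(world.paralog_pairs)}")
    print(f"  planted GO terms     : {len(world.planted_associations)}")
    print(f"  datasets emitted     : {len(manifest)} -> {OUT}")


if __name__ == "__main__":
    main()
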