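#!/usr/bin/env python
"""Simulate model genomes and kit-like sequencing libraries.

Generates two synthetic bacterial genomes — a low-GC genome (~33%,
staphylococcal-like) and a mid-GC genome (~50%, enterobacterial-like) —
and, for each, per-base depth tracks from three library chemistries:

  * tagmentation-like: logistic suppression of low-GC windows
    (the transposase insertion-bias signature),
  * pcr-like: mild suppression at both GC extremes,
  * pcr-free: uniform, unbiased coverage.

Writes FASTA + samtools-depth TSV pairs under results/simulated/, which
scripts 02-03 profile.  Fragment mode is used so the depth files look like
real pileups (reads spanning positions), at 50x mean depth.
"""

import json
from pathlib import Path

from gcbias.simulate import (
    BiasFunction,
    bimodal_landscape,
    generate_genome,
    simulate_coverage,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 20240901

GENOMES = {
    # (total length, dominant GC modes, full GC range)
    "lowgc": dict(total_length=600_000, gc_modes=(0.30, 0.36), gc_range=(0.25, 0.45)),
    "midgc": dict(total_length=600_000, gc_modes=(0.46, 0.54), gc_range=(0.38, 0.62)),
}

KITS = {
    "tagmentation": BiasFunction.logistic_low_gc(g0=0.40, s=0.03, floor=0.2),
    "pcr": BiasFunction.extreme_suppression(center=0.5, width=0.18, depth=0.35),
    "pcr_free": BiasFunction.uniform(),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": SEED, "mean_depth": 50.0, "datasets": []}
    for gi, (gname, kw) in enumerate(GENOMES.items()):
        genome = generate_genome(
            bimodal_landscape(seed=SEED + gi, **kw), contig_id=gname
        )
        fasta = OUT / f"{gname}.fasta"
        with open(fasta, "w") as fh:
            fh.write(f">{genome.contig_id}\n")
            for i in range(0, genome.length, 80):
                fh.write(genome.bases[i : i + 80] + "\n")
        for ki, (kit, bias) in enumerate(KITS.items()):
            track = simulate_coverage(
                genome, 50.0, bias, mode="fragment", read_length=150,
                seed=SEED + 100 + 10 * gi + ki,
            )
            depth = OUT / f"{gname}.{kit}.depth.tsv"
            with open(depth, "w") as fh:
                for pos, d in enumerate(track.depth, start=1):
                    fh.write(f"{gname}\t{pos}\t{d:g}\n")
            manifest["datasets"].append(
                {"genome": gname, "kit": kit, "fasta": fasta.name,
                 "depth": depth.name, "bias_family": bias.family}
            )
            print(f"wrote {depth.name} (mean depth {track.depth.mean():.1f}x)")
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2))


if __name__ == "__main__":
    main()
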