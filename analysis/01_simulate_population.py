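#!/usr/bin/env python
"""Simulate the default XY population and write its on-disk artifacts.

Generates 25 males + 25 females over three autosomal scaffolds and an X
scaffold carrying 21 Mb PAR1 / 71 Mb HRX / 19 Mb PAR2, then writes the VCF,
the sample->sex map, the ground-truth region BED and a scaffold-length table
under results/.
"""
import sys
from pathlib import Path

from sexscan import SimConfig, simulate_population, write_regions_bed, write_sex_map, write_vcf

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    sim = simulate_population(SimConfig(seed=seed))
    write_vcf(sim.table, RESULTS / "population.vcf", layout=sim.layout)
    write_sex_map(sim.sex_map, RESULTS / "population.sex.tsv")
    write_regions_bed(sim.layout.regions, RESULTS / "population.truth.bed")
    with open(RESULTS / "scaffold_lengths.tsv", "w") as fh:
        for s, l in sim.layout.scaffolds:
            fh.write(f"{s}\t{l}\n")
    print(
        f"simulated {sim.table.n_sites} SNPs x {sim.table.n_samples} samples "
        f"(seed {seed}); truth spans: "
        + ", ".join(f"{r.label} {r.start}-{r.end}" for r in sim.layout.regions)
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
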