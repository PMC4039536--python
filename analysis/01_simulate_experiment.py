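#!/usr/bin/env python
"""Simulate the HU BrdU-IP-Seq experiment: WT and rif1Δ, two replicates each.

Writes the small inputs (genome tables, origin annotation, ground truth) under
results/sim/ and the large fragment BEDs under scratch/sim/.
"""

import argparse
import shutil
from pathlib import Path

from repliscape.config import AnalysisConfig
from repliscape.pipeline import ExperimentDesign, build_genome_and_origins, hu_regimes
from repliscape.simulate import simulate_experiment


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--scratch-dir", type=Path, default=Path("scratch/sim"))
    args = ap.parse_args()

    design = ExperimentDesign()
    config = AnalysisConfig(seed=args.seed)
    layout, origins, truth = build_genome_and_origins(args.seed, design)
    import numpy as np

    sim_seed = int(np.random.SeedSequence(args.seed).spawn(3)[2].generate_state(1)[0] % (2**31))
    simulate_experiment(
        layout, origins, truth, hu_regimes(design),
        n_replicates=design.n_replicates, seed=sim_seed,
        bin_width=config.bin_width, out_dir=args.scratch_dir,
    )
    args.out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("genome.chrom.sizes", "centromeres.tsv", "origins.tsv", "truth.tsv"):
        shutil.copy(args.scratch_dir / name, args.out_dir / name)

    n_reg = int(truth.table.regulated.sum())
    print(f"simulated {design.n_chrom} chromosomes x {design.chrom_length/1e3:.0f} kb, "
          f"{len(origins)} origins ({n_reg} Rif1-regulated in truth)")
    print(f"fragment BEDs ({design.n_replicates} reps x 2 strains x {design.depth:,} "
          f"fragments) -> {args.scratch_dir}")
    print(f"genome/origin/truth tables -> {args.out_dir}")


if __name__ == "__main__":
    main()
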