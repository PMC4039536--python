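#!/usr/bin/env python
"""Genomic-landscape statistics of the classified origins: pericentric and
subtelomeric class tables, mean CEN distance per class with Welch t-tests,
and overlap with a synthetic binding-site table.

In this simulation origins are placed independently of centromeres, so these
tables exercise and document the machinery rather than recover biology."""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from repliscape.config import AnalysisConfig
from repliscape.landscape import (
    mean_distance_by_class,
    overlap_with_sites,
    proximity_class_counts,
)
from repliscape.pipeline import ExperimentDesign, run_hu_experiment


def synthetic_site_table(layout, n_sites, seed):
    """Random ORF/intergenic binding-site windows (synthetic stand-in for a
    published binding dataset, which is not redistributable here)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sites):
        chrom = rng.choice(layout.names)
        if rng.random() < 0.6:
            start = int(rng.integers(0, layout.length(chrom) - 3000))
            end = start + int(rng.integers(300, 3000))
            rows.append((f"orf{i}", "ORF", chrom, start, end, start, end))
        else:
            start = int(rng.integers(0, layout.length(chrom) - 4000))
            end = start + int(rng.integers(500, 4000))
            if rng.random() < 0.5:
                ws, we = start, min(end, start + 1000)
            else:
                ws, we = max(start, end - 1000), end
            rows.append((f"ig{i}", "intergenic", chrom, start, end, ws, we))
    return pd.DataFrame(
        rows, columns=["name", "feature_type", "chrom", "start", "end", "win_start", "win_end"]
    )


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    config = AnalysisConfig(seed=args.seed)
    hu = run_hu_experiment(args.seed, ExperimentDesign(), config)
    cl = hu.classification
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for landmark in ("CEN", "TEL"):
        table = proximity_class_counts(cl, hu.layout, landmark, config.landmark_threshold)
        table.to_csv(args.out_dir / f"proximity_{landmark.lower()}.tsv", sep="\t", index=False)
        within = table["within"].sum()
        per_class = ", ".join(
            f"{c} {w}" for c, w in zip(table["class"], table["within"])
        )
        print(f"{within} origins within {config.landmark_threshold // 1000} kb of a "
              f"{landmark}; per class: {per_class}")

    summary, pairs = mean_distance_by_class(cl, hu.layout, config.landmark_threshold)
    summary.to_csv(args.out_dir / "cen_distance_by_class.tsv", sep="\t", index=False)
    pairs.to_csv(args.out_dir / "cen_distance_tests.tsv", sep="\t", index=False)
    for c, n, mean in zip(summary["class"], summary["n"], summary["mean_distance"]):
        print(f"mean CEN distance, {c}: {mean / 1000:.0f} kb (n={n})")

    sites = synthetic_site_table(hu.layout, 400, args.seed + 7)
    overlap = overlap_with_sites(cl, sites, config, hu.layout, exclude_subtelomeric=True)
    overlap.to_csv(args.out_dir / "site_overlap.tsv", sep="\t", index=False)
    total = overlap.set_index("class").loc["all"]
    print(f"binding-site overlap (subtelomeric origins excluded): "
          f"{total.proximal}/{total.n} origins within 1 kb windows of a site")


if __name__ == "__main__":
    main()
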