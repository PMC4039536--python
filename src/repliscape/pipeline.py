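"""End-to-end experiment presets: simulation through classification.

The default design is a desk-scale model of the yeast experiment: 16
chromosomes of 600 kb (~9.6 Mb; the real genome is ~12 Mb), 288 origins at
least 20 kb apart, half early (μ = 10 min) and half late (μ = 35 min), 75% of
late origins Rif1-regulated (advanced by Δ = 20 min in rif1Δ), σ = 4 min
firing-time noise, and two replicate libraries of 2x10^5 fragments per
strain. The HU arm harvests at 45 min with 50 bp/min forks and a 2x stretch
of the firing program; the timepoint arms harvest unperturbed S-phase
(1500 bp/min forks) at 25 and 35 min.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .core import BinnedTrack, FragmentSet, GenomeLayout, Origin
from .differential import differential_analysis
from .landscape import MetaProfile, assign_trep_quartiles, metaprofile
from .peaks import Peak, call_peaks, peaks_to_origins
from .simulate import (
    RIF1D,
    WT,
    SimRegime,
    SimTruth,
    make_sim_genome,
    place_origins,
    simulate_experiment,
)
from .tracks import (
    average_and_resmooth,
    bin_fragments,
    match_scale,
    median_smooth,
    pooled_counts,
    quantile_normalize,
)

__all__ = [
    "ExperimentDesign",
    "build_genome_and_origins",
    "hu_regimes",
    "timepoint_regimes",
    "strain_track",
    "call_origins",
    "HUResult",
    "run_hu_experiment",
    "TimepointResult",
    "run_timepoint_experiment",
]


@dataclass(frozen=True)
class ExperimentDesign:
    n_chrom: int = 16
    chrom_length: int = 600_000
    n_origins: int = 288
    early_fraction: float = 0.5
    mu_early: float = 10.0
    mu_late: float = 35.0
    regulated_late_fraction: float = 0.75
    delta: float = 20.0
    sigma: float = 4.0
    depth: int = 200_000
    timepoint_depth: int = 1_000_000
    n_replicates: int = 2
    fragment_length: int = 200
    background_rate: float = 0.05
    hu_t_harvest: float = 45.0
    hu_fork_speed: float = 50.0
    hu_time_scale: float = 2.0
    s_fork_speed: float = 1500.0


def build_genome_and_origins(
    seed: int, design: ExperimentDesign = ExperimentDesign()
) -> tuple[GenomeLayout, list[Origin], SimTruth]:
    genome_seed, origin_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(2)
    ]
    layout = make_sim_genome(design.n_chrom, design.chrom_length, genome_seed)
    origins, truth = place_origins(
        layout,
        design.n_origins,
        design.early_fraction,
        design.mu_early,
        design.mu_late,
        design.regulated_late_fraction,
        design.delta,
        origin_seed,
    )
    return layout, origins, truth


def _common(design: ExperimentDesign) -> dict:
    return dict(
        sigma=design.sigma,
        delta=design.delta,
        background_rate=design.background_rate,
        depth=design.depth,
        fragment_length=design.fragment_length,
    )


def hu_regimes(design: ExperimentDesign = ExperimentDesign()) -> list[SimRegime]:
    kw = dict(
        t_harvest=design.hu_t_harvest,
        fork_speed=design.hu_fork_speed,
        time_scale=design.hu_time_scale,
        **_common(design),
    )
    return [SimRegime.hu(WT, **kw), SimRegime.hu(RIF1D, **kw)]


def timepoint_regimes(
    t_harvest: float, design: ExperimentDesign = ExperimentDesign()
) -> list[SimRegime]:
    # the timepoint arms emulate the dense tiling-array profiles, hence the
    # deeper per-library coverage than the HU sequencing arm
    kw = dict(fork_speed=design.s_fork_speed, **_common(design))
    kw["depth"] = design.timepoint_depth
    return [SimRegime.timepoint(WT, t_harvest, **kw), SimRegime.timepoint(RIF1D, t_harvest, **kw)]


def strain_track(
    fragment_sets: Sequence[FragmentSet],
    layout: GenomeLayout,
    config: AnalysisConfig,
) -> BinnedTrack:
    """Replicates -> binned -> smoothed -> quantile-normalized -> averaged track."""
    binned = [bin_fragments(fs, layout, config.bin_width) for fs in fragment_sets]
    smoothed = [median_smooth(t, config.smooth_window) for t in binned]
    normalized = quantile_normalize(smoothed)
    return average_and_resmooth(normalized, config.smooth_window)


def call_origins(
    fragment_sets: Sequence[FragmentSet],
    origins: Sequence[Origin],
    layout: GenomeLayout,
    config: AnalysisConfig,
) -> tuple[set[str], list[Peak], int]:
    """Pool replicates, call peaks, keep origins a peak aligns with."""
    raw = pooled_counts(fragment_sets, layout, config.bin_width)
    peaks = call_peaks(raw, layout, config)
    called, discarded = peaks_to_origins(peaks, origins, config, layout)
    return called, peaks, discarded


@dataclass
class HUResult:
    layout: GenomeLayout
    origins: list[Origin]
    truth: SimTruth
    fragments: dict[str, list[FragmentSet]]
    called: dict[str, set[str]]
    union_origins: list[Origin]
    classification: pd.DataFrame


def run_hu_experiment(
    seed: int,
    design: ExperimentDesign = ExperimentDesign(),
    config: Optional[AnalysisConfig] = None,
    out_dir=None,
) -> HUResult:
    """Simulate the HU arm and run it through peak calling and classification."""
    config = config or AnalysisConfig()
    layout, origins, truth = build_genome_and_origins(seed, design)
    sim_seed = int(np.random.SeedSequence(seed).spawn(3)[2].generate_state(1)[0] % (2**31))
    fragments = simulate_experiment(
        layout, origins, truth, hu_regimes(design),
        n_replicates=design.n_replicates, seed=sim_seed,
        bin_width=config.bin_width, out_dir=out_dir,
    )
    called = {
        strain: call_origins(reps, origins, layout, config)[0]
        for strain, reps in fragments.items()
    }
    union_names = called[WT] | called[RIF1D]
    union_origins = [o for o in origins if o.name in union_names]
    classification = differential_analysis(fragments, union_origins, config, layout, wt_label=WT)
    return HUResult(layout, origins, truth, fragments, called, union_origins, classification)


@dataclass
class TimepointResult:
    layout: GenomeLayout
    origins: list[Origin]
    truth: SimTruth
    quartiles: dict[str, int]
    tracks: dict[tuple[float, str], BinnedTrack]  # (t_harvest, strain) -> display track
    profiles: dict[tuple[float, str, int], MetaProfile]  # (t, strain, quartile)


def run_timepoint_experiment(
    seed: int,
    design: ExperimentDesign = ExperimentDesign(),
    config: Optional[AnalysisConfig] = None,
    t_harvests: Sequence[float] = (25.0, 35.0),
) -> TimepointResult:
    """Simulate fixed-timepoint arms and build T_Rep-quartile metaprofiles.

    Within a timepoint, the rif1Δ track is brought onto the WT scale with a
    shared high-signal anchor (see ``tracks.match_scale``), so quartile
    profiles are comparable across strains.
    """
    config = config or AnalysisConfig()
    layout, origins, truth = build_genome_and_origins(seed, design)
    quartiles = assign_trep_quartiles(origins)
    by_quartile = {q: [o for o in origins if quartiles[o.name] == q] for q in (1, 2, 3, 4)}

    t_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(4 + len(t_harvests))[4:]
    ]
    tracks: dict[tuple[float, str], BinnedTrack] = {}
    profiles: dict[tuple[float, str, int], MetaProfile] = {}
    for t_h, t_seed in zip(t_harvests, t_seeds):
        fragments = simulate_experiment(
            layout, origins, truth, timepoint_regimes(t_h, design),
            n_replicates=design.n_replicates, seed=t_seed, bin_width=config.bin_width,
        )
        wt_track = strain_track(fragments[WT], layout, config)
        mut_track = match_scale(strain_track(fragments[RIF1D], layout, config), wt_track)
        tracks[(t_h, WT)] = wt_track
        tracks[(t_h, RIF1D)] = mut_track
        for strain, track in ((WT, wt_track), (RIF1D, mut_track)):
            for q, group in by_quartile.items():
                profiles[(t_h, strain, q)] = metaprofile(
                    track, group, config.profile_window, label=f"t{t_h:g}_{strain}_Q{q}"
                )
    return TimepointResult(layout, origins, truth, quartiles, tracks, profiles)
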