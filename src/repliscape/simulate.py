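"""Synthetic BrdU-IP-Seq experiments for WT and rif1Δ cells.

The generator emulates population-level BrdU incorporation in synchronized
cells released into S-phase, either arrested in hydroxyurea (HU) or harvested
at a fixed timepoint:

* each origin ``o`` fires at a Normal(μ_o, σ) time truncated at 0 (minutes
  after release), independently across cells and origins;
* a fork from a fired origin moves at speed ``v`` (bp/min), so position ``x``
  is replicated in the fraction of cells where some origin fired early enough
  for a fork to reach it by the harvest time ``t_h``;
* origins combine as independent rescuers, ``1 - Π_o (1 - f_o(x))``, which
  reproduces passive replication of dormant origins without per-cell fork
  bookkeeping;
* sequencing draws fragment start bins multinomially from the expected
  density (replicated fraction plus a uniform background).

HU is modeled as a harvest-time cutoff with slow forks plus a stretch of the
firing program (``time_scale``): dNTP depletion both slows forks ~30-fold and
dilates firing times, so an origin with characteristic time μ fires near
``time_scale * μ`` minutes after release into HU. With the defaults
(μ_early = 10, μ_late = 35, t_h = 45, time_scale = 2) early origins fire well
before harvest while late origins effectively do not — the HU-arrest
phenotype. In rif1Δ, each Rif1-regulated late origin has its μ advanced by Δ.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr  # standard normal CDF, vectorized

from .core import BinnedTrack, FragmentSet, GenomeLayout, Origin
from . import io as rio

__all__ = [
    "SimRegime",
    "SimTruth",
    "make_sim_genome",
    "place_origins",
    "replicated_fraction_profile",
    "sample_fragments",
    "simulate_experiment",
]

WT = "WT"
RIF1D = "rif1d"
CENTROMERE_WIDTH = 120


@dataclass(frozen=True)
class SimRegime:
    """One strain x condition arm of the simulated experiment.

    fork_speed is in bp/min, times in minutes, background_rate in fragments
    per kb of unreplicated DNA (relative to a fully replicated kb), depth in
    fragments per replicate library.
    """

    label: str  # WT or rif1d
    arrest: str  # "HU" or "timepoint"
    t_harvest: float
    fork_speed: float
    sigma: float = 4.0
    delta: float = 20.0
    time_scale: float = 1.0
    background_rate: float = 0.05
    depth: int = 200_000
    fragment_length: int = 200

    def __post_init__(self) -> None:
        if self.label not in (WT, RIF1D):
            raise ValueError(f"regime label must be {WT!r} or {RIF1D!r}")
        if self.arrest not in ("HU", "timepoint"):
            raise ValueError("arrest mode must be 'HU' or 'timepoint'")
        if self.fork_speed <= 0:
            raise ValueError("fork speed must be positive")
        if self.sigma < 0 or self.delta < 0:
            raise ValueError("sigma and delta must be non-negative")
        if self.t_harvest <= 0:
            raise ValueError("harvest time must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.time_scale <= 0:
            raise ValueError("time_scale must be positive")

    @classmethod
    def hu(cls, label: str, *, t_harvest: float = 45.0, fork_speed: float = 50.0,
           time_scale: float = 2.0, **kw) -> "SimRegime":
        """HU arrest: slow forks, firing program stretched ~2x."""
        return cls(label, "HU", t_harvest, fork_speed, time_scale=time_scale, **kw)

    @classmethod
    def timepoint(cls, label: str, t_harvest: float, *, fork_speed: float = 1500.0,
                  **kw) -> "SimRegime":
        """Unperturbed S-phase harvested at a fixed time after release."""
        return cls(label, "timepoint", t_harvest, fork_speed, **kw)


@dataclass
class SimTruth:
    """Ground truth for parameter recovery: per-origin firing parameters.

    ``table`` has one row per origin: name, mu_wt, mu_mut, regulated.
    Regulated origins are Rif1-repressed in truth: mu_wt - mu_mut = delta.
    """

    table: pd.DataFrame
    delta: float

    def __post_init__(self) -> None:
        need = {"name", "mu_wt", "mu_mut", "regulated"}
        if not need <= set(self.table.columns):
            raise ValueError(f"truth table needs columns {sorted(need)}")
        t = self.table
        if (t["mu_wt"] < 0).any() or (t["mu_mut"] < 0).any():
            raise ValueError("firing times must be non-negative")
        reg = t["regulated"].to_numpy(bool)
        if not np.allclose((t["mu_wt"] - t["mu_mut"])[reg], self.delta):
            raise ValueError("regulated origins must satisfy mu_wt - mu_mut == delta")
        if not (t["mu_wt"][~reg] == t["mu_mut"][~reg]).all():
            raise ValueError("unregulated origins must have identical mu in both strains")

    def mu_for(self, label: str) -> pd.Series:
        col = "mu_wt" if label == WT else "mu_mut"
        return self.table.set_index("name")[col]

    def regulated_names(self) -> set[str]:
        return set(self.table.loc[self.table["regulated"], "name"])

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, delta: float) -> "SimTruth":
        return cls(pd.read_csv(path, sep="\t", dtype={"name": str}), delta)


def make_sim_genome(n_chrom: int, chrom_length: int, seed: int) -> GenomeLayout:
    """Equal-length chromosomes with one seeded 120 bp centromere each."""
    if n_chrom < 1:
        raise ValueError("need at least one chromosome")
    if chrom_length < 100_000:
        raise ValueError("chromosomes must be at least 100 kb")
    rng = np.random.default_rng(seed)
    chromosomes = [(f"chr{i + 1:02d}", chrom_length) for i in range(n_chrom)]
    centromeres = {}
    for name, length in chromosomes:
        start = int(rng.integers(CENTROMERE_WIDTH, length - 2 * CENTROMERE_WIDTH))
        centromeres[name] = (start, start + CENTROMERE_WIDTH)
    return GenomeLayout(chromosomes, centromeres)


def place_origins(
    layout: GenomeLayout,
    n_origins: int,
    early_fraction: float,
    mu_early: float,
    mu_late: float,
    regulated_late_fraction: float,
    delta: float,
    seed: int,
    min_spacing: int = 20_000,
    origin_width: int = 300,
) -> tuple[list[Origin], SimTruth]:
    """Scatter origins with >= ``min_spacing`` bp between midpoints and assign
    each a WT firing time in {mu_early, mu_late}; a seeded subset of late
    origins is Rif1-regulated (mu advanced by ``delta`` in rif1Δ).

    t_rep of each returned Origin is set to its WT μ so downstream timing-
    quartile analyses have a timing source.
    """
    if mu_early >= mu_late:
        raise ValueError("mu_early must be smaller than mu_late")
    if not (0.0 <= early_fraction <= 1.0 and 0.0 <= regulated_late_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    n_chrom = len(layout.chromosomes)
    if n_origins < 2 * n_chrom:
        raise ValueError("need at least two origins per chromosome")
    rng = np.random.default_rng(seed)

    base, extra = divmod(n_origins, n_chrom)
    per_chrom = [base + (1 if i < extra else 0) for i in range(n_chrom)]
    margin = origin_width
    midpoints: list[tuple[str, int]] = []
    for (name, length), k in zip(layout.chromosomes, per_chrom):
        usable = length - 2 * margin - (k - 1) * min_spacing
        if usable <= 0:
            raise ValueError(
                f"{name}: cannot place {k} origins {min_spacing} bp apart in {length} bp"
            )
        u = np.sort(rng.uniform(0.0, usable, size=k))
        pos = (margin + u + np.arange(k) * min_spacing).astype(int)
        midpoints.extend((name, int(p)) for p in pos)

    n_early = int(round(early_fraction * n_origins))
    order = rng.permutation(n_origins)
    early_idx = set(order[:n_early].tolist())
    late_idx = [i for i in range(n_origins) if i not in early_idx]
    n_regulated = int(round(regulated_late_fraction * len(late_idx)))
    regulated_idx = set(
        rng.choice(late_idx, size=n_regulated, replace=False).tolist() if n_regulated else []
    )

    origins: list[Origin] = []
    rows = []
    for i, (chrom, mid) in enumerate(midpoints):
        name = f"ORI{i + 1:03d}"
        mu_wt = mu_early if i in early_idx else mu_late
        regulated = i in regulated_idx
        mu_mut = mu_wt - delta if regulated else mu_wt
        if mu_mut < 0:
            raise ValueError("delta drives a regulated origin's firing time below 0")
        half = origin_width // 2
        origins.append(Origin(name, chrom, mid - half, mid + half, "confirmed", float(mu_wt)))
        rows.append((name, float(mu_wt), float(mu_mut), regulated))
    truth = SimTruth(pd.DataFrame(rows, columns=["name", "mu_wt", "mu_mut", "regulated"]), delta)
    return origins, truth


def _firing_cdf(tau: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """P(firing time <= tau) for Normal(mu, sigma) truncated at 0."""
    tau = np.asarray(tau, dtype=float)
    if sigma == 0.0:
        return ((tau >= mu) & (tau >= 0.0)).astype(float)
    lo = ndtr(-mu / sigma)
    f = (ndtr((tau - mu) / sigma) - lo) / (1.0 - lo)
    return np.clip(np.where(tau < 0.0, 0.0, f), 0.0, 1.0)


def replicated_fraction_profile(
    layout: GenomeLayout,
    origins: Sequence[Origin],
    truth: SimTruth,
    regime: SimRegime,
    bin_width: int = 50,
) -> BinnedTrack:
    """Deterministic expected BrdU density per bin under a regime.

    A position x is replicated by origin o in the fraction of cells where o
    fired by ``t_h - |x - mid(o)| / v``; origins combine as
    ``1 - Π (1 - f_o)``. The density adds a uniform background of
    ``background_rate * bin_width / 1000`` per bin.
    """
    mu = truth.mu_for(regime.label)
    sigma_eff = regime.sigma * regime.time_scale
    track = BinnedTrack.zeros(layout, bin_width)
    by_chrom: dict[str, list[Origin]] = {}
    for o in origins:
        by_chrom.setdefault(o.chrom, []).append(o)
    background = regime.background_rate * bin_width / 1000.0
    for chrom, n in layout.n_bins(bin_width).items():
        centers = np.arange(n) * bin_width + bin_width / 2.0
        log_not = np.zeros(n)
        for o in by_chrom.get(chrom, []):
            tau = regime.t_harvest - np.abs(centers - o.midpoint) / regime.fork_speed
            f = _firing_cdf(tau, float(mu[o.name]) * regime.time_scale, sigma_eff)
            with np.errstate(divide="ignore"):
                log_not += np.log1p(-f)
        replicated = -np.expm1(log_not)
        track.data[chrom] = replicated + background
    return track


def sample_fragments(
    density_profile: BinnedTrack,
    depth: int,
    fragment_length: int,
    seed: int,
    layout: GenomeLayout,
) -> FragmentSet:
    """Draw exactly ``depth`` fragments with start bins ~ Multinomial(density)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    density_profile.validate(layout)
    order = layout.names
    dens = density_profile.concat(order)
    total = dens.sum()
    if total <= 0:
        raise ValueError("density is all zero")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, dens / total)
    bw = density_profile.bin_width
    offsets = rng.integers(0, bw, size=depth)

    chroms_out: list[np.ndarray] = []
    starts_out: list[np.ndarray] = []
    ends_out: list[np.ndarray] = []
    pos = 0
    taken = 0
    for chrom in order:
        n = len(density_profile.data[chrom])
        c = counts[pos : pos + n]
        pos += n
        k = int(c.sum())
        if k == 0:
            continue
        bins = np.repeat(np.arange(n), c)
        starts = bins * bw + offsets[taken : taken + k]
        taken += k
        length = layout.length(chrom)
        starts = np.minimum(np.maximum(starts, 0), max(length - fragment_length, 1))
        ends = np.minimum(starts + fragment_length, length)
        chroms_out.append(np.full(k, chrom, dtype=object))
        starts_out.append(starts)
        ends_out.append(ends)
    df = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms_out),
            "start": np.concatenate(starts_out).astype(int),
            "end": np.concatenate(ends_out).astype(int),
        }
    )
    return FragmentSet(df, layout)


def _safe_label(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", label)


def simulate_experiment(
    layout: GenomeLayout,
    origins: Sequence[Origin],
    truth: SimTruth,
    regimes: Sequence[SimRegime],
    n_replicates: int = 2,
    seed: int = 0,
    bin_width: int = 50,
    out_dir: Optional[str | Path] = None,
) -> dict[str, list[FragmentSet]]:
    """Simulate replicate fragment libraries for each regime.

    Replicate seeds are spawned deterministically from the master seed. When
    ``out_dir`` is given, fragment BEDs, the origin table, the genome tables
    and the truth TSV are written alongside.
    """
    if not regimes:
        raise ValueError("need at least one regime")
    labels = [r.label for r in regimes]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate regime labels")
    children = np.random.SeedSequence(seed).spawn(len(regimes) * n_replicates)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    out: dict[str, list[FragmentSet]] = {}
    for ri, regime in enumerate(regimes):
        density = replicated_fraction_profile(layout, origins, truth, regime, bin_width)
        reps = []
        for j in range(n_replicates):
            s = child_seeds[ri * n_replicates + j]
            reps.append(sample_fragments(density, regime.depth, regime.fragment_length, s, layout))
        out[regime.label] = reps
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rio.write_chrom_sizes(layout, out_dir / "genome.chrom.sizes")
        rio.write_centromeres(layout, out_dir / "centromeres.tsv")
        rio.write_origin_table(origins, out_dir / "origins.tsv")
        truth.write_tsv(out_dir / "truth.tsv")
        for label, reps in out.items():
            for j, fs in enumerate(reps, start=1):
                rio.write_fragments_bed(fs, out_dir / f"{_safe_label(label)}_rep{j}.bed")
    return out
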