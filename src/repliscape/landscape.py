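"""Timing-quartile metaprofiles and genomic-landscape statistics.

Covers the positional analyses of origin regulation: T_Rep quartile
metaprofiles of BrdU signal centered on origin midpoints, pericentric /
subtelomeric proximity tabulation per regulation class (within 20 kb of a
centromere or chromosome end), mean centromere distance per class with
pairwise Welch t-tests after excluding pericentric and subtelomeric origins,
and overlap of origin windows with binding-site windows.

Interval conventions: edge-gap distance (0 on any overlap), half-open
intervals throughout, "within X kb" means distance <= X kb. Telomere
landmarks are the two chromosome-end coordinates; centromere distance is
measured from the origin midpoint by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .core import BinnedTrack, GenomeLayout, Origin

__all__ = [
    "MetaProfile",
    "assign_trep_quartiles",
    "metaprofile",
    "distance_to_nearest",
    "proximity_class_counts",
    "mean_distance_by_class",
    "overlap_with_sites",
]


@dataclass
class MetaProfile:
    """Mean signal over a group of origins, aligned on origin midpoints."""

    label: str
    offsets: np.ndarray  # bp relative to the midpoint, symmetric about 0
    mean: np.ndarray  # mean signal per offset (nan where n == 0)
    n: np.ndarray  # origins contributing per offset

    def center_mean(self, half_width_bp: int = 500) -> float:
        """Mean of the profile within +/- half_width_bp of the midpoint."""
        sel = np.abs(self.offsets) <= half_width_bp
        return float(np.nanmean(self.mean[sel]))


def assign_trep_quartiles(origins: Sequence[Origin]) -> dict[str, int]:
    """Quartile (1 = earliest) per origin by T_Rep rank.

    Stable sort by (t_rep, name); the four contiguous rank blocks differ in
    size by at most one, earlier quartiles taking the extra origin when
    n mod 4 != 0.
    """
    if len(origins) < 4:
        raise ValueError("need at least 4 origins for quartiles")
    missing = [o.name for o in origins if o.t_rep is None]
    if missing:
        raise ValueError(f"origins lacking t_rep: {missing[:5]}")
    ordered = sorted(origins, key=lambda o: (o.t_rep, o.name))
    n = len(ordered)
    base, rem = divmod(n, 4)
    sizes = [base + 1] * rem + [base] * (4 - rem)
    labels: dict[str, int] = {}
    pos = 0
    for q, size in enumerate(sizes, start=1):
        for o in ordered[pos : pos + size]:
            labels[o.name] = q
        pos += size
    return labels


def metaprofile(
    track: BinnedTrack,
    origins_group: Sequence[Origin],
    window_bp: int,
    label: str = "",
) -> MetaProfile:
    """Average signal around origin midpoints at bin resolution.

    Offsets beyond a chromosome end contribute nothing at that offset (the
    per-offset n is decremented); the mean is over contributing origins.
    """
    if not origins_group:
        raise ValueError("empty origin group")
    bw = track.bin_width
    half = window_bp // (2 * bw)
    n_off = 2 * half + 1
    sums = np.zeros(n_off)
    n = np.zeros(n_off, dtype=int)
    rel = np.arange(-half, half + 1)
    for o in origins_group:
        vec = track.data[o.chrom]
        idx = o.midpoint // bw + rel
        valid = (idx >= 0) & (idx < len(vec))
        sums[valid] += vec[idx[valid]]
        n[valid] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    return MetaProfile(label=label, offsets=rel * bw, mean=mean, n=n)


def _edge_gap(qs: int, qe: int, ls: int, le: int) -> int:
    """Edge-gap distance between half-open intervals (0 on overlap).

    Zero-width landmarks (points) are supported: a point at p is (p, p).
    """
    if qs < le and ls < qe:
        return 0
    if qe <= ls:
        return ls - qe
    return qs - le


def distance_to_nearest(
    query_intervals: Sequence[tuple[str, int, int]],
    landmark_intervals: Sequence[tuple[str, int, int]],
) -> np.ndarray:
    """Per query, the edge-gap distance to the nearest same-chromosome landmark.

    Cross-chromosome matches are never considered; queries on chromosomes
    with no landmark get nan (flagged for exclusion downstream).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in landmark_intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    out = np.empty(len(query_intervals))
    for i, (chrom, qs, qe) in enumerate(query_intervals):
        marks = by_chrom.get(chrom)
        if not marks:
            out[i] = np.nan
            continue
        out[i] = min(_edge_gap(qs, qe, ls, le) for ls, le in marks)
    return out


def _landmarks(layout: GenomeLayout, landmark: str) -> list[tuple[str, int, int]]:
    if landmark == "CEN":
        return [(c, s, e) for c, (s, e) in layout.centromeres.items()]
    if landmark == "TEL":
        out = []
        for chrom, length in layout.chromosomes:
            out.append((chrom, 0, 0))
            out.append((chrom, length, length))
        return out
    raise ValueError("landmark must be 'CEN' or 'TEL'")


def _midpoint_queries(classified: pd.DataFrame) -> list[tuple[str, int, int]]:
    mids = (classified["start"].to_numpy() + classified["end"].to_numpy()) // 2
    return [(c, int(m), int(m)) for c, m in zip(classified["chrom"], mids)]


def proximity_class_counts(
    classified: pd.DataFrame,
    layout: GenomeLayout,
    landmark: str,
    threshold: int,
) -> pd.DataFrame:
    """Per-class counts of origins within / beyond ``threshold`` of a landmark.

    "Within" is distance <= threshold, measured from the origin midpoint.
    """
    dist = distance_to_nearest(_midpoint_queries(classified), _landmarks(layout, landmark))
    within = dist <= threshold
    rows = []
    for cls, sub in classified.groupby("class", sort=True):
        w = int(within[classified.index.get_indexer(sub.index)].sum())
        rows.append((cls, w, len(sub) - w))
    return pd.DataFrame(rows, columns=["class", "within", "beyond"])


def mean_distance_by_class(
    classified: pd.DataFrame,
    layout: GenomeLayout,
    threshold: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean CEN distance per class after excluding pericentric/subtelomeric
    origins, plus pairwise two-sided Welch t-tests between classes.

    Identical degenerate samples (zero variance, equal means) get p = 1 by
    convention; classes with n < 2 are skipped (p = nan, flagged).
    """
    queries = _midpoint_queries(classified)
    d_cen = distance_to_nearest(queries, _landmarks(layout, "CEN"))
    d_tel = distance_to_nearest(queries, _landmarks(layout, "TEL"))
    keep = ~((d_cen <= threshold) | (d_tel <= threshold)) & ~np.isnan(d_cen)
    sub = classified.loc[keep].copy()
    sub["cen_distance"] = d_cen[keep]

    summary_rows = []
    samples: dict[str, np.ndarray] = {}
    for cls, grp in sub.groupby("class", sort=True):
        samples[cls] = grp["cen_distance"].to_numpy(float)
        summary_rows.append((cls, len(grp), float(grp["cen_distance"].mean())))
    summary = pd.DataFrame(summary_rows, columns=["class", "n", "mean_distance"])

    pair_rows = []
    for a, b in combinations(sorted(samples), 2):
        xa, xb = samples[a], samples[b]
        if len(xa) < 2 or len(xb) < 2:
            pair_rows.append((a, b, np.nan, True))
            continue
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            p = 1.0 if xa.mean() == xb.mean() else 0.0
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        pair_rows.append((a, b, p, False))
    pairs = pd.DataFrame(pair_rows, columns=["class_a", "class_b", "pvalue", "skipped"])
    return summary, pairs


def overlap_with_sites(
    classified: pd.DataFrame,
    sites: pd.DataFrame,
    config: AnalysisConfig,
    layout: Optional[GenomeLayout] = None,
    exclude_subtelomeric: bool = False,
) -> pd.DataFrame:
    """Per-class counts of origins whose 1 kb midpoint window shares >= 1 bp
    with any binding-site window (``win_start``/``win_end`` columns from the
    site-table reader).

    With ``exclude_subtelomeric``, origins within ``landmark_threshold`` of a
    chromosome end are removed before counting (their class n shrinks too).
    """
    work = classified
    if exclude_subtelomeric:
        if layout is None:
            raise ValueError("excluding subtelomeric origins requires the genome layout")
        d_tel = distance_to_nearest(_midpoint_queries(classified), _landmarks(layout, "TEL"))
        work = classified.loc[d_tel > config.landmark_threshold]

    site_by_chrom: dict[str, np.ndarray] = {}
    for chrom, grp in sites.groupby("chrom", sort=False):
        site_by_chrom[chrom] = grp[["win_start", "win_end"]].to_numpy(int)

    half = config.proximity_window // 2
    proximal = np.zeros(len(work), dtype=bool)
    mids = (work["start"].to_numpy() + work["end"].to_numpy()) // 2
    for i, (chrom, mid) in enumerate(zip(work["chrom"], mids)):
        wins = site_by_chrom.get(chrom)
        if wins is None:
            continue
        lo, hi = int(mid) - half, int(mid) - half + config.proximity_window
        proximal[i] = bool(((wins[:, 0] < hi) & (lo < wins[:, 1])).any())

    rows = []
    for cls, grp in work.groupby("class", sort=True):
        sel = work.index.get_indexer(grp.index)
        rows.append((cls, len(grp), int(proximal[sel].sum())))
    out = pd.DataFrame(rows, columns=["class", "n", "proximal"])
    out.loc[len(out)] = ("all", len(work), int(proximal.sum()))
    return out
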