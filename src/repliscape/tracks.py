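"""Fragment counts to smoothed, normalized BrdU signal tracks.

Protocol: fragments are binned into 50 bp non-overlapping bins by fragment
midpoint, median-smoothed over a 1 kb window, quantile-normalized between
replicates, then the replicates are averaged and smoothed again.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import BinnedTrack, FragmentSet, GenomeLayout

__all__ = [
    "bin_fragments",
    "median_smooth",
    "quantile_normalize",
    "average_and_resmooth",
    "pooled_counts",
    "match_scale",
]


def bin_fragments(fragments, layout: GenomeLayout, bin_width: int) -> BinnedTrack:
    """Count fragment midpoints per bin; conserves the fragment count exactly."""
    fs = FragmentSet.coerce(fragments, layout)
    track = BinnedTrack.zeros(layout, bin_width)
    if len(fs) == 0:
        return track
    mids = fs.midpoints()
    for chrom, sub in mids.groupby("chrom", sort=False):
        bins = sub["pos"].to_numpy() // bin_width
        track.data[chrom] += np.bincount(bins, minlength=len(track.data[chrom])).astype(float)
    return track


def _window_bins(window_bp: int, bin_width: int) -> int:
    # symmetric, odd bin count: 1 kb over 50 bp bins -> 21 bins
    return 2 * (window_bp // (2 * bin_width)) + 1


def _sliding_median(vec: np.ndarray, w: int) -> np.ndarray:
    """Centered sliding median with truncated (shrinking) windows at the ends."""
    n = len(vec)
    if w <= 1 or n == 0:
        return vec.copy()
    half = w // 2
    out = np.empty(n)
    if n >= w:
        windows = np.lib.stride_tricks.sliding_window_view(vec, w)
        out[half : n - half] = np.median(windows, axis=1)
        edge = half
    else:
        edge = n  # everything is an edge
    for i in range(min(edge, n)):
        out[i] = np.median(vec[max(0, i - half) : i + half + 1])
    for i in range(max(n - edge, 0), n):
        out[i] = np.median(vec[max(0, i - half) : i + half + 1])
    return out


def median_smooth(track: BinnedTrack, window_bp: int) -> BinnedTrack:
    """Sliding-window median over ``window_bp``.

    The window holds ``2*floor(window_bp / (2*bin_width)) + 1`` bins so it is
    symmetric about the scored bin; at chromosome ends the window shrinks
    rather than padding, so no signal is invented at telomeres.
    """
    if window_bp < track.bin_width:
        raise ValueError("smoothing window smaller than one bin")
    w = _window_bins(window_bp, track.bin_width)
    return BinnedTrack(track.bin_width, {c: _sliding_median(v, w) for c, v in track.data.items()})


def quantile_normalize(tracks: Sequence[BinnedTrack]) -> list[BinnedTrack]:
    """Force all tracks to share one genome-wide value distribution.

    Each track's value at rank r is replaced by the across-track mean of the
    rank-r values; ties within a track receive the mean reference value over
    their tied rank span (the standard convention — count data guarantee
    heavy ties).
    """
    if len(tracks) < 2:
        raise ValueError("quantile normalization needs at least two tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_shape(t):
            raise ValueError("tracks differ in layout or bin width")
    order = list(first.data)
    mat = np.stack([t.concat(order) for t in tracks])  # (T, n)
    sorted_mat = np.sort(mat, axis=1)
    reference = sorted_mat.mean(axis=0)

    out = []
    for row in mat:
        idx = np.argsort(row, kind="mergesort")
        sv = row[idx]
        # group boundaries of tied runs in sorted order
        starts = np.flatnonzero(np.r_[True, sv[1:] != sv[:-1]])
        bounds = np.r_[starts, len(sv)]
        sums = np.add.reduceat(reference, starts)
        counts = np.diff(bounds)
        means = sums / counts
        normalized_sorted = np.repeat(means, counts)
        normalized = np.empty_like(row)
        normalized[idx] = normalized_sorted
        out.append(normalized)

    results = []
    for vec in out:
        data = {}
        pos = 0
        for chrom in order:
            n = len(first.data[chrom])
            data[chrom] = vec[pos : pos + n].copy()
            pos += n
        results.append(BinnedTrack(first.bin_width, data))
    return results


def average_and_resmooth(tracks: Sequence[BinnedTrack], window_bp: int) -> BinnedTrack:
    """Bin-wise mean of replicate tracks followed by another median smooth."""
    if len(tracks) < 2:
        raise ValueError("need at least two tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_shape(t):
            raise ValueError("tracks differ in layout or bin width")
    mean = BinnedTrack(
        first.bin_width,
        {c: np.mean([t.data[c] for t in tracks], axis=0) for c in first.data},
    )
    return median_smooth(mean, window_bp)


def match_scale(
    track: BinnedTrack, reference: BinnedTrack, signal_quantile: float = 0.75
) -> BinnedTrack:
    """Bring a track onto a reference track's scale for cross-strain display.

    The factor is the summed-signal ratio reference/track over bins that are
    high-signal in BOTH tracks (each above its own ``signal_quantile`` of
    positive bins). Anchoring on strong shared signal — in practice the
    plateaus of the earliest, least regulated origins — makes the comparison
    robust to one strain carrying extra signal mass (e.g. deregulated late
    origins in rif1Δ), which a total-sum rescaling would smear into every
    region. The selection is deliberately symmetric: thresholding on only one
    track's noisy values would inflate that track's conditional mean
    (regression to the mean) and bias the factor.
    """
    if not track.same_shape(reference):
        raise ValueError("tracks differ in layout or bin width")
    a = track.concat(list(track.data))
    b = reference.concat(list(track.data))
    if not ((a > 0).any() and (b > 0).any()):
        raise ValueError("a track has no positive bins")
    sel = (a > np.quantile(a[a > 0], signal_quantile)) & (b > np.quantile(b[b > 0], signal_quantile))
    if not sel.any():
        raise ValueError("no high-signal bins shared by both tracks")
    factor = float(b[sel].sum() / a[sel].sum())
    return BinnedTrack(track.bin_width, {c: v * factor for c, v in track.data.items()})


def pooled_counts(fragment_sets, layout: GenomeLayout, bin_width: int) -> BinnedTrack:
    """Sum raw midpoint counts over replicate libraries (for peak calling)."""
    track = BinnedTrack.zeros(layout, bin_width)
    for fs in fragment_sets:
        binned = bin_fragments(fs, layout, bin_width)
        for chrom in track.data:
            track.data[chrom] += binned.data[chrom]
    return track
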