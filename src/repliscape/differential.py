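"""Differential origin firing between WT and rif1Δ, with three-way classes.

Origins called in either strain are counted over their 1 kb midpoint windows
per replicate library, normalized, and tested with a two-group negative-
binomial exact conditional test under a single pooled dispersion (2-vs-2
replicate designs cannot support per-origin dispersions). Benjamini-Hochberg
FDR control at q < 0.05 then assigns each origin one of three classes:

* ``Rif1-repressed``   — significantly higher signal in rif1Δ,
* ``Rif1-activated``   — significantly lower signal in rif1Δ,
* ``Rif1-unregulated`` — no significant change.

The fold-change sign convention is positive = higher in rif1Δ (i.e. repressed
by Rif1); the class names invert the sign on purpose.

Normalization default is DESeq-style median-of-ratios size factors computed
on the origin-window count matrix. Plain library-size (total fragment count)
normalization is available but biased here: the deregulated late origins add
a large block of signal mass to the rif1Δ libraries, so at fixed sequencing
depth every unchanged origin loses relative coverage and would be miscalled
as Rif1-activated. The median ratio over origins is robust to that
composition shift as long as changed origins are a minority.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, nbinom

from .config import AnalysisConfig
from .core import FragmentSet, GenomeLayout, Origin

__all__ = [
    "OriginCounts",
    "count_origin_windows",
    "size_factors",
    "estimate_dispersion",
    "nb_exact_test",
    "bh_fdr",
    "classify_origins",
    "differential_analysis",
    "CLASS_REPRESSED",
    "CLASS_UNREGULATED",
    "CLASS_ACTIVATED",
]

CLASS_REPRESSED = "Rif1-repressed"
CLASS_UNREGULATED = "Rif1-unregulated"
CLASS_ACTIVATED = "Rif1-activated"


@dataclass
class OriginCounts:
    """Origin-window count matrix: one row per origin, one column per library."""

    origins: list[Origin]
    strains: list[str]  # strain label per sample column
    counts: np.ndarray  # (n_origins, n_samples)
    libsizes: np.ndarray  # total fragments per sample

    def columns(self, strain: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.strains) == strain)


def count_origin_windows(
    fragment_sets: dict[str, Sequence[FragmentSet]],
    origins: Sequence[Origin],
    config: AnalysisConfig,
    layout: GenomeLayout | None = None,
) -> OriginCounts:
    """Count fragment midpoints in each origin's 1 kb window, per library."""
    if not origins:
        raise ValueError("empty origin list")
    strains: list[str] = []
    sets: list[FragmentSet] = []
    for strain, reps in fragment_sets.items():
        for fs in reps:
            strains.append(strain)
            sets.append(FragmentSet.coerce(fs, layout))
    counts = np.zeros((len(origins), len(sets)), dtype=int)
    for j, fs in enumerate(sets):
        mids = fs.midpoints()
        by_chrom = {c: np.sort(sub["pos"].to_numpy()) for c, sub in mids.groupby("chrom", sort=False)}
        for i, o in enumerate(origins):
            pos = by_chrom.get(o.chrom)
            if pos is None:
                continue
            chrom_len = layout.length(o.chrom) if layout is not None else None
            lo, hi = o.window(config.origin_window, chrom_len)
            counts[i, j] = np.searchsorted(pos, hi, "left") - np.searchsorted(pos, lo, "left")
    libsizes = np.array([len(fs) for fs in sets], dtype=float)
    return OriginCounts(list(origins), strains, counts, libsizes)


def _median_ratio(counts: np.ndarray) -> np.ndarray | None:
    positive = (counts > 0).all(axis=1)
    if positive.sum() < 3:
        return None
    logc = np.log(counts[positive].astype(float))
    log_geo = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - log_geo, axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def size_factors(
    counts: np.ndarray,
    libsizes: np.ndarray,
    method: str = "median-ratio",
    strains: Sequence[str] | None = None,
    refine_threshold: float = 1.0,
) -> np.ndarray:
    """Per-sample normalization factors (geometric mean ~ 1).

    ``median-ratio``: DESeq-style median over origins of the ratio to the
    row-wise geometric mean, using rows positive in every sample. When the
    strain labels are given, one refinement pass re-estimates the factors on
    rows whose first-pass between-strain fold change is below
    ``refine_threshold`` (|log2| < 1): when a large minority of origins is
    strongly changed in one direction, the plain median lands in the tail of
    the unchanged block and leaves a small systematic shift that deep counts
    would register as differential. Falls back to library sizes when too few
    usable rows exist. ``library``: total fragment count.
    """
    if method == "library":
        return libsizes / np.exp(np.mean(np.log(libsizes)))
    if method != "median-ratio":
        raise ValueError(f"unknown normalization method {method!r}")
    sf = _median_ratio(counts)
    if sf is None:
        return size_factors(counts, libsizes, "library")
    if strains is not None:
        strains = np.asarray(strains)
        labels = pd.unique(strains)
        if len(labels) == 2:
            norm = counts / sf
            m = [norm[:, strains == lab].mean(axis=1) for lab in labels]
            fc = np.log2((m[1] + 0.5) / (m[0] + 0.5))
            stable = np.abs(fc) < refine_threshold
            refined = _median_ratio(counts[stable]) if stable.sum() >= 3 else None
            if refined is not None:
                sf = refined
    return sf


def estimate_dispersion(
    counts: np.ndarray, strains: Sequence[str], sf: np.ndarray | None = None
) -> float:
    """Common NB dispersion by the method of moments.

    For each origin and strain with normalized counts (mean m, sample
    variance s^2): phi_hat = (s^2 - m) / m^2. Returns the median over origins
    of max(phi_hat, 0); 0 when every estimate is non-positive (Poisson
    fallback).
    """
    strains = np.asarray(strains)
    if sf is None:
        sf = np.ones(counts.shape[1])
    estimates = []
    for strain in pd.unique(strains):
        cols = np.flatnonzero(strains == strain)
        if len(cols) < 2:
            raise ValueError(f"strain {strain!r} has fewer than 2 replicates")
        norm = counts[:, cols] / sf[cols]
        m = norm.mean(axis=1)
        s2 = norm.var(axis=1, ddof=1)
        ok = m > 0
        phi_hat = (s2[ok] - m[ok]) / m[ok] ** 2
        estimates.append(np.maximum(phi_hat, 0.0))
    if not estimates or sum(len(e) for e in estimates) == 0:
        return 0.0
    return float(np.median(np.concatenate(estimates)))


def nb_exact_test(
    counts_wt: Sequence[float],
    counts_mut: Sequence[float],
    phi: float,
    sizes_wt: Sequence[float] | None = None,
    sizes_mut: Sequence[float] | None = None,
) -> float:
    """Two-sided exact conditional test of equal means between two groups.

    Counts are scaled to a common effective library size (divided by the
    per-sample normalization factors), pooled per group, and the probability
    of splits of the pooled total at least as extreme (i.e. at most as
    probable) as the observed one is accumulated under the null that both
    groups share one mean — NB(phi) group-sum probabilities, reducing to the
    binomial split when phi = 0.
    """
    counts_wt = np.asarray(counts_wt, dtype=float)
    counts_mut = np.asarray(counts_mut, dtype=float)
    if (counts_wt < 0).any() or (counts_mut < 0).any():
        raise ValueError("counts must be non-negative")
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    sw = np.ones(len(counts_wt)) if sizes_wt is None else np.asarray(sizes_wt, dtype=float)
    sm = np.ones(len(counts_mut)) if sizes_mut is None else np.asarray(sizes_mut, dtype=float)
    y1 = int(round((counts_wt / sw).sum()))
    y2 = int(round((counts_mut / sm).sum()))
    total = y1 + y2
    if total == 0:
        return 1.0  # all counts zero: no evidence by convention
    n1, n2 = len(counts_wt), len(counts_mut)
    y = np.arange(total + 1)
    if phi == 0.0:
        logp = binom.logpmf(y, total, n1 / (n1 + n2))
    else:
        mu = total / (n1 + n2)  # pooled per-replicate mean under the null
        q = 1.0 / (1.0 + phi * mu)  # NB success prob, shared by both groups
        logp = nbinom.logpmf(y, n1 / phi, q) + nbinom.logpmf(total - y, n2 / phi, q)
        logp -= float(np.logaddexp.reduce(logp))  # normalize the conditional law
    probs = np.exp(logp)
    include = probs <= probs[y1] * (1.0 + 1e-9)
    if include.all():
        return 1.0  # the observed split is the (joint) mode: nothing is more extreme
    p = float(probs[include].sum())
    return min(max(p, np.nextafter(0, 1)), 1.0)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_origins(records: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Assign the three-way class from q-values and fold-change sign."""
    out = records.copy()
    significant = out["qvalue"] < config.fdr_q_threshold
    cls = np.full(len(out), CLASS_UNREGULATED, dtype=object)
    cls[significant.to_numpy() & (out["log2fc"].to_numpy() > 0)] = CLASS_REPRESSED
    cls[significant.to_numpy() & (out["log2fc"].to_numpy() < 0)] = CLASS_ACTIVATED
    out["class"] = cls
    return out


def differential_analysis(
    fragment_sets: dict[str, Sequence[FragmentSet]],
    origins: Sequence[Origin],
    config: AnalysisConfig,
    layout: GenomeLayout | None = None,
    wt_label: str = "WT",
    normalization: str = "median-ratio",
) -> pd.DataFrame:
    """Full differential pipeline: counts -> dispersion -> exact tests -> BH -> classes.

    ``origins`` should be the union of origins peak-called in either strain.
    Returns one row per origin in the classification-table schema.
    """
    strains = list(fragment_sets)
    if wt_label not in strains or len(strains) != 2:
        raise ValueError(f"need exactly two strains including {wt_label!r}, got {strains}")
    mut_label = next(s for s in strains if s != wt_label)
    oc = count_origin_windows(fragment_sets, origins, config, layout)
    sf = size_factors(oc.counts, oc.libsizes, normalization, strains=oc.strains)
    phi = estimate_dispersion(oc.counts, oc.strains, sf)
    wt_cols, mut_cols = oc.columns(wt_label), oc.columns(mut_label)

    pvals = np.empty(len(origins))
    log2fc = np.empty(len(origins))
    for i in range(len(origins)):
        row = oc.counts[i]
        pvals[i] = nb_exact_test(row[wt_cols], row[mut_cols], phi, sf[wt_cols], sf[mut_cols])
        norm_wt = (row[wt_cols] / sf[wt_cols]).mean()
        norm_mut = (row[mut_cols] / sf[mut_cols]).mean()
        log2fc[i] = math.log2((norm_mut + 0.5) / (norm_wt + 0.5))
    qvals = bh_fdr(pvals)
    records = pd.DataFrame(
        {
            "name": [o.name for o in origins],
            "chrom": [o.chrom for o in origins],
            "start": [o.start for o in origins],
            "end": [o.end for o in origins],
            "trep": [np.nan if o.t_rep is None else o.t_rep for o in origins],
            "count_wt": oc.counts[:, wt_cols].sum(axis=1),
            "count_mut": oc.counts[:, mut_cols].sum(axis=1),
            "log2fc": log2fc,
            "pvalue": pvals,
            "qvalue": qvals,
        }
    )
    return classify_origins(records, config)
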