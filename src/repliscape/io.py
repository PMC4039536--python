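"""Readers and writers for the on-disk formats.

Formats handled here:

* ``chrom.sizes`` — two whitespace-delimited columns, name then length.
* centromere table — TSV with header ``chrom  start  end`` (0-based half-open).
* origin table — TSV with header ``name chrom start end status trep``;
  coordinates on disk are 1-based inclusive (the OriDB dialect) and are
  converted to the internal 0-based half-open convention on read. Rows whose
  status is not ``confirmed``/``likely`` are dropped (counted in the log).
* fragment BED — BED3+, natively 0-based half-open.
* bedGraph — one line per maximal run of equal-valued adjacent bins;
  zero-valued runs are omitted and restored to 0 on read.
* classification TSV — per-origin differential results
  (``name chrom start end trep count_wt count_mut log2fc pvalue qvalue class``),
  internal coordinates.
* metaprofile TSV — ``offset mean n`` per bin offset.
* binding-site table — TSV with header
  ``name feature_type chrom start end gene_side``; ``feature_type`` is ``ORF``
  or ``intergenic``. For ORFs the whole interval is the overlap window; for
  intergenics the window is the 1 kb of the interval nearest the naming gene,
  whose side is given by ``gene_side`` (``left``/``right``).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import ORIGIN_STATUSES, BinnedTrack, FragmentSet, GenomeLayout, Origin

logger = logging.getLogger("repliscape")

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_centromeres",
    "write_centromeres",
    "read_origin_table",
    "write_origin_table",
    "read_fragments_bed",
    "write_fragments_bed",
    "write_bedgraph",
    "read_bedgraph",
    "write_classification_tsv",
    "read_classification_tsv",
    "write_metaprofile_tsv",
    "read_metaprofile_tsv",
    "read_sites_table",
    "setup_logging",
]

CLASSIFICATION_COLUMNS = [
    "name", "chrom", "start", "end", "trep",
    "count_wt", "count_mut", "log2fc", "pvalue", "qvalue", "class",
]


def setup_logging(level: str = "INFO") -> None:
    """Send pipeline log lines to stderr at the requested verbosity."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
        force=True,
    )


# ---------------------------------------------------------------------------
# genome layout


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    chromosomes: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'name length', got {line.strip()!r}")
            name, raw_len = parts
            try:
                length = int(raw_len)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: length {raw_len!r} is not an integer") from exc
            chromosomes.append((name, length))
    if not chromosomes:
        raise ValueError(f"{path}: no chromosomes")
    return GenomeLayout(chromosomes)


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_centromeres(path: str | Path, layout: GenomeLayout) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: centromere table needs columns {sorted(need)}")
    cens = {str(r.chrom): (int(r.start), int(r.end)) for r in df.itertuples()}
    return layout.with_centromeres(cens)


def write_centromeres(layout: GenomeLayout, path: str | Path) -> None:
    rows = [(c, s, e) for c, (s, e) in layout.centromeres.items()]
    pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# origins


def read_origin_table(path: str | Path, layout: GenomeLayout) -> list[Origin]:
    """Read an OriDB-style origin table (1-based inclusive coordinates).

    The single coordinate conversion in the package happens here: start gets
    the -1 shift to 0-based, the inclusive end is already the half-open end.
    """
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "chrom": str})
    need = ["name", "chrom", "start", "end", "status", "trep"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: origin table missing columns {missing}")
    lengths = layout.lengths
    origins: list[Origin] = []
    dropped = 0
    for i, row in enumerate(df.itertuples(), start=2):  # header = line 1
        status = str(row.status)
        if status not in ORIGIN_STATUSES:
            dropped += 1
            continue
        if row.chrom not in lengths:
            raise ValueError(f"{path}: row {i}: unknown chromosome {row.chrom!r}")
        start, end = int(row.start) - 1, int(row.end)
        if not (0 <= start < end <= lengths[row.chrom]):
            raise ValueError(f"{path}: row {i}: origin {row.name} outside chromosome bounds")
        trep = None if pd.isna(row.trep) else float(row.trep)
        origins.append(Origin(str(row.name), str(row.chrom), start, end, status, trep))
    if dropped:
        logger.info("read_origin_table: dropped %d row(s) with status outside %s", dropped, ORIGIN_STATUSES)
    return origins


def write_origin_table(origins: Iterable[Origin], path: str | Path) -> None:
    """Write origins back in the on-disk 1-based inclusive dialect."""
    rows = [
        (o.name, o.chrom, o.start + 1, o.end, o.status, "" if o.t_rep is None else o.t_rep)
        for o in origins
    ]
    pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "status", "trep"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# fragments (BED)


def read_fragments_bed(path: str | Path, layout: GenomeLayout) -> FragmentSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=FragmentSet.COLUMNS) if rows else pd.DataFrame(
        {"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=int), "end": pd.Series(dtype=int)}
    )
    return FragmentSet(df, layout)


def write_fragments_bed(fragments: FragmentSet, path: str | Path) -> None:
    fragments.df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# bedGraph tracks


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    """Run-length encode the binned track; zero runs are omitted."""
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom, vec in track.data.items():
            if len(vec) == 0:
                continue
            change = np.flatnonzero(vec[1:] != vec[:-1]) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vec)]])
            for s, e in zip(starts, ends):
                value = vec[s]
                if value == 0:
                    continue
                fh.write(f"{chrom}\t{s * bw}\t{e * bw}\t{value:g}\n")


def read_bedgraph(path: str | Path, layout: GenomeLayout, bin_width: int) -> BinnedTrack:
    track = BinnedTrack.zeros(layout, bin_width)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            if chrom not in track.data:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            s, e = int(start), int(end)
            if s % bin_width:
                raise ValueError(f"{path}:{lineno}: interval not aligned to {bin_width} bp bins")
            track.data[chrom][s // bin_width : -(-e // bin_width)] = float(value)
    return track


# ---------------------------------------------------------------------------
# classification and metaprofile tables


def write_classification_tsv(records: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in CLASSIFICATION_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"classification table missing columns {missing}")
    records[CLASSIFICATION_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_classification_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "chrom": str, "class": str})
    missing = [c for c in CLASSIFICATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: classification table missing columns {missing}")
    return df


def write_metaprofile_tsv(profile, path: str | Path) -> None:
    df = pd.DataFrame({"offset": profile.offsets, "mean": profile.mean, "n": profile.n})
    with open(path, "w") as fh:
        fh.write(f"# group: {profile.label}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_metaprofile_tsv(path: str | Path):
    from .landscape import MetaProfile  # local import avoids a cycle

    with open(path) as fh:
        header = fh.readline()
        label = header.split(":", 1)[1].strip() if header.startswith("# group:") else ""
        df = pd.read_csv(fh, sep="\t")
    return MetaProfile(
        label=label,
        offsets=df["offset"].to_numpy(),
        mean=df["mean"].to_numpy(float),
        n=df["n"].to_numpy(int),
    )


# ---------------------------------------------------------------------------
# binding-site tables


def read_sites_table(path: str | Path, layout: GenomeLayout, intergenic_window: int = 1000) -> pd.DataFrame:
    """Read a binding-site table and precompute each site's overlap window.

    ORF features use their whole interval; intergenic features use the
    ``intergenic_window`` bp of the interval nearest the naming gene
    (``gene_side`` column, ``left`` or ``right``). Returns the table with
    added ``win_start``/``win_end`` columns (0-based half-open).
    """
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "feature_type": str, "chrom": str})
    need = ["name", "feature_type", "chrom", "start", "end"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: site table missing columns {missing}")
    lengths = layout.lengths
    win_start, win_end = [], []
    for i, row in enumerate(df.itertuples(), start=2):
        if row.chrom not in lengths:
            raise ValueError(f"{path}: row {i}: unknown chromosome {row.chrom!r}")
        s, e = int(row.start), int(row.end)
        ftype = str(row.feature_type)
        if ftype == "ORF":
            ws, we = s, e
        elif ftype == "intergenic":
            side = str(getattr(row, "gene_side", "")).lower()
            if side == "left":
                ws, we = s, min(e, s + intergenic_window)
            elif side == "right":
                ws, we = max(s, e - intergenic_window), e
            else:
                raise ValueError(
                    f"{path}: row {i}: intergenic feature needs gene_side 'left' or 'right'"
                )
        else:
            raise ValueError(f"{path}: row {i}: malformed feature type {ftype!r}")
        win_start.append(ws)
        win_end.append(we)
    out = df.copy()
    out["win_start"] = win_start
    out["win_end"] = win_end
    return out
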