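"""Core domain containers shared across the pipeline.

All coordinates inside the package are 0-based, half-open ``[start, end)``,
the BED convention. Readers that consume 1-based inclusive tables (the
OriDB-style origin table) convert on input; nothing downstream ever sees
1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "Origin",
    "ReadFragment",
    "FragmentSet",
    "BinnedTrack",
    "ORIGIN_STATUSES",
]

ORIGIN_STATUSES = ("confirmed", "likely")


@dataclass
class GenomeLayout:
    """Chromosome names/lengths plus centromere intervals.

    Telomere landmarks are the two chromosome ends (positions 0 and length);
    they are derived, not stored.
    """

    chromosomes: list[tuple[str, int]]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome name(s): {dupes}")
        if not names:
            raise ValueError("no chromosomes")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}")
        lengths = dict(self.chromosomes)
        for chrom, (s, e) in self.centromeres.items():
            if chrom not in lengths:
                raise ValueError(f"centromere on unknown chromosome {chrom!r}")
            if not (0 <= s < e <= lengths[chrom]):
                raise ValueError(f"centromere {chrom}:{s}-{e} outside chromosome")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def telomeres(self, chrom: str) -> tuple[int, int]:
        """The two chromosome-end positions used as TEL landmarks."""
        return (0, self.length(chrom))

    def n_bins(self, bin_width: int) -> dict[str, int]:
        return {n: -(-length // bin_width) for n, length in self.chromosomes}

    def with_centromeres(self, centromeres: dict[str, tuple[int, int]]) -> "GenomeLayout":
        return GenomeLayout(list(self.chromosomes), dict(centromeres))


@dataclass(frozen=True)
class Origin:
    """A replication origin (ARS) with its OriDB-style annotation.

    ``t_rep`` is the characteristic replication time in minutes (lower =
    earlier); it may be missing (None) for origins without timing data.
    """

    name: str
    chrom: str
    start: int
    end: int
    status: str = "confirmed"
    t_rep: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"origin {self.name}: start >= end")
        if self.status not in ORIGIN_STATUSES:
            raise ValueError(f"origin {self.name}: status {self.status!r} not in {ORIGIN_STATUSES}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def window(self, width: int, chrom_length: Optional[int] = None) -> tuple[int, int]:
        """The ``width``-bp window centered on the origin midpoint, clipped."""
        lo = self.midpoint - width // 2
        hi = lo + width
        if chrom_length is not None:
            lo, hi = max(lo, 0), min(hi, chrom_length)
        return max(lo, 0), hi


@dataclass(frozen=True)
class ReadFragment:
    """A sequenced fragment reduced to its genomic interval (strand ignored)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment {self.chrom}:{self.start}-{self.end}: start >= end")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class FragmentSet:
    """Columnar container for many fragments (one BrdU-IP-Seq library).

    Stores chrom/start/end as a DataFrame so binning and window counting stay
    vectorized at sequencing depth. Accepts and yields ``ReadFragment``
    records for small-scale use.
    """

    COLUMNS = ["chrom", "start", "end"]

    def __init__(self, df: pd.DataFrame, layout: Optional[GenomeLayout] = None):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"fragment table missing columns {missing}")
        df = df[self.COLUMNS].reset_index(drop=True)
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"fragment row {bad}: end <= start")
        if layout is not None and len(df):
            lengths = layout.lengths
            unknown = set(df["chrom"]) - set(lengths)
            if unknown:
                raise ValueError(f"fragments on unknown chromosome(s): {sorted(unknown)}")
            for chrom, sub in df.groupby("chrom", sort=False):
                if (sub["start"] < 0).any() or (sub["end"] > lengths[chrom]).any():
                    raise ValueError(f"fragment outside chromosome {chrom}")
        self.df = df

    @classmethod
    def from_records(
        cls, fragments: Iterable[ReadFragment], layout: Optional[GenomeLayout] = None
    ) -> "FragmentSet":
        rows = [(f.chrom, f.start, f.end) for f in fragments]
        df = pd.DataFrame(rows, columns=cls.COLUMNS) if rows else pd.DataFrame(
            {"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=int), "end": pd.Series(dtype=int)}
        )
        return cls(df, layout)

    @classmethod
    def coerce(cls, fragments, layout: Optional[GenomeLayout] = None) -> "FragmentSet":
        if isinstance(fragments, FragmentSet):
            return fragments
        return cls.from_records(fragments, layout)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[ReadFragment]:
        for chrom, start, end in self.df.itertuples(index=False):
            yield ReadFragment(chrom, int(start), int(end))

    def midpoints(self) -> pd.DataFrame:
        mid = (self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2
        return pd.DataFrame({"chrom": self.df["chrom"], "pos": mid})


@dataclass
class BinnedTrack:
    """Per-chromosome vectors of signal in fixed-width non-overlapping bins."""

    bin_width: int
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}

    @classmethod
    def zeros(cls, layout: GenomeLayout, bin_width: int) -> "BinnedTrack":
        return cls(bin_width, {c: np.zeros(n) for c, n in layout.n_bins(bin_width).items()})

    def validate(self, layout: GenomeLayout) -> None:
        expect = layout.n_bins(self.bin_width)
        for chrom, vec in self.data.items():
            if chrom not in expect:
                raise ValueError(f"track chromosome {chrom!r} not in layout")
            if len(vec) != expect[chrom]:
                raise ValueError(
                    f"track {chrom}: {len(vec)} bins, layout expects {expect[chrom]}"
                )
            if (vec < 0).any():
                raise ValueError(f"track {chrom}: negative values")

    def concat(self, order: Optional[list[str]] = None) -> np.ndarray:
        order = order or list(self.data)
        return np.concatenate([self.data[c] for c in order])

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(self.bin_width, {c: v.copy() for c, v in self.data.items()})

    def same_shape(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and set(self.data) == set(other.data)
            and all(len(self.data[c]) == len(other.data[c]) for c in self.data)
        )
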