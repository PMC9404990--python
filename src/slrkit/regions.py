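"""Named chromosome regions (PAR / IV / YDR) and interval bookkeeping.

All coordinates are 0-based, half-open. The sex-linked region (SLR) is the
union of the inversion (names starting with ``IV``) and the Y-duplication
region (``YDR``); pseudoautosomal regions have names starting with ``PAR``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class Region:
    """A named half-open interval on a chromosome."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"region {self.name}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap(self, start: int, end: int) -> int:
        """Overlap in bp with another half-open interval."""
        return max(0, min(self.end, end) - max(self.start, start))


class RegionMap:
    """An ordered collection of non-overlapping named regions on one chromosome."""

    def __init__(self, regions: Sequence[Region]):
        regions = sorted(regions, key=lambda r: (r.chrom, r.start))
        for a, b in zip(regions, regions[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"regions {a.name} and {b.name} overlap")
        self.regions = list(regions)

    @classmethod
    def from_layout(cls, chrom: str, layout: Iterable[tuple[str, int]]) -> "RegionMap":
        """Build contiguous regions from ``(name, length)`` pairs starting at 0."""
        regions, pos = [], 0
        for name, length in layout:
            regions.append(Region(name, chrom, pos, pos + length))
            pos += length
        return cls(regions)

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def get(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"no region named {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(r.name == name for r in self.regions)

    def label_of(self, pos: int, chrom: str | None = None) -> str | None:
        """Region name covering a position, or None if uncovered.

        PAR1/PAR2 and IV1/IV2 style names are reported as-is; use
        :meth:`broad_label_of` for the collapsed PAR/IV/YDR labels.
        """
        for r in self.regions:
            if (chrom is None or r.chrom == chrom) and r.contains(pos):
                return r.name
        return None

    def broad_label_of(self, pos: int, chrom: str | None = None) -> str | None:
        name = self.label_of(pos, chrom)
        return None if name is None else broad_label(name)

    def slr_regions(self) -> list[Region]:
        return [r for r in self.regions if broad_label(r.name) in ("IV", "YDR")]

    def par_regions(self) -> list[Region]:
        return [r for r in self.regions if broad_label(r.name) == "PAR"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.chrom, r.start, r.end, r.name) for r in self.regions],
            columns=["chrom", "start", "end", "name"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionMap":
        return cls([Region(row["name"], row["chrom"], int(row["start"]), int(row["end"]))
                    for _, row in df.iterrows()])


def broad_label(name: str) -> str:
    """Collapse PAR1/PAR2 -> PAR and IV1/IV2/IV2-1 -> IV; YDR stays YDR."""
    if name.startswith("PAR"):
        return "PAR"
    if name.startswith("IV"):
        return "IV"
    return name


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def any_overlap(start: int, end: int, mask: Iterable[tuple[int, int]]) -> bool:
    """True if [start, end) overlaps any interval in ``mask`` by >= 1 bp."""
    return any(min(end, e) - max(start, s) > 0 for s, e in mask)
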