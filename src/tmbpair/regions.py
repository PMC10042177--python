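"""Genomic interval algebra for callable-region accounting.

The TMB denominator is the size of the "callable exome": an exome
definition (canonical exons, a capture-kit footprint, or a targeted
panel) merged into non-overlapping intervals and with assembly gaps
subtracted.  All coordinates are BED-style half-open, 0-based;
1-based VCF positions are converted on ingest by the callers.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "load_bed",
    "write_bed",
    "BedParseError",
]

BP_PER_MB = 1_000_000


class BedParseError(ValueError):
    """Raised for malformed BED input; carries the offending line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class RegionSet:
    """An ordered collection of :class:`GenomicInterval` with a label.

    A freshly loaded set may contain overlapping or unsorted intervals;
    :meth:`merge` returns the normalised (sorted, disjoint, book-ended
    coalesced) form that every downstream length and membership
    computation assumes.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = "regions"):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.label = label
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return (
            f"RegionSet(label={self.label!r}, n={len(self.intervals)}, "
            f"bp={self.total_length_bp})"
        )

    # -- length accounting -------------------------------------------------

    @property
    def total_length_bp(self) -> int:
        """Sum of interval lengths; equals the base-pair union size iff merged."""
        return sum(iv.length for iv in self.intervals)

    def total_length_mb(self) -> float:
        """Total length in megabases (1 Mb = 1e6 bp exactly)."""
        return self.total_length_bp / BP_PER_MB

    @property
    def is_merged(self) -> bool:
        prev: GenomicInterval | None = None
        for iv in self.intervals:
            if prev is not None and prev.chrom == iv.chrom and iv.start <= prev.end:
                return False
            if prev is not None and (prev.chrom, prev.start) > (iv.chrom, iv.start):
                return False
            prev = iv
        return True

    # -- set algebra -------------------------------------------------------

    def merge(self) -> "RegionSet":
        """Coalesce into the minimal sorted disjoint cover of the same base pairs.

        Overlapping and book-ended (end == next start) intervals merge,
        matching ``bedtools merge`` defaults.  Idempotent.
        """
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        out: list[GenomicInterval] = []
        for iv in ivs:
            if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
                if iv.end > out[-1].end:
                    out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
            else:
                out.append(iv)
        return RegionSet(out, label=self.label)

    def subtract(self, gaps: "RegionSet") -> "RegionSet":
        """Base pairs in ``self`` and not in ``gaps``, as merged intervals.

        Both operands are normalised internally, so callers may pass raw
        sets; subtracting an empty set is the identity (up to merging).
        """
        a = self.merge().intervals
        b = gaps.merge().intervals
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in b:
            by_chrom.setdefault(iv.chrom, []).append(iv)

        out: list[GenomicInterval] = []
        for iv in a:
            cuts = by_chrom.get(iv.chrom, ())
            cursor = iv.start
            for gap in cuts:
                if gap.end <= cursor or gap.start >= iv.end:
                    continue
                if gap.start > cursor:
                    out.append(GenomicInterval(iv.chrom, cursor, gap.start))
                cursor = max(cursor, gap.end)
                if cursor >= iv.end:
                    break
            if cursor < iv.end:
                out.append(GenomicInterval(iv.chrom, cursor, iv.end))
        return RegionSet(out, label=self.label)

    def intersect(self, other: "RegionSet") -> "RegionSet":
        """Base pairs present in both sets (via two complement subtractions)."""
        return self.merge().subtract(self.merge().subtract(other))

    # -- membership --------------------------------------------------------

    def _build_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self._index is None:
            merged = self if self.is_merged else self.merge()
            idx: dict[str, tuple[list[int], list[int]]] = {}
            for iv in merged.intervals:
                s, e = idx.setdefault(iv.chrom, ([], []))
                s.append(iv.start)
                e.append(iv.end)
            self._index = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for c, (s, e) in idx.items()
            }
        return self._index

    def contains(self, chrom: str, pos_0based: int) -> bool:
        """True iff some interval satisfies start <= pos < end."""
        idx = self._build_index()
        if chrom not in idx:
            return False
        starts, ends = idx[chrom]
        i = bisect.bisect_right(starts, pos_0based) - 1
        return i >= 0 and pos_0based < ends[i]

    def contains_many(self, chroms: Sequence[str], pos_0based: Sequence[int]) -> np.ndarray:
        """Vectorised membership test; returns a boolean array."""
        idx = self._build_index()
        chroms = np.asarray(chroms)
        pos = np.asarray(pos_0based, dtype=np.int64)
        out = np.zeros(len(pos), dtype=bool)
        for chrom in np.unique(chroms):
            mask = chroms == chrom
            if str(chrom) not in idx:
                continue
            starts, ends = idx[str(chrom)]
            p = pos[mask]
            i = np.searchsorted(starts, p, side="right") - 1
            ok = (i >= 0) & (p < ends[np.clip(i, 0, len(ends) - 1)])
            out[mask] = ok
        return out

    # -- chromosome-name dialects -------------------------------------------

    def with_chrom_prefix(self, mode: str) -> "RegionSet":
        """Return a copy with 'chr' prefixes stripped or added.

        mode: "none" (verbatim), "strip", or "add".
        """
        if mode == "none":
            return self
        if mode == "strip":
            f = lambda c: c[3:] if c.startswith("chr") else c  # noqa: E731
        elif mode == "add":
            f = lambda c: c if c.startswith("chr") else "chr" + c  # noqa: E731
        else:
            raise ValueError(f"unknown chrom-prefix mode {mode!r}")
        return RegionSet(
            [GenomicInterval(f(iv.chrom), iv.start, iv.end) for iv in self.intervals],
            label=self.label,
        )


def load_bed(path: str | Path, label: str | None = None) -> RegionSet:
    """Read a BED3+ file into a raw (un-merged) :class:`RegionSet`.

    Track/browser and '#' comment lines are skipped.  Malformed lines
    raise :class:`BedParseError` naming the line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: require 0 <= start < end, got {start}..{end}"
                )
            intervals.append(GenomicInterval(chrom, start, end))
    return RegionSet(intervals, label=label or path.stem)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    """Write intervals as sorted BED3."""
    ivs = sorted(regions.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in ivs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
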