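"""Genomic interval data model, BED/chrom.sizes I/O, and multi-factor segmentation.

Coordinates are 0-based, half-open (BED convention) everywhere internally.
The central primitive is :func:`multi_intersect`, which segments the union of
several factors' peak sets into maximal runs of constant factor membership —
the "matrix of unique genomic loci" that occupancy classification consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Genome",
    "Interval",
    "PeakSet",
    "OccupancySegment",
    "BedParseError",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "summit_windows",
    "multi_intersect",
]


class BedParseError(ValueError):
    """Raised for malformed BED input; carries the offending line number."""


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome names with lengths in bp."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def validate(self, iv: "Interval") -> None:
        if iv.chrom not in self.lengths:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.lengths[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} extends past "
                f"chromosome end {self.lengths[iv.chrom]}"
            )


def read_chrom_sizes(path) -> Genome:
    """Read a two-column ``<name>\\t<length>`` chrom.sizes file."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise BedParseError(f"line {lineno}: expected two columns")
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError:
                raise BedParseError(f"line {lineno}: length {parts[1]!r} not an integer")
    return Genome(lengths)


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval [start, end) with optional summit, score and name."""

    chrom: str
    start: int
    end: int
    summit: int | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Summit if present, else the floor midpoint."""
        if self.summit is not None:
            return self.summit
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PeakSet:
    """A factor's peaks, kept sorted by (chrom, start)."""

    factor: str
    intervals: list[Interval]

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


@dataclass(frozen=True)
class OccupancySegment:
    """A maximal run of constant factor membership from multi_intersect."""

    interval: Interval
    membership: tuple[bool, ...]
    factors: tuple[str, ...]

    @property
    def k(self) -> int:
        return sum(self.membership)

    @property
    def factor_set(self) -> frozenset[str]:
        return frozenset(f for f, m in zip(self.factors, self.membership) if m)


def read_bed(path, genome: Genome, factor: str | None = None) -> PeakSet:
    """Parse BED3 / BED6 (optionally +summit-offset 7th column) into a PeakSet.

    The 7th column, when present, is the summit position as an offset from
    ``start`` (MACS-style); otherwise the summit defaults to the interval
    midpoint. Coordinates are validated against *genome*.
    """
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise BedParseError(f"{path}, line {lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise BedParseError(f"{path}, line {lineno}: non-integer coordinates")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    score = float(parts[4])
                except ValueError:
                    raise BedParseError(f"{path}, line {lineno}: bad score {parts[4]!r}")
            summit = None
            if len(parts) > 6 and parts[6] not in (".", ""):
                try:
                    summit = start + int(parts[6])
                except ValueError:
                    raise BedParseError(f"{path}, line {lineno}: bad summit offset")
            try:
                iv = Interval(chrom, start, end, summit=summit, score=score, name=name)
                genome.validate(iv)
            except ValueError as exc:
                raise BedParseError(f"{path}, line {lineno}: {exc}") from exc
            intervals.append(iv)
    return PeakSet(factor or str(path), intervals)


def write_bed(intervals: Iterable[Interval] | PeakSet, path, *, summit_offset: bool = False) -> None:
    """Write intervals as BED6 (name, score, '.' strand), canonical form.

    With ``summit_offset=True`` a 7th column holds summit - start.
    """
    if isinstance(intervals, PeakSet):
        intervals = intervals.intervals
    with open(path, "w") as fh:
        for iv in intervals:
            row = [
                iv.chrom,
                str(iv.start),
                str(iv.end),
                iv.name if iv.name is not None else ".",
                ("%g" % iv.score) if iv.score is not None else "0",
                ".",
            ]
            if summit_offset:
                row.append(str(iv.center - iv.start))
            fh.write("\t".join(row) + "\n")


def summit_windows(peaks: PeakSet, genome: Genome, halfwidth: int = 200) -> PeakSet:
    """Replace each peak by a fixed window centred on its summit.

    Windows are [summit - halfwidth, summit + halfwidth), clipped to
    chromosome bounds. Peaks without an explicit summit use the midpoint.
    """
    if halfwidth < 1:
        raise ValueError(f"halfwidth must be >= 1, got {halfwidth}")
    out = []
    for iv in peaks:
        c = iv.center
        start = max(0, c - halfwidth)
        end = min(genome[iv.chrom], c + halfwidth)
        summit = min(max(c, start), end - 1)
        out.append(Interval(iv.chrom, start, end, summit=summit, score=iv.score, name=iv.name))
    return PeakSet(peaks.factor, out)


def multi_intersect(peaksets: Sequence[PeakSet]) -> list[OccupancySegment]:
    """Segment the union of all peaks into runs of constant factor membership.

    Membership is boolean per factor: overlapping windows of the same factor
    count once. Returned segments tile the covered bases without overlap,
    are sorted, and adjacent segments always differ in membership.
    """
    if not peaksets:
        raise ValueError("multi_intersect needs at least one peak set")
    factors = tuple(ps.factor for ps in peaksets)
    if len(set(factors)) != len(factors):
        raise ValueError("duplicate factor labels in input peak sets")

    chroms: dict[str, list[tuple[int, int, int]]] = {}
    for fi, ps in enumerate(peaksets):
        for iv in ps:
            chroms.setdefault(iv.chrom, []).append((iv.start, iv.end, fi))

    segments: list[OccupancySegment] = []
    for chrom in sorted(chroms):
        events = chroms[chrom]
        starts = np.array([e[0] for e in events])
        ends = np.array([e[1] for e in events])
        fis = np.array([e[2] for e in events])
        bounds = np.unique(np.concatenate([starts, ends]))
        nseg = len(bounds) - 1
        # coverage depth per factor per elementary slice, via diff of events
        depth = np.zeros((len(factors), nseg), dtype=np.int32)
        si = np.searchsorted(bounds, starts)
        ei = np.searchsorted(bounds, ends)
        for a, b, f in zip(si, ei, fis):
            depth[f, a] += 1
            if b < nseg:
                depth[f, b] -= 1
        depth = np.cumsum(depth, axis=1)
        member = depth > 0

        run_start = None
        run_member: tuple[bool, ...] | None = None
        for j in range(nseg + 1):
            m = tuple(member[:, j]) if j < nseg else None
            if m is not None and not any(m):
                m = None
            if m == run_member and m is not None:
                continue
            if run_member is not None:
                segments.append(
                    OccupancySegment(
                        Interval(chrom, int(bounds[run_start]), int(bounds[j])),
                        run_member,
                        factors,
                    )
                )
            run_start, run_member = j, m
    return segments


def segments_to_intervals(segments: Sequence[OccupancySegment]) -> list[Interval]:
    """Convenience: segment spans as Intervals with k in the score column."""
    return [
        replace(s.interval, score=float(s.k), name=",".join(sorted(s.factor_set)))
        for s in segments
    ]
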