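"""Binned coverage tracks, cross-sample rank-order normalization, and
anchored tag-density profiles in RPM (reads per million).

Rank-order normalization makes samples comparable by replacing each bin's
value with the cross-sample mean of values at the same descending rank, so
every sample keeps its own spatial rank structure but all samples end up
with the same value distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import Genome

__all__ = [
    "BinnedTrack",
    "ProfileMatrix",
    "bin_coverage",
    "bin_bedgraph",
    "rank_order_normalize",
    "anchored_profile",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass
class BinnedTrack:
    """Fixed-width binned signal for one sample across a genome."""

    label: str
    width: int
    values: dict[str, np.ndarray]
    total_reads: float | None = None  # library size for RPM scaling

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError(f"bin width must be >= 1, got {self.width}")
        for chrom, v in self.values.items():
            v = np.asarray(v, dtype=np.float64)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{chrom}: non-finite bin values")
            self.values[chrom] = v

    def flat(self, chrom_order: list[str] | None = None) -> np.ndarray:
        order = chrom_order or sorted(self.values)
        return np.concatenate([self.values[c] for c in order])

    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def compatible_with(self, other: "BinnedTrack") -> bool:
        return (
            self.width == other.width
            and set(self.values) == set(other.values)
            and all(len(self.values[c]) == len(other.values[c]) for c in self.values)
        )


@dataclass
class ProfileMatrix:
    """Anchors x relative-position bins, in RPM; NaN marks off-chromosome bins."""

    matrix: np.ndarray
    flank: int
    width: int
    anchor_ids: list[str] = field(default_factory=list)

    @property
    def positions(self) -> np.ndarray:
        """Bin-centre offsets relative to the anchor, in bp."""
        n = self.flank // self.width
        return (np.arange(-n, n) + 0.5) * self.width

    def column_means(self) -> np.ndarray:
        """Mean RPM per relative position, ignoring off-chromosome padding."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.matrix, axis=0)


def _n_bins(genome: Genome, chrom: str, width: int) -> int:
    return -(-genome[chrom] // width)  # ceil division


def bin_coverage(
    reads,
    genome: Genome,
    width: int,
    label: str = "sample",
    point: str = "start",
) -> BinnedTrack:
    """Bin point reads into fixed-width bins.

    `reads` is an iterable of (chrom, start, end) or (chrom, pos) tuples;
    each read is assigned to exactly one bin by its assignment point
    (``"start"`` = 5' start, ``"midpoint"``), so total signal equals the
    number of reads.
    """
    if point not in ("start", "midpoint"):
        raise ValueError(f"unknown assignment point {point!r}")
    values = {c: np.zeros(_n_bins(genome, c, width)) for c in genome.names}
    n = 0
    for read in reads:
        chrom = read[0]
        if chrom not in genome:
            raise ValueError(f"read on unknown chromosome {chrom!r}")
        if len(read) >= 3 and point == "midpoint":
            pos = (int(read[1]) + int(read[2])) // 2
        else:
            pos = int(read[1])
        if not (0 <= pos < genome[chrom]):
            raise ValueError(f"read position {pos} outside {chrom} [0, {genome[chrom]})")
        values[chrom][pos // width] += 1
        n += 1
    return BinnedTrack(label, width, values, total_reads=float(n))


def bin_bedgraph(
    entries,
    genome: Genome,
    width: int,
    label: str = "sample",
    total_reads: float | None = None,
) -> BinnedTrack:
    """Bin bedGraph intervals; each interval contributes value x overlap bp.

    Total binned signal equals sum(value x interval length) to float
    precision, i.e. base-level coverage mass is conserved.
    """
    values = {c: np.zeros(_n_bins(genome, c, width)) for c in genome.names}
    for chrom, start, end, value in entries:
        if chrom not in genome:
            raise ValueError(f"bedGraph entry on unknown chromosome {chrom!r}")
        start, end = int(start), int(end)
        if start < 0 or end > genome[chrom] or start >= end:
            raise ValueError(f"bad bedGraph interval {chrom}:{start}-{end}")
        b0, b1 = start // width, (end - 1) // width
        for b in range(b0, b1 + 1):
            lo = max(start, b * width)
            hi = min(end, (b + 1) * width)
            values[chrom][b] += float(value) * (hi - lo)
    return BinnedTrack(label, width, values, total_reads=total_reads)


def rank_order_normalize(tracks: list[BinnedTrack]) -> list[BinnedTrack]:
    """Quantile-style normalization preserving each sample's rank order.

    All samples' bins (genome-wide, zeros included) are sorted descending;
    the reference distribution is the across-sample mean at each rank; each
    sample's bins are re-assigned the reference value at their own rank.
    Tied values within a sample share the mean of the reference values their
    rank span covers, so the map is well defined and order preserving.
    """
    if len(tracks) < 2:
        raise ValueError("rank_order_normalize needs >= 2 tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if not t.compatible_with(first):
            raise ValueError(f"track {t.label!r} has a different bin grid")

    chrom_order = sorted(first.values)
    flats = [t.flat(chrom_order) for t in tracks]
    n = len(flats[0])
    # reference: mean across samples of ascending-sorted values
    ref = np.mean([np.sort(f) for f in flats], axis=0)

    out_tracks = []
    for t, f in zip(tracks, flats):
        order = np.argsort(f, kind="stable")
        assigned = np.empty(n)
        assigned[order] = ref
        # average reference values across each tied run
        sorted_vals = f[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals)) + 1
        starts = np.concatenate([[0], boundaries])
        sums = np.add.reduceat(ref, starts)
        lens = np.diff(np.concatenate([starts, [n]]))
        tie_means = sums / lens
        assigned_sorted = np.repeat(tie_means, lens)
        assigned[order] = assigned_sorted

        new_values = {}
        offset = 0
        for c in chrom_order:
            size = len(t.values[c])
            new_values[c] = assigned[offset:offset + size].copy()
            offset += size
        out_tracks.append(BinnedTrack(t.label, t.width, new_values, total_reads=t.total_reads))
    return out_tracks


def anchored_profile(
    track: BinnedTrack,
    anchors,
    flank: int,
    width: int | None = None,
) -> ProfileMatrix:
    """Per-anchor signal in RPM over [centre - flank, centre + flank).

    Anchors too close to a chromosome end are NaN-padded; padding is
    excluded from column means. Requires `track.total_reads` for RPM.
    """
    width = width or track.width
    if width != track.width:
        raise ValueError("profile bin width must match the track's bin width")
    if flank % width != 0 or flank <= 0:
        raise ValueError(f"flank ({flank}) must be a positive multiple of width ({width})")
    if not track.total_reads:
        raise ValueError("track needs total_reads for RPM scaling")
    half = flank // width
    scale = 1e6 / track.total_reads

    rows = []
    ids = []
    for anchor in anchors:
        chrom = anchor.chrom
        if chrom not in track.values:
            continue
        v = track.values[chrom]
        cb = anchor.center // width
        row = np.full(2 * half, np.nan)
        lo, hi = cb - half, cb + half
        s, e = max(lo, 0), min(hi, len(v))
        if e > s:
            row[s - lo:e - lo] = v[s:e] * scale
        rows.append(row)
        ids.append(anchor.name or f"{chrom}:{anchor.start}-{anchor.end}")
    if not rows:
        raise ValueError("no anchor lies on a chromosome covered by the track")
    return ProfileMatrix(np.vstack(rows), flank, width, ids)


def read_bedgraph(path):
    """Yield (chrom, start, end, value) tuples from a bedGraph file."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}, line {lineno}: expected 4 columns")
            yield parts[0], int(parts[1]), int(parts[2]), float(parts[3])


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write a binned track as bedGraph (one line per nonzero bin)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            for b in np.flatnonzero(v):
                fh.write(f"{chrom}\t{b * track.width}\t{(b + 1) * track.width}\t{v[b]:g}\n")


def profile_to_frame(profile: ProfileMatrix) -> pd.DataFrame:
    frame = pd.DataFrame(profile.matrix, columns=[f"{int(p)}" for p in profile.positions])
    frame.insert(0, "anchor", profile.anchor_ids)
    return frame
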