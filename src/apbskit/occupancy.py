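"""Architectural protein binding sites (APBSs): collapse, classify, summarise.

An APBS is a collapsed run of boundary-sharing occupancy segments, centred on
the segment with the most bound factors. Occupancy k (number of distinct
factors) maps onto three classes: low (1-3), medium (4-6), high (>=7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import Interval, OccupancySegment, PeakSet

__all__ = [
    "APBS",
    "GroupOccupancySummary",
    "classify",
    "collapse_segments",
    "anchor_occupancy",
    "overlap_fraction",
    "cobinding_matrix",
    "region_occupancy_summary",
    "DROSOPHILA_APBS_FACTORS",
    "DROSOPHILA_COMBINATORIAL_FACTORS",
]

# Factor-list presets: the 11-factor APBS panel and the 9-factor panel used
# to define combinatorially bound loci independently of TFIIIC/SMC complexes.
DROSOPHILA_APBS_FACTORS = (
    "dCTCF", "BEAF-32", "Su(Hw)", "CP190", "Mod(mdg4)", "DREF",
    "Chromator", "L(3)mbt", "dTFIIIC220", "Rad21", "CAP-H2",
)
DROSOPHILA_COMBINATORIAL_FACTORS = (
    "dCTCF", "BEAF-32", "Su(Hw)", "CP190", "Mod(mdg4)", "Zw5",
    "DREF", "Chromator", "L(3)mbt",
)

LOW_MAX = 3
MEDIUM_MAX = 6


def classify(k: int) -> str:
    """Map occupancy count k to its class: low (1-3), medium (4-6), high (>=7)."""
    if k <= 0:
        raise ValueError(f"occupancy k must be >= 1, got {k}")
    if k <= LOW_MAX:
        return "low"
    if k <= MEDIUM_MAX:
        return "medium"
    return "high"


@dataclass(frozen=True)
class APBS:
    """A collapsed occupancy site.

    ``interval`` spans the merged run; ``core`` is the representative
    (highest-k) segment the site is centred on; ``k`` and ``factor_set``
    come from that segment.
    """

    interval: Interval
    core: Interval
    factor_set: frozenset[str]
    k: int

    @property
    def occupancy_class(self) -> str:
        return classify(self.k)

    @property
    def center(self) -> int:
        return self.core.center


@dataclass(frozen=True)
class GroupOccupancySummary:
    group: str
    n: int
    mean_occupancy: float
    occupancies: tuple[int, ...]


def collapse_segments(segments: list[OccupancySegment]) -> list[APBS]:
    """Merge boundary-sharing segment runs into APBSs.

    Each maximal run of directly adjacent segments (gap 0) becomes one site
    whose span is the union of the run and whose factor set and k are taken
    from the highest-k segment in the run (ties: leftmost). Any gap of
    >= 1 bp separates sites.
    """
    out: list[APBS] = []
    run: list[OccupancySegment] = []

    def flush() -> None:
        if not run:
            return
        best = max(run, key=lambda s: s.k)  # max() keeps the leftmost on ties
        span = Interval(run[0].interval.chrom, run[0].interval.start, run[-1].interval.end)
        out.append(APBS(span, best.interval, best.factor_set, best.k))

    prev: OccupancySegment | None = None
    for seg in segments:
        if prev is not None:
            if seg.interval.chrom == prev.interval.chrom and seg.interval.start < prev.interval.end:
                raise ValueError("segments overlap or are unsorted")
            if seg.interval.chrom < prev.interval.chrom:
                raise ValueError("segments not sorted by chromosome")
        adjacent = (
            prev is not None
            and seg.interval.chrom == prev.interval.chrom
            and seg.interval.start == prev.interval.end
        )
        if not adjacent:
            flush()
            run = []
        run.append(seg)
        prev = seg
    flush()
    return out


def _merged_starts_ends(peaks: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged (start, end) arrays for fast overlap queries."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in peaks.by_chrom().items():
        starts, ends = [], []
        for iv in ivs:  # already sorted
            if ends and iv.start <= ends[-1]:
                ends[-1] = max(ends[-1], iv.end)
            else:
                starts.append(iv.start)
                ends.append(iv.end)
        out[chrom] = (np.asarray(starts), np.asarray(ends))
    return out


def _overlaps_any(chrom: str, start: int, end: int,
                  merged: dict[str, tuple[np.ndarray, np.ndarray]]) -> bool:
    if chrom not in merged:
        return False
    starts, ends = merged[chrom]
    i = int(np.searchsorted(starts, end, side="left"))  # candidates start before `end`
    return i > 0 and ends[i - 1] > start


def overlap_fraction(loci, peaks: PeakSet) -> tuple[int, float, int]:
    """Count loci with >= 1 bp overlap against a factor's peaks.

    Returns ``(count, fraction, percent)`` with percent rounded to the
    nearest integer, e.g. 1489 of 3728 -> 40.
    """
    loci = list(loci)
    if not loci:
        raise ValueError("overlap_fraction needs at least one locus")
    merged = _merged_starts_ends(peaks)
    count = 0
    for locus in loci:
        iv = locus.interval if isinstance(locus, APBS) else locus
        if _overlaps_any(iv.chrom, iv.start, iv.end, merged):
            count += 1
    frac = count / len(loci)
    return count, frac, int(round(frac * 100))


def cobinding_matrix(locus_sets: dict[str, list], factor_sets: list[PeakSet]) -> pd.DataFrame:
    """Overlap-frequency table: fraction of each locus set bound by each factor.

    Rows are locus-set labels, columns factor labels, entries in [0, 1].
    A factor scored against loci defined by that same factor yields 1.0.
    """
    data = {}
    for label, loci in locus_sets.items():
        row = {}
        for ps in factor_sets:
            _, frac, _ = overlap_fraction(loci, ps)
            row[ps.factor] = frac
        data[label] = row
    return pd.DataFrame.from_dict(data, orient="index")


def anchor_occupancy(
    anchors: PeakSet,
    factor_sets: list[PeakSet],
    radius: int = 500,
    subunit_groups: dict[str, str] | None = None,
) -> list[int]:
    """Anchor-based occupancy: distinct partner groups within `radius` bp.

    For each anchor, occupancy = 1 (the anchor factor itself) plus the number
    of distinct groups having at least one peak whose nearest edge lies
    within `radius` of the anchor centre. Factors sharing a group (multiple
    subunits of one complex) count once.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    subunit_groups = subunit_groups or {}
    groups: dict[str, list[PeakSet]] = {}
    for ps in factor_sets:
        groups.setdefault(subunit_groups.get(ps.factor, ps.factor), []).append(ps)

    # per group: sorted per-chromosome starts/ends
    group_ivs: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for g, sets in groups.items():
        per: dict[str, tuple[list, list]] = {}
        for ps in sets:
            for iv in ps:
                per.setdefault(iv.chrom, ([], []))
                per[iv.chrom][0].append(iv.start)
                per[iv.chrom][1].append(iv.end)
        group_ivs[g] = {
            c: (np.sort(np.asarray(s)), np.asarray(e)[np.argsort(np.asarray(s))])
            for c, (s, e) in per.items()
        }

    occ = []
    for anchor in anchors:
        c = anchor.center
        n = 1
        for g, per in group_ivs.items():
            if anchor.chrom not in per:
                continue
            starts, ends = per[anchor.chrom]
            # nearest-edge distance from centre c to interval [s, e)
            d = np.maximum(0, np.maximum(starts - c, c - (ends - 1)))
            if d.size and d.min() <= radius:
                n += 1
        occ.append(n)
    return occ


def region_occupancy_summary(
    regions: list[tuple[str, Interval]],
    apbs: list[APBS],
) -> list[GroupOccupancySummary]:
    """Per-group mean occupancy of labelled regions.

    A region's occupancy is the maximum k among APBSs overlapping it,
    0 if none overlap. Group means are reported to one decimal.
    """
    by_group: dict[str, list[int]] = {}
    for label, region in regions:
        best = 0
        for site in apbs:
            if site.interval.overlaps(region):
                best = max(best, site.k)
        by_group.setdefault(label, []).append(best)
    return [
        GroupOccupancySummary(g, len(v), round(float(np.mean(v)), 1), tuple(v))
        for g, v in by_group.items()
    ]


def apbs_to_bed_rows(sites: list[APBS]) -> list[Interval]:
    """APBS catalog as BED6-ready intervals: name = factor set, score = k."""
    from dataclasses import replace

    return [
        replace(s.interval, score=float(s.k), name=",".join(sorted(s.factor_set)))
        for s in sites
    ]


def membership_table(sites: list[APBS], factors: tuple[str, ...]) -> pd.DataFrame:
    """Locus x factor boolean matrix of the catalog."""
    rows = []
    for s in sites:
        rows.append({
            "chrom": s.interval.chrom,
            "start": s.interval.start,
            "end": s.interval.end,
            "k": s.k,
            "class": s.occupancy_class,
            **{f: (f in s.factor_set) for f in factors},
        })
    return pd.DataFrame(rows)
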