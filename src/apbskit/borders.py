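"""TAD border strength from restriction-fragment Hi-C contact maps.

The border-strength statistic is a local contrast at each restriction cut
site S: mean per-pair contact count within the w fragments on either side of
S (intra), divided by the mean per-pair count between the two sides (inter),
then centred so the genome-wide median equals 1. Strong TAD borders show
high local contrast (rich intra-domain, poor cross-border contacts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .intervals import Interval
from .occupancy import APBS, classify

__all__ = [
    "FragmentMap",
    "ContactMatrix",
    "TADSet",
    "BorderScore",
    "local_contrast",
    "delineate_borders",
    "strength_by_occupancy",
    "tad_size_by_apbs",
    "read_contacts_tsv",
    "write_contacts_tsv",
    "scores_to_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentMap:
    """Per-chromosome restriction cut sites; fragment i = [cut_i, cut_{i+1})."""

    cuts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, c in self.cuts.items():
            c = np.asarray(c)
            if c.ndim != 1 or len(c) < 2 or np.any(np.diff(c) <= 0):
                raise ValueError(f"{chrom}: cut sites must be strictly increasing, >= 2")
            self.cuts[chrom] = c

    def n_fragments(self, chrom: str) -> int:
        return len(self.cuts[chrom]) - 1

    def fragment_bounds(self, chrom: str, i: int) -> tuple[int, int]:
        c = self.cuts[chrom]
        return int(c[i]), int(c[i + 1])

    def fragment_at(self, chrom: str, pos: int) -> int | None:
        """Index of the fragment containing bp position `pos`, or None."""
        c = self.cuts[chrom]
        if pos < c[0] or pos >= c[-1]:
            return None
        return int(np.searchsorted(c, pos, side="right") - 1)


@dataclass
class ContactMatrix:
    """Symmetric fragment-level contact counts for one chromosome."""

    chrom: str
    counts: sparse.csr_matrix  # upper triangle is authoritative; symmetric

    @classmethod
    def from_triplets(cls, chrom: str, i, j, c, n_fragments: int) -> "ContactMatrix":
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        c = np.asarray(c, dtype=np.float64)
        if np.any(i < 0) or np.any(j < 0) or np.any(i >= n_fragments) or np.any(j >= n_fragments):
            raise ValueError(f"{chrom}: fragment index out of range (F={n_fragments})")
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        m = sparse.coo_matrix((c, (lo, hi)), shape=(n_fragments, n_fragments)).tocsr()
        m.sum_duplicates()
        return cls(chrom, m)

    @property
    def n_fragments(self) -> int:
        return self.counts.shape[0]

    def dense_symmetric(self) -> np.ndarray:
        """Full symmetric dense matrix with zero diagonal."""
        upper = self.counts.toarray()
        full = upper + upper.T
        np.fill_diagonal(full, 0.0)
        return full


@dataclass
class TADSet:
    """Ordered, non-overlapping domains in bp; borders between consecutive domains."""

    domains: list[Interval]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Interval]] = {}
        for d in self.domains:
            by_chrom.setdefault(d.chrom, []).append(d)
        for chrom, ds in by_chrom.items():
            ds.sort()
            for a, b in zip(ds, ds[1:]):
                if b.start < a.end:
                    raise ValueError(f"{chrom}: overlapping domains {a} / {b}")
        self.domains = [d for c in sorted(by_chrom) for d in by_chrom[c]]

    def borders(self) -> list[tuple[str, int]]:
        """(chrom, bp) positions between consecutive domains."""
        out = []
        by_chrom: dict[str, list[Interval]] = {}
        for d in self.domains:
            by_chrom.setdefault(d.chrom, []).append(d)
        for chrom in sorted(by_chrom):
            ds = by_chrom[chrom]
            for a, b in zip(ds, ds[1:]):
                out.append((chrom, (a.end + b.start) // 2))
        return out


@dataclass(frozen=True)
class BorderScore:
    chrom: str
    cut_index: int  # cut site index s: between fragments s-1 and s
    cut_bp: int
    raw: float
    centered: float


def local_contrast(
    matrices: list[ContactMatrix] | ContactMatrix,
    fragmap: FragmentMap,
    window_w: int = 10,
    pseudocount: float = 1.0,
) -> list[BorderScore]:
    """Score every interior cut site by intra/inter contact contrast.

    At cut site s, A is the `window_w` fragments left of s and B the
    `window_w` fragments right. Per-pair means exclude the diagonal:

        raw = (intra_sum / n_intra_pairs) / ((inter_sum + pseudocount) / n_inter_pairs)

    with n_intra_pairs = w(w-1) (both sides pooled) and n_inter_pairs = w^2.
    Centred scores divide by the median raw score over all scored sites, so
    the genome-wide median is exactly 1.
    """
    if isinstance(matrices, ContactMatrix):
        matrices = [matrices]
    if window_w < 2:
        raise ValueError(f"window_w must be >= 2, got {window_w}")
    w = window_w
    n_intra = w * (w - 1)  # w*(w-1)/2 unordered pairs per side, two sides
    n_inter = w * w

    raw_scores: list[tuple[str, int, int, float]] = []
    for cm in matrices:
        F = cm.n_fragments
        if F < 2 * w:  # at least one interior cut site with w fragments per side
            log.info("chromosome %s has %d fragments < 2w=%d; skipped", cm.chrom, F, 2 * w)
            continue
        full = cm.dense_symmetric()
        # summed-area table over the symmetric matrix
        P = np.zeros((F + 1, F + 1))
        P[1:, 1:] = np.cumsum(np.cumsum(full, axis=0), axis=1)

        def block(r0: int, r1: int, c0: int, c1: int) -> float:
            return P[r1, c1] - P[r0, c1] - P[r1, c0] + P[r0, c0]

        cuts = fragmap.cuts[cm.chrom]
        for s in range(w, F - w + 1):
            a0, a1 = s - w, s
            b0, b1 = s, s + w
            intra = (block(a0, a1, a0, a1) + block(b0, b1, b0, b1)) / 2.0  # symmetric, zero diag
            inter = block(a0, a1, b0, b1)
            raw = (intra / n_intra) / ((inter + pseudocount) / n_inter)
            raw_scores.append((cm.chrom, s, int(cuts[s]), raw))

    if not raw_scores:
        raise ValueError("no cut site could be scored (windows exceed every chromosome)")
    raws = np.array([r[3] for r in raw_scores])
    med = float(np.median(raws))
    if med == 0.0:
        raise ValueError("degenerate input: median raw contrast is 0 (all-zero matrix?)")
    centered = raws / med
    for _ in range(3):  # polish away even-count rounding so the median is exactly 1
        m = float(np.median(centered))
        if m == 1.0:
            break
        centered = centered / m
    return [
        BorderScore(chrom, s, bp, raw, float(c))
        for (chrom, s, bp, raw), c in zip(raw_scores, centered)
    ]


def scores_to_frame(scores: list[BorderScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.chrom, b.cut_index, b.cut_bp, b.raw, b.centered) for b in scores],
        columns=["chrom", "cut_index", "cut_bp", "raw_contrast", "border_strength"],
    )


def delineate_borders(
    tads: TADSet,
    apbs: list[APBS],
    fragmap: FragmentMap | None = None,
    window: str | int = "one_cut_site",
) -> tuple[list[str], dict[str, float]]:
    """Label each TAD border by the best APBS class within a window.

    Mode ``"one_cut_site"`` uses the two fragments flanking the cut site
    nearest the border; an integer window uses border position +- window bp.
    Borders with no APBS in the window are labelled ``"none"``. Returns
    per-border labels and class percentages (summing to ~100).
    """
    borders = tads.borders()
    if not borders:
        raise ValueError("TAD set implies no borders")
    if window == "one_cut_site" and fragmap is None:
        raise ValueError("one_cut_site mode requires a fragment map")

    by_chrom: dict[str, list[APBS]] = {}
    for site in apbs:
        by_chrom.setdefault(site.interval.chrom, []).append(site)

    labels = []
    rank = {"none": 0, "low": 1, "medium": 2, "high": 3}
    for chrom, pos in borders:
        if window == "one_cut_site":
            cuts = fragmap.cuts.get(chrom)
            if cuts is None:
                labels.append("none")
                continue
            s = int(np.clip(np.searchsorted(cuts, pos), 1, len(cuts) - 1))
            # pick the nearer of the flanking cut sites
            if s > 1 and abs(int(cuts[s - 1]) - pos) < abs(int(cuts[s]) - pos):
                s -= 1
            lo = int(cuts[max(s - 1, 0)])
            hi = int(cuts[min(s + 1, len(cuts) - 1)])
        else:
            lo, hi = pos - int(window), pos + int(window)
        best = "none"
        for site in by_chrom.get(chrom, ()):  # windows are few; linear scan is fine
            if site.interval.start < hi and lo < site.interval.end:
                cls = site.occupancy_class
                if rank[cls] > rank[best]:
                    best = cls
        labels.append(best)

    pct = {
        cls: 100.0 * sum(1 for l in labels if l == cls) / len(labels)
        for cls in ("high", "medium", "low", "none")
    }
    return labels, pct


def strength_by_occupancy(
    apbs: list[APBS],
    scores: list[BorderScore],
    max_dist: int = 5000,
) -> pd.DataFrame:
    """Mean centred contrast per occupancy k (and per class).

    Each APBS is assigned the nearest scored cut site (by centre-to-cut
    distance); sites farther than `max_dist` from any scored cut are
    dropped and counted in the ``excluded`` attribute of the result.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {b.chrom for b in scores}:
        sub = [(b.cut_bp, b.centered) for b in scores if b.chrom == chrom]
        sub.sort()
        by_chrom[chrom] = (np.array([s[0] for s in sub]), np.array([s[1] for s in sub]))

    rows = []
    excluded = 0
    for site in apbs:
        if site.interval.chrom not in by_chrom:
            excluded += 1
            continue
        bps, ls = by_chrom[site.interval.chrom]
        c = site.center
        i = int(np.searchsorted(bps, c))
        cand = [j for j in (i - 1, i) if 0 <= j < len(bps)]
        j = min(cand, key=lambda j: abs(int(bps[j]) - c))
        if abs(int(bps[j]) - c) > max_dist:
            excluded += 1
            continue
        rows.append({"k": site.k, "class": site.occupancy_class, "L": ls[j]})
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError("no APBS lies within max_dist of a scored cut site")
    out = frame.groupby("k")["L"].agg(n="size", mean_strength="mean", sd_strength="std").reset_index()
    out.attrs["excluded"] = excluded
    out.attrs["by_class"] = (
        frame.groupby("class")["L"].agg(n="size", mean_strength="mean").reset_index()
    )
    return out


def tad_size_by_apbs(
    tads: TADSet,
    apbs: list[APBS],
    density_radius: int = 10_000,
    n_strata: int = 3,
) -> dict:
    """TAD size versus local APBS density around its borders.

    For each domain: size (bp), the max APBS k within `density_radius` of
    either domain edge, and the APBS count in those windows (density).
    Returns per-stratum median sizes (density terciles by default) and the
    Spearman rank correlation between size and density.
    """
    if len(tads.domains) < 2:
        raise ValueError("need at least two TADs")
    centers: dict[str, np.ndarray] = {}
    ks: dict[str, np.ndarray] = {}
    for chrom in {d.chrom for d in tads.domains}:
        sub = sorted((s.center, s.k) for s in apbs if s.interval.chrom == chrom)
        centers[chrom] = np.array([x[0] for x in sub])
        ks[chrom] = np.array([x[1] for x in sub])

    rows = []
    for d in tads.domains:
        cs, kk = centers[d.chrom], ks[d.chrom]
        density = 0
        max_k = 0
        for edge in (d.start, d.end):
            if cs.size:
                lo = np.searchsorted(cs, edge - density_radius, side="left")
                hi = np.searchsorted(cs, edge + density_radius, side="right")
                density += hi - lo
                if hi > lo:
                    max_k = max(max_k, int(kk[lo:hi].max()))
        rows.append({"chrom": d.chrom, "size": len(d), "density": density, "max_border_k": max_k})
    frame = pd.DataFrame(rows)

    qs = np.quantile(frame["density"], np.linspace(0, 1, n_strata + 1))
    strata = np.clip(np.searchsorted(qs, frame["density"], side="right") - 1, 0, n_strata - 1)
    frame["stratum"] = strata
    medians = frame.groupby("stratum")["size"].median().to_dict()
    if frame["density"].nunique() > 1 and frame["size"].nunique() > 1:
        rho, p = stats.spearmanr(frame["size"], frame["density"])
    else:
        rho, p = 0.0, 1.0
    return {"per_tad": frame, "median_size_by_stratum": medians,
            "spearman_rho": float(rho), "spearman_p": float(p)}


def read_contacts_tsv(path, fragmap: FragmentMap) -> list[ContactMatrix]:
    """Read sparse triplets (chrom, i, j, count) into per-chromosome matrices."""
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["chrom", "i", "j", "count"], comment="#")
    out = []
    for chrom, sub in frame.groupby("chrom", sort=True):
        out.append(ContactMatrix.from_triplets(
            str(chrom), sub["i"].to_numpy(), sub["j"].to_numpy(),
            sub["count"].to_numpy(), fragmap.n_fragments(str(chrom)),
        ))
    return out


def write_contacts_tsv(matrices: list[ContactMatrix], path) -> None:
    with open(path, "w") as fh:
        for cm in matrices:
            coo = cm.counts.tocoo()
            order = np.lexsort((coo.col, coo.row))
            for r, c, v in zip(coo.row[order], coo.col[order], coo.data[order]):
                if v != 0:
                    fh.write(f"{cm.chrom}\t{r}\t{c}\t{v:g}\n")
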