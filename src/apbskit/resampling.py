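"""Chromosome-aware shuffling nulls and Monte Carlo permutation tests.

Empirical P values follow the convention P = r/n with r = #{null >= observed};
zero exceedances are reported as the bound "P < 1/n" (flagged), never as 0.
Observed/expected enrichment is log2(observed / null mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Callable, Sequence

import numpy as np

from .intervals import Genome, Interval, PeakSet

__all__ = [
    "EnrichmentResult",
    "shuffle_sites",
    "perm_test",
    "label_perm_test",
    "obs_over_exp",
]


@dataclass(frozen=True)
class EnrichmentResult:
    observed: float
    expected: float  # null mean
    null_sd: float
    log2_ratio: float | None  # None when expected == 0
    p_value: float
    p_is_upper_bound: bool  # True when r = 0: P reported as "< 1/n"
    n_perm: int
    seed: int | None
    null_sample: np.ndarray | None = None

    @property
    def p_display(self) -> str:
        """Decimal-style report, e.g. ``P < 0.00001`` for 0/100,000 exceedances."""
        p = np.format_float_positional(self.p_value, trim="-")
        return f"P < {p}" if self.p_is_upper_bound else f"P = {p}"


def shuffle_sites(
    sites: PeakSet | Sequence[Interval],
    genome: Genome,
    mode: str = "chrom_bounded",
    rng: np.random.Generator | None = None,
) -> list[Interval]:
    """Randomize site positions, preserving per-chromosome counts and lengths.

    ``chrom_bounded``: new starts uniform in [0, chrom_len - len].
    ``span_bounded``: uniform in [min start, max end - len] of the original
    sites on that chromosome (the span actually occupied by the data), with
    all auxiliary attributes (score, name) carried along.
    """
    if mode not in ("chrom_bounded", "span_bounded"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    rng = rng if rng is not None else np.random.default_rng()
    intervals = list(sites.intervals if isinstance(sites, PeakSet) else sites)

    bounds: dict[str, tuple[int, int]] = {}
    for iv in intervals:
        if mode == "chrom_bounded":
            bounds.setdefault(iv.chrom, (0, genome[iv.chrom]))
        else:
            lo, hi = bounds.get(iv.chrom, (iv.start, iv.end))
            bounds[iv.chrom] = (min(lo, iv.start), max(hi, iv.end))

    out: list[Interval] = []  # original input order preserved
    for iv in intervals:
        lo, hi = bounds[iv.chrom]
        length = len(iv)
        span = hi - lo - length
        if span < 0:
            raise ValueError(
                f"site of length {length} cannot be placed in [{lo}, {hi}) on {iv.chrom}"
            )
        start = lo + int(rng.integers(0, span + 1))
        summit = None if iv.summit is None else start + (iv.summit - iv.start)
        out.append(dc_replace(iv, start=start, end=start + length, summit=summit))
    return out


def _finalize(observed: float, null: np.ndarray, n: int, seed, keep_null: bool) -> EnrichmentResult:
    r = int(np.sum(null >= observed))
    if r == 0:
        p, bound = 1.0 / n, True
    else:
        p, bound = r / n, False
    expected = float(np.mean(null))
    if expected > 0 and observed > 0:
        log2_ratio = math.log2(observed / expected)
    elif expected > 0:
        log2_ratio = -math.inf
    else:
        log2_ratio = None
    return EnrichmentResult(
        observed=float(observed),
        expected=expected,
        null_sd=float(np.std(null)),
        log2_ratio=log2_ratio,
        p_value=p,
        p_is_upper_bound=bound,
        n_perm=n,
        seed=seed,
        null_sample=null if keep_null else None,
    )


def perm_test(
    observed: float,
    statistic: Callable[[np.random.Generator], float],
    n: int = 100_000,
    seed: int | None = None,
    keep_null: bool = True,
) -> EnrichmentResult:
    """One-sided Monte Carlo permutation test.

    `statistic` draws one null value per call from the supplied generator
    (typically: shuffle the sites, recompute the overlap statistic).
    P = #{null >= observed} / n; zero exceedances report the bound 1/n.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    null = np.empty(n)
    for i in range(n):
        null[i] = statistic(rng)
    return _finalize(observed, null, n, seed, keep_null)


def label_perm_test(
    labels: Sequence,
    statistic: Callable[[Sequence], float],
    n: int = 100_000,
    seed: int | None = None,
    alternative: str = "greater",
    keep_null: bool = True,
) -> EnrichmentResult:
    """Permutation test randomizing site labels with positions fixed.

    `statistic(labels)` maps a label assignment to a scalar; the observed
    value uses the given labels, the null permutes them uniformly. The
    default alternative is one-sided (null >= observed); "two-sided"
    doubles the smaller tail (capped at 1).
    """
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("label permutation needs >= 2 distinct label classes")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    observed = float(statistic(labels))
    arr = np.array(labels, dtype=object)
    null = np.empty(n)
    for i in range(n):
        null[i] = statistic(list(rng.permutation(arr)))
    res = _finalize(observed, null, n, seed, keep_null)
    if alternative == "two-sided":
        r_hi = int(np.sum(null >= observed))
        r_lo = int(np.sum(null <= observed))
        r = min(r_hi, r_lo)
        if r == 0:
            p, bound = min(1.0, 2.0 / n), True
        else:
            p, bound = min(1.0, 2.0 * r / n), False
        res = dc_replace(res, p_value=p, p_is_upper_bound=bound)
    return res


def obs_over_exp(observed: float, null_sample) -> tuple[float | None, str]:
    """log2(observed / null mean) with an enrichment/depletion call.

    Returns (None, "undefined") when the null mean is 0.
    """
    null = np.asarray(null_sample, dtype=float)
    expected = float(np.mean(null))
    if expected == 0:
        return None, "undefined"
    if observed == 0:
        return -math.inf, "depleted"
    ratio = math.log2(observed / expected)
    sign = "enriched" if ratio > 0 else ("depleted" if ratio < 0 else "neutral")
    return ratio, sign
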