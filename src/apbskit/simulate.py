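"""Seeded synthetic-data generators with planted ground truth.

Every pipeline input class can be generated here: clustered multi-factor
peak landscapes, distance-decay Hi-C contact maps with leaky TAD borders,
multi-sample coverage tracks sharing a latent rank structure, and
multi-cell-line site catalogs with a planted specific-to-constitutive
ubiquity axis. Generators are pure functions of (config, seed): identical
inputs give bit-identical outputs, and every emitted object passes the
consuming module's validators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .borders import ContactMatrix, FragmentMap, TADSet
from .intervals import Genome, Interval, PeakSet
from .occupancy import DROSOPHILA_APBS_FACTORS
from .tracks import BinnedTrack

__all__ = [
    "SynthConfig",
    "gen_factor_peaks",
    "gen_contact_map",
    "gen_tracks",
    "gen_cell_line_catalogs",
]


@dataclass
class SynthConfig:
    """Parameters of the synthetic study conditions.

    Defaults mirror the statistical structure the analysis assumes: a small
    multi-chromosome genome, 300 co-binding loci with an occupancy spectrum
    skewed toward low k, summit jitter well below the 200 bp window
    halfwidth, 21 TADs (20 interior borders) with a leakage grid spanning
    0.1-0.9, Poisson contact counts with amplitude 100 and decay exponent 1.
    """

    seed: int = 0
    # genome
    n_chromosomes: int = 2
    chrom_length: int = 16_000_000
    # factor peak landscape
    factors: tuple[str, ...] = DROSOPHILA_APBS_FACTORS
    n_loci: int = 300
    occupancy_weights: tuple[float, ...] = (
        0.25, 0.17, 0.13, 0.10, 0.08, 0.07, 0.06, 0.05, 0.04, 0.03, 0.02
    )  # P(k = 1..11)
    summit_jitter_sd: float = 50.0
    peak_halfwidth: int = 200
    background_rate_per_mb: float = 1.0
    min_locus_gap: int = 3000
    # contact map
    n_domains: int = 21
    mean_fragment_length: int = 2000
    min_fragment_length: int = 500
    fragments_per_domain: int = 40
    leakage_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    contact_amplitude: float = 100.0
    decay_exponent: float = 1.0
    count_noise: str = "poisson"  # or "nbinom"
    nbinom_dispersion: float = 10.0
    # tracks
    n_samples: int = 3
    track_bin_width: int = 100
    track_noise_sd: float = 0.0
    track_background: float = 1.0
    # cell-line catalogs
    n_experiments: int = 20
    n_sites: int = 4000
    site_halfwidth: int = 100
    min_site_gap: int = 1100
    n_borders_per_chrom: int = 50
    constitutive_fraction: float = 0.05
    border_prob_range: tuple[float, float] = (0.02, 0.9)
    border_window: int = 20_000
    drop_probability: float = 0.0

    def genome(self) -> Genome:
        return Genome({f"chr{i + 1}": self.chrom_length for i in range(self.n_chromosomes)})

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("synthetic config requires an explicit seed")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("factors", "occupancy_weights", "leakage_grid", "border_prob_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _locus_positions(config: SynthConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Place loci with a guaranteed minimum gap by jittering a regular grid."""
    genome = config.genome()
    per_chrom = np.full(config.n_chromosomes, config.n_loci // config.n_chromosomes)
    per_chrom[: config.n_loci % config.n_chromosomes] += 1
    out = []
    for ci, chrom in enumerate(genome.names):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        slot = genome[chrom] // n
        margin = config.min_locus_gap // 2 + config.peak_halfwidth
        if slot <= 2 * margin:
            raise ValueError(
                f"locus density too high on {chrom}: slot {slot} bp cannot hold "
                f"min gap {config.min_locus_gap} plus windows"
            )
        offsets = rng.integers(margin, slot - margin, size=n)
        for i in range(n):
            out.append((chrom, int(i * slot + offsets[i])))
    return out


def gen_factor_peaks(config: SynthConfig) -> tuple[dict[str, PeakSet], pd.DataFrame]:
    """Clustered co-binding landscape: k factors per planted locus + background.

    Each locus draws k from the occupancy distribution and k factors
    (weighted by a decreasing per-factor frequency), each contributing a
    peak whose summit is the locus centre plus truncated Gaussian jitter.
    Independent background peaks are added per factor. The truth table
    records each locus's position, k and factor subset.
    """
    rng = np.random.default_rng(config.seed)
    genome = config.genome()
    factors = config.factors
    weights = np.asarray(config.occupancy_weights, dtype=float)
    if len(weights) != len(factors):
        raise ValueError("occupancy_weights must have one entry per possible k = 1..n_factors")
    weights = weights / weights.sum()
    factor_freq = np.linspace(1.0, 0.4, len(factors))
    factor_freq /= factor_freq.sum()

    loci = _locus_positions(config, rng)
    peaks: dict[str, list[Interval]] = {f: [] for f in factors}
    truth_rows = []
    for li, (chrom, center) in enumerate(loci):
        k = int(rng.choice(np.arange(1, len(factors) + 1), p=weights))
        members = rng.choice(len(factors), size=k, replace=False, p=factor_freq)
        chosen = [factors[i] for i in sorted(members)]
        for f in chosen:
            jitter = rng.normal(0.0, config.summit_jitter_sd) if config.summit_jitter_sd > 0 else 0.0
            summit = int(np.clip(center + jitter, config.peak_halfwidth,
                                 genome[chrom] - config.peak_halfwidth - 1))
            peaks[f].append(Interval(
                chrom, summit - config.peak_halfwidth, summit + config.peak_halfwidth,
                summit=summit, name=f"locus{li}",
            ))
        truth_rows.append({
            "locus": li, "chrom": chrom, "center": center,
            "k": k, "factors": ",".join(chosen),
        })

    n_bg = rng.poisson(
        config.background_rate_per_mb * config.chrom_length / 1e6,
        size=(len(factors), config.n_chromosomes),
    )
    for fi, f in enumerate(factors):
        for ci, chrom in enumerate(genome.names):
            starts = rng.integers(
                0, config.chrom_length - 2 * config.peak_halfwidth, size=int(n_bg[fi, ci])
            )
            for s in starts:
                s = int(s)
                peaks[f].append(Interval(
                    chrom, s, s + 2 * config.peak_halfwidth,
                    summit=s + config.peak_halfwidth, name="background",
                ))

    return (
        {f: PeakSet(f, ivs) for f, ivs in peaks.items()},
        pd.DataFrame(truth_rows),
    )


def gen_contact_map(
    config: SynthConfig,
) -> tuple[list[ContactMatrix], FragmentMap, TADSet, pd.DataFrame]:
    """Distance-decay Hi-C map with TADs of tunable border leakage.

    Expected counts for fragments i < j on one chromosome:
        E_ij = A * (d_ij + 1)^(-alpha) * prod(lambda_b over borders between i and j)
    with d_ij = j - i, sampled with Poisson (or negative binomial) noise.
    Border leakage lambda is assigned by cycling the configured grid; the
    truth table records each border's cut index, bp position and lambda.
    """
    if config.decay_exponent <= 0:
        raise ValueError("decay exponent must be > 0")
    rng = np.random.default_rng(config.seed + 1)
    chrom = "chr1"
    F = config.n_domains * config.fragments_per_domain
    lengths = np.maximum(
        config.min_fragment_length,
        rng.exponential(config.mean_fragment_length, size=F).astype(int),
    )
    cuts = np.concatenate([[0], np.cumsum(lengths)])
    fragmap = FragmentMap({chrom: cuts})

    # borders at fragment indices: between consecutive equal-size domains
    border_idx = np.arange(1, config.n_domains) * config.fragments_per_domain
    grid = np.asarray(config.leakage_grid, dtype=float)
    lam = np.array([grid[b % len(grid)] for b in range(len(border_idx))])

    # cumulative log-leakage: crossing borders multiplies expected counts
    log_lam_at = np.zeros(F)
    for bi, s in enumerate(border_idx):
        log_lam_at[s:] += np.log(lam[bi])

    i, j = np.triu_indices(F, k=1)
    d = (j - i).astype(float)
    log_e = (
        np.log(config.contact_amplitude)
        - config.decay_exponent * np.log1p(d)
        + (log_lam_at[j] - log_lam_at[i])
    )
    expected = np.exp(log_e)
    if config.count_noise == "poisson":
        counts = rng.poisson(expected)
    elif config.count_noise == "nbinom":
        r = config.nbinom_dispersion
        counts = rng.negative_binomial(r, r / (r + expected))
    else:
        raise ValueError(f"unknown count noise model {config.count_noise!r}")

    nz = counts > 0
    cm = ContactMatrix.from_triplets(chrom, i[nz], j[nz], counts[nz], F)

    domains = [
        Interval(chrom, int(cuts[di * config.fragments_per_domain]),
                 int(cuts[(di + 1) * config.fragments_per_domain]))
        for di in range(config.n_domains)
    ]
    truth = pd.DataFrame({
        "border": np.arange(len(border_idx)),
        "chrom": chrom,
        "cut_index": border_idx,
        "cut_bp": cuts[border_idx],
        "leakage": lam,
    })
    return [cm], fragmap, TADSet(domains), truth


def gen_tracks(
    config: SynthConfig,
    loci_truth: pd.DataFrame | None = None,
    distortions: list | None = None,
) -> tuple[list[BinnedTrack], dict[str, np.ndarray]]:
    """Multi-sample tracks sharing one latent signal, with per-sample
    monotone distortion and optional additive noise.

    The latent track is a flat background plus Gaussian bumps at planted
    loci with amplitude proportional to occupancy k. Each sample s applies
    a monotone map (power-law gamma plus scale) to the latent values, so
    samples differ in value scale but share rank structure. Returns the
    tracks and the latent signal (the truth).
    """
    rng = np.random.default_rng(config.seed + 2)
    genome = config.genome()
    width = config.track_bin_width
    latent = {
        c: np.full(-(-genome[c] // width), config.track_background)
        for c in genome.names
    }
    if loci_truth is None:
        loci_truth = gen_factor_peaks(config)[1]
    bump_halfwidth_bins = max(1, config.peak_halfwidth // width)
    xs = np.arange(-3 * bump_halfwidth_bins, 3 * bump_halfwidth_bins + 1)
    kernel = np.exp(-0.5 * (xs / bump_halfwidth_bins) ** 2)
    for _, row in loci_truth.iterrows():
        v = latent[row["chrom"]]
        b = int(row["center"]) // width
        lo, hi = max(0, b + xs[0]), min(len(v), b + xs[-1] + 1)
        v[lo:hi] += float(row["k"]) * kernel[lo - (b + xs[0]): hi - (b + xs[0])]

    if distortions is None:
        gammas = np.linspace(0.8, 1.2, config.n_samples)
        scales = np.linspace(0.5, 2.0, config.n_samples)
        distortions = [
            (lambda v, g=g, s=s: s * np.power(v, g)) for g, s in zip(gammas, scales)
        ]
    tracks = []
    for si, f in enumerate(distortions):
        values = {}
        for c, v in latent.items():
            out = f(v)
            if config.track_noise_sd > 0:
                out = np.maximum(0.0, out + rng.normal(0, config.track_noise_sd, size=len(v)))
            values[c] = out
        total = float(sum(vv.sum() for vv in values.values()))
        tracks.append(BinnedTrack(f"sample{si + 1}", width, values, total_reads=total))
    return tracks, latent


def gen_cell_line_catalogs(
    config: SynthConfig,
    borders: list[tuple[str, int]] | None = None,
) -> tuple[dict[str, PeakSet], pd.DataFrame, list[tuple[str, int]]]:
    """Per-cell-line site catalogs with a planted ubiquity-border coupling.

    Each site draws a planted ubiquity u in [2, n_experiments]; its
    probability of being placed at a TAD border rises linearly with u over
    `border_prob_range`. The site appears in u randomly chosen experiments,
    minus per-line dropouts at `drop_probability`. Truth records each
    site's centre, u and border status. Returns the catalogs, the truth
    table, and the (possibly generated) border positions.
    """
    import bisect

    rng = np.random.default_rng(config.seed + 3)
    genome = config.genome()
    if borders is None:
        borders = []
        for chrom in genome.names:
            pos = np.sort(rng.integers(200_000, genome[chrom] - 200_000,
                                       size=config.n_borders_per_chrom))
            borders.extend((chrom, int(p)) for p in pos)
    borders_by_chrom: dict[str, np.ndarray] = {}
    for chrom, p in borders:
        borders_by_chrom.setdefault(chrom, [])
        borders_by_chrom[chrom].append(p)
    borders_by_chrom = {c: np.sort(np.asarray(v)) for c, v in borders_by_chrom.items()}

    labels = [f"exp{e + 1:02d}" for e in range(config.n_experiments)]
    p_lo, p_hi = config.border_prob_range
    hw = config.site_halfwidth
    # planted composites stay > 1 kb apart so clustering recovers them one-to-one
    # and the dominant-neighbour merge rule cannot rewire the planted axis
    min_gap = config.min_site_gap

    per_exp: dict[str, list[Interval]] = {l: [] for l in labels}
    truth_rows = []
    chrom_names = genome.names
    occupied: dict[str, list[int]] = {c: [] for c in chrom_names}  # kept sorted
    n_const = int(round(config.n_sites * config.constitutive_fraction))

    for si in range(config.n_sites):
        if si < n_const:
            u = config.n_experiments
        else:
            u = int(rng.integers(2, config.n_experiments + 1))
        p_border = p_lo + (p_hi - p_lo) * (u - 2) / max(1, config.n_experiments - 2)
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        at_border = bool(rng.random() < p_border) and chrom in borders_by_chrom
        occ = occupied[chrom]
        placed = False
        for _ in range(100):
            if at_border:
                b = int(rng.choice(borders_by_chrom[chrom]))
                center = b + int(rng.integers(-config.border_window // 2,
                                              config.border_window // 2 + 1))
            else:
                center = int(rng.integers(hw, genome[chrom] - hw))
            center = int(np.clip(center, hw, genome[chrom] - hw - 1))
            i = bisect.bisect_left(occ, center)
            clear = (i == 0 or center - occ[i - 1] >= min_gap) and (
                i == len(occ) or occ[i] - center >= min_gap
            )
            if clear:
                placed = True
                break
        if not placed and at_border:
            # crowded border neighbourhoods fall back to a uniform placement
            at_border = False
            for _ in range(100):
                center = int(rng.integers(hw, genome[chrom] - hw))
                i = bisect.bisect_left(occ, center)
                if (i == 0 or center - occ[i - 1] >= min_gap) and (
                    i == len(occ) or occ[i] - center >= min_gap
                ):
                    break
        bisect.insort(occ, center)
        chosen = rng.choice(config.n_experiments, size=u, replace=False)
        observed_u = 0
        for e in chosen:
            if config.drop_probability > 0 and rng.random() < config.drop_probability:
                continue
            jitter = int(rng.integers(-hw // 2, hw // 2 + 1))
            c = int(np.clip(center + jitter, hw, genome[chrom] - hw - 1))
            per_exp[labels[e]].append(Interval(chrom, c - hw, c + hw, summit=c))
            observed_u += 1
        truth_rows.append({
            "site": si, "chrom": chrom, "center": center,
            "planted_u": u, "observed_u": observed_u, "at_border": at_border,
        })
    return (
        {l: PeakSet(l, ivs) for l, ivs in per_exp.items()},
        pd.DataFrame(truth_rows),
        borders,
    )
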