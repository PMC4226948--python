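"""Planted-truth recovery experiments over the synthetic study conditions.

Each function runs one self-contained experiment end to end — generate
inputs with a seeded generator, run the pipeline stage under study, score
the result against the planted truth — and returns plain numbers. The
analysis drivers, the test suite and the reproduction script all call
these, so every reported quantity comes from one code path.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .borders import local_contrast, delineate_borders
from .intervals import Genome, Interval, PeakSet
from .occupancy import APBS, overlap_fraction
from .resampling import perm_test, shuffle_sites
from .simulate import SynthConfig, gen_cell_line_catalogs, gen_contact_map
from .ubiquity import bin_by_ubiquity, border_localization, build_catalog, ubiquity_merge

__all__ = [
    "worked_example_overlaps",
    "border_strength_recovery",
    "delineation_on_planted_borders",
    "permutation_calibration",
    "ubiquity_recovery",
]


def worked_example_overlaps(
    n_loci: int = 3728,
    counts: dict[str, int] = None,
) -> dict[str, tuple[int, float, int]]:
    """Overlap fractions for the published co-binding counts.

    Builds a landscape of `n_loci` combinatorially bound loci and, per
    factor, a peak set overlapping exactly the published number of them
    (defaults: dTFIIIC220 1,489; CAP-H2 2,124; Rad21 1,830), then measures
    count/fraction/percent with overlap_fraction.
    """
    counts = counts or {"dTFIIIC220": 1489, "CAP-H2": 2124, "Rad21": 1830}
    spacing = 2_000
    genome_len = (n_loci + 1) * spacing
    genome = Genome({"chr1": genome_len})
    loci = [Interval("chr1", i * spacing, i * spacing + 400) for i in range(n_loci)]
    out = {}
    for factor, n_overlap in counts.items():
        peaks = PeakSet(factor, [
            Interval("chr1", i * spacing + 100, i * spacing + 300)
            for i in range(n_overlap)
        ])
        out[factor] = overlap_fraction(loci, peaks)
    return out


def border_strength_recovery(seed: int, window_w: int = 10) -> dict:
    """Recover planted border leakage from a simulated contact map.

    Under the default map (20 interior borders, leakage grid 0.1-0.9,
    Poisson counts), scores every cut site and compares the centred
    contrast at true borders against the planted leakage lambda:
    Spearman rho of (-lambda, L), mean L per lambda tercile, and the
    genome-wide median of L (1 by construction).
    """
    cfg = SynthConfig(seed=seed)
    matrices, fragmap, tads, truth = gen_contact_map(cfg)
    scores = local_contrast(matrices, fragmap, window_w=window_w)
    by_idx = {(s.chrom, s.cut_index): s.centered for s in scores}
    lam = truth["leakage"].to_numpy()
    L = np.array([
        by_idx[(row["chrom"], row["cut_index"])] for _, row in truth.iterrows()
    ])
    rho = float(stats.spearmanr(-lam, L).statistic)
    terciles = np.digitize(lam, np.quantile(lam, [1 / 3, 2 / 3]))
    tercile_means = [float(L[terciles == t].mean()) for t in range(3)]
    return {
        "spearman": rho,
        "tercile_means": tercile_means,  # decreasing in lambda = increasing strength
        "median_centered": float(np.median([s.centered for s in scores])),
        "n_borders": len(truth),
        "n_scored": len(scores),
    }


def delineation_on_planted_borders(seed: int, plant: bool = True) -> dict:
    """Delineation percentages when high-occupancy sites sit exactly at
    (or nowhere near) every TAD border."""
    cfg = SynthConfig(seed=seed)
    matrices, fragmap, tads, truth = gen_contact_map(cfg)
    apbs = []
    if plant:
        for _, row in truth.iterrows():
            bp = int(row["cut_bp"])
            iv = Interval(row["chrom"], max(0, bp - 200), bp + 200)
            apbs.append(APBS(iv, iv, frozenset(f"f{i}" for i in range(8)), 8))
    labels, pct = delineate_borders(tads, apbs, fragmap, "one_cut_site")
    return {"labels": labels, "percentages": pct, "n_borders": len(labels)}


def _total_overlap_bp(sites, merged_starts, merged_ends, cum):
    """Total bp overlap of sites with merged target intervals.

    `cum[i]` is covered bp in targets before merged interval i;
    coverage before a position x interpolates within an interval.
    """
    def covered_before(x):
        i = np.searchsorted(merged_ends, x, side="right")
        c = cum[i]
        if i < len(merged_starts) and merged_starts[i] < x:
            c += x - merged_starts[i]
        return c

    total = 0
    for iv in sites:
        total += covered_before(iv.end) - covered_before(iv.start)
    return total


def permutation_calibration(
    n_replicates: int = 500,
    n_perm: int = 1_000,
    seed: int = 0,
    n_sites: int = 40,
) -> np.ndarray:
    """Empirical P values under a null with no planted association.

    Each replicate draws unrelated query and target interval sets, takes
    total overlap bp as the statistic, and runs a Monte Carlo permutation
    test with chromosome-bounded shuffling. The landscape is dense enough
    that the statistic is effectively continuous (no atom at zero overlap),
    so the returned replicate P values should be uniform.
    """
    genome = Genome({"chr1": 100_000})
    master = np.random.default_rng(seed)
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        rng = np.random.default_rng(master.integers(2**31))
        sites = shuffle_sites(
            [Interval("chr1", 0, int(l)) for l in rng.integers(200, 600, size=n_sites)],
            genome, rng=rng,
        )
        targets = shuffle_sites(
            [Interval("chr1", 0, int(l)) for l in rng.integers(200, 600, size=n_sites)],
            genome, rng=rng,
        )
        starts = np.sort([t.start for t in targets])
        ends = np.array(sorted(t.end for t in targets))
        merged_s, merged_e = [], []
        for s, e in zip(starts, ends):
            if merged_e and s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        merged_s, merged_e = np.array(merged_s), np.array(merged_e)
        cum = np.concatenate([[0], np.cumsum(merged_e - merged_s)])

        observed = _total_overlap_bp(sites, merged_s, merged_e, cum)

        def statistic(g):
            shuffled = shuffle_sites(sites, genome, rng=g)
            return _total_overlap_bp(shuffled, merged_s, merged_e, cum)

        res = perm_test(float(observed), statistic, n=n_perm,
                        seed=int(master.integers(2**31)), keep_null=False)
        pvals[r] = res.p_value
    return pvals


def ubiquity_recovery(
    n_replicates: int = 100,
    seed: int = 0,
    n_shuffles: int = 60,
) -> dict:
    """Fraction of replicates where per-bin border enrichment is strictly
    monotone in ubiquity (Spearman rho = 1 over the 8 bins)."""
    monotone = 0
    ratios_last = None
    for r in range(n_replicates):
        rep_seed = seed + r
        cfg = SynthConfig(seed=rep_seed)
        catalogs, truth, borders = gen_cell_line_catalogs(cfg)
        catalog = ubiquity_merge(build_catalog(catalogs, match_dist=200))
        bins = bin_by_ubiquity(catalog, n_bins=8)
        frame = border_localization(bins, borders, cfg.genome(),
                                    window=cfg.border_window,
                                    n_shuffles=n_shuffles, seed=rep_seed)
        rho = stats.spearmanr(frame["bin"], frame["obs_over_exp"]).statistic
        monotone += rho == 1.0
        ratios_last = frame["obs_over_exp"].to_numpy()
    return {
        "fraction_monotone": monotone / n_replicates,
        "n_replicates": n_replicates,
        "example_ratios": ratios_last,
    }
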