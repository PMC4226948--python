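"""Synthetic-data generators: determinism, validator compliance, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apbskit import (
    SynthConfig,
    collapse_segments, gen_cell_line_catalogs, gen_contact_map,
    gen_factor_peaks, gen_tracks, local_contrast, multi_intersect,
    rank_order_normalize, anchored_profile,
)
from apbskit.intervals import Interval


def small_config(**kw):
    defaults = dict(
        seed=0, n_chromosomes=1, chrom_length=2_000_000, n_loci=60,
        n_domains=6, fragments_per_domain=12,
        n_experiments=6, n_sites=150, n_borders_per_chrom=8,
    )
    defaults.update(kw)
    return SynthConfig(**defaults)


class TestDeterminism:
    def test_peak_generator_is_pure(self):
        cfg = small_config(seed=5)
        p1, t1 = gen_factor_peaks(cfg)
        p2, t2 = gen_factor_peaks(small_config(seed=5))
        pd.testing.assert_frame_equal(t1, t2)
        for f in p1:
            assert [(iv.start, iv.end) for iv in p1[f]] == [(iv.start, iv.end) for iv in p2[f]]

    def test_contact_generator_is_pure(self):
        a = gen_contact_map(small_config(seed=6))
        b = gen_contact_map(small_config(seed=6))
        assert (a[0][0].counts != b[0][0].counts).nnz == 0
        pd.testing.assert_frame_equal(a[3], b[3])

    def test_catalog_generator_is_pure(self):
        a = gen_cell_line_catalogs(small_config(seed=7))
        b = gen_cell_line_catalogs(small_config(seed=7))
        pd.testing.assert_frame_equal(a[1], b[1])
        assert a[2] == b[2]

    def test_different_seeds_differ(self):
        t1 = gen_factor_peaks(small_config(seed=1))[1]
        t2 = gen_factor_peaks(small_config(seed=2))[1]
        assert not t1.equals(t2)


class TestFactorPeaks:
    def test_zero_jitter_no_background_recovers_k_exactly(self):
        cfg = small_config(summit_jitter_sd=0.0, background_rate_per_mb=0.0)
        peaksets, truth = gen_factor_peaks(cfg)
        sites = collapse_segments(multi_intersect(list(peaksets.values())))
        by_center = {s.center: s.k for s in sites}
        assert len(sites) == len(truth)
        for _, row in truth.iterrows():
            assert by_center[row["center"]] == row["k"]

    def test_all_mass_at_k1_yields_no_cobinding(self):
        weights = tuple([1.0] + [0.0] * 10)
        cfg = small_config(occupancy_weights=weights, background_rate_per_mb=0.0)
        peaksets, truth = gen_factor_peaks(cfg)
        segs = multi_intersect(list(peaksets.values()))
        assert max(s.k for s in segs) == 1
        assert (truth["k"] == 1).all()

    def test_default_jitter_recovers_k_at_99_percent(self):
        """Occupancy recovery holds when jitter sd is well below the window
        halfwidth (50 vs 200 bp), pooled over several seeds."""
        import bisect

        total_ok, total = 0, 0
        for seed in range(3):
            cfg = SynthConfig(seed=seed)
            peaksets, truth = gen_factor_peaks(cfg)
            sites = collapse_segments(multi_intersect(list(peaksets.values())))
            per_chrom = {}
            for s in sites:
                per_chrom.setdefault(s.interval.chrom, []).append((s.center, s.k))
            for c in per_chrom:
                per_chrom[c].sort()
            for _, row in truth.iterrows():
                arr = per_chrom[row["chrom"]]
                centers = [x[0] for x in arr]
                i = bisect.bisect(centers, row["center"])
                cand = [j for j in (i - 1, i) if 0 <= j < len(arr)]
                j = min(cand, key=lambda j: abs(centers[j] - row["center"]))
                total_ok += (
                    abs(centers[j] - row["center"]) < 300 and arr[j][1] == row["k"]
                )
                total += 1
        assert total_ok / total >= 0.99

    def test_overcrowded_config_rejected(self):
        with pytest.raises(ValueError, match="density"):
            gen_factor_peaks(small_config(n_loci=2000, chrom_length=100_000))


class TestContactMap:
    def test_no_leakage_means_no_border_structure(self):
        cfg = small_config(leakage_grid=(1.0,), n_domains=10, fragments_per_domain=20)
        matrices, fragmap, tads, truth = gen_contact_map(cfg)
        scores = local_contrast(matrices, fragmap, window_w=10)
        by_idx = {s.cut_index: s.centered for s in scores}
        at_borders = [by_idx[i] for i in truth["cut_index"] if i in by_idx]
        assert np.mean(at_borders) == pytest.approx(1.0, abs=0.1)

    def test_tight_border_dominates_all_other_sites(self):
        cfg = small_config(
            leakage_grid=(0.01,), n_domains=2, fragments_per_domain=25,
            contact_amplitude=200.0,
        )
        matrices, fragmap, tads, truth = gen_contact_map(cfg)
        scores = local_contrast(matrices, fragmap, window_w=10)
        border_idx = int(truth["cut_index"].iloc[0])
        border_L = next(s.centered for s in scores if s.cut_index == border_idx)
        assert border_L == max(s.centered for s in scores)

    def test_emitted_objects_are_mutually_consistent(self):
        matrices, fragmap, tads, truth = gen_contact_map(small_config())
        cm = matrices[0]
        assert cm.n_fragments == fragmap.n_fragments(cm.chrom)
        assert tads.domains[0].start == int(fragmap.cuts[cm.chrom][0])
        assert tads.domains[-1].end == int(fragmap.cuts[cm.chrom][-1])
        assert len(tads.borders()) == len(truth)

    def test_invalid_decay_rejected(self):
        with pytest.raises(ValueError):
            gen_contact_map(small_config(decay_exponent=0.0))

    def test_negative_binomial_noise_available(self):
        a = gen_contact_map(small_config(count_noise="nbinom"))
        assert a[0][0].counts.sum() > 0


class TestTracks:
    def test_identity_distortion_zero_noise_gives_identical_samples(self):
        cfg = small_config(track_noise_sd=0.0)
        _, truth = gen_factor_peaks(cfg)
        tracks, latent = gen_tracks(cfg, loci_truth=truth,
                                    distortions=[lambda v: v, lambda v: v])
        np.testing.assert_array_equal(tracks[0].values["chr1"], tracks[1].values["chr1"])
        out = rank_order_normalize(tracks)
        np.testing.assert_allclose(out[0].values["chr1"], tracks[0].values["chr1"])

    def test_monotone_distortions_normalize_back_together(self):
        cfg = small_config(track_noise_sd=0.0)
        tracks, _ = gen_tracks(cfg)
        out = rank_order_normalize(tracks)
        for t in out[1:]:
            np.testing.assert_allclose(
                t.values["chr1"], out[0].values["chr1"], rtol=1e-9
            )

    def test_signal_concentrates_at_high_occupancy_loci(self):
        cfg = small_config(track_noise_sd=0.0)
        _, truth = gen_factor_peaks(cfg)
        tracks, _ = gen_tracks(cfg, loci_truth=truth)
        track = tracks[0]
        hi = truth[truth["k"] >= 7]
        lo = truth[truth["k"] <= 2]
        assert not hi.empty and not lo.empty
        def mean_at(rows):
            anchors = [Interval(r["chrom"], r["center"] - 50, r["center"] + 50)
                       for _, r in rows.iterrows()]
            pm = anchored_profile(track, anchors, flank=500, width=cfg.track_bin_width)
            return np.nanmean(pm.matrix)
        assert mean_at(hi) > mean_at(lo)


class TestCellLineCatalogs:
    def test_zero_dropout_constitutive_sites_have_full_u(self):
        cfg = small_config(drop_probability=0.0, constitutive_fraction=0.2)
        catalogs, truth, _ = gen_cell_line_catalogs(cfg)
        const = truth[truth["planted_u"] == cfg.n_experiments]
        assert (const["observed_u"] == cfg.n_experiments).all()

    def test_flat_profile_gives_flat_localization(self):
        from apbskit import bin_by_ubiquity, border_localization, build_catalog

        cfg = small_config(
            seed=11, n_sites=600, n_experiments=8,
            border_prob_range=(0.0, 0.0), constitutive_fraction=0.0,
            chrom_length=8_000_000,
        )
        catalogs, truth, borders = gen_cell_line_catalogs(cfg)
        assert not truth["at_border"].any()
        cat = build_catalog(catalogs, match_dist=200)
        bins = bin_by_ubiquity(cat, n_bins=4)
        frame = border_localization(bins, borders, cfg.genome(),
                                    n_shuffles=40, seed=11)
        # no planted coupling: every bin's ratio is consistent with 1
        assert (frame["p_value"] > 0.01).all()

    def test_dropout_reduces_observed_u(self):
        cfg = small_config(drop_probability=0.4)
        _, truth, _ = gen_cell_line_catalogs(cfg)
        assert (truth["observed_u"] <= truth["planted_u"]).all()
        assert (truth["observed_u"] < truth["planted_u"]).any()
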