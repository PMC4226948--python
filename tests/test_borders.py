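"""Border-strength statistic, delineation, and TAD-size summaries."""

import itertools

import numpy as np
import pytest
from scipy import stats

from apbskit import (
    ContactMatrix, FragmentMap, Interval, TADSet,
    delineate_borders, local_contrast, strength_by_occupancy, tad_size_by_apbs,
)
from apbskit.borders import read_contacts_tsv, write_contacts_tsv
from apbskit.occupancy import APBS


def make_apbs(chrom, start, end, k):
    iv = Interval(chrom, start, end)
    return APBS(iv, iv, frozenset(f"f{i}" for i in range(k)), k)


def uniform_fragmap(F, frag_len=100, chrom="chr1"):
    return FragmentMap({chrom: np.arange(F + 1) * frag_len})


def brute_force_contrast(full, w, pseudocount):
    """Independent oracle: exhaustive pair enumeration per cut site."""
    F = full.shape[0]
    raws = []
    for s in range(w, F - w + 1):
        A = range(s - w, s)
        B = range(s, s + w)
        intra = sum(full[i, j] for side in (A, B)
                    for i, j in itertools.combinations(side, 2))
        inter = sum(full[i, j] for i in A for j in B)
        n_intra = w * (w - 1)
        n_inter = w * w
        raws.append((intra / n_intra) / ((inter + pseudocount) / n_inter))
    raws = np.array(raws)
    return raws, raws / np.median(raws)


def matrix_from_dense(full, chrom="chr1"):
    F = full.shape[0]
    i, j = np.triu_indices(F, k=1)
    nz = full[i, j] > 0
    return ContactMatrix.from_triplets(chrom, i[nz], j[nz], full[i, j][nz], F)


class TestLocalContrast:
    def test_uniform_matrix_scores_one_everywhere(self):
        F = 30
        full = np.full((F, F), 5.0)
        np.fill_diagonal(full, 0)
        scores = local_contrast(matrix_from_dense(full), uniform_fragmap(F), window_w=5)
        assert all(s.centered == pytest.approx(1.0) for s in scores)

    def test_two_block_toy_matches_pair_enumeration(self):
        """Two 3-fragment blocks, intra-pair count 8 and inter-pair count 2."""
        F, w = 6, 3
        full = np.zeros((F, F))
        for i, j in itertools.combinations(range(3), 2):
            full[i, j] = full[j, i] = 8
        for i, j in itertools.combinations(range(3, 6), 2):
            full[i, j] = full[j, i] = 8
        for i in range(3):
            for j in range(3, 6):
                full[i, j] = full[j, i] = 2
        scores = local_contrast(matrix_from_dense(full), uniform_fragmap(F),
                                window_w=w, pseudocount=1.0)
        assert len(scores) == 1  # only the block boundary is scorable
        # oracle: intra mean 8, inter (2*9 + 1)/9
        expected_raw = 8.0 / ((2 * 9 + 1) / 9)
        assert scores[0].raw == pytest.approx(expected_raw)
        assert scores[0].cut_index == 3

    def test_lower_inter_counts_raise_border_score(self):
        F, w = 20, 5
        base = np.full((F, F), 6.0)
        np.fill_diagonal(base, 0)
        scores = {}
        for inter_val in (4.0, 2.0, 1.0):
            full = base.copy()
            full[:10, 10:] = inter_val
            full[10:, :10] = inter_val
            ss = local_contrast(matrix_from_dense(full), uniform_fragmap(F), window_w=w)
            scores[inter_val] = next(s.raw for s in ss if s.cut_index == 10)
        assert scores[1.0] > scores[2.0] > scores[4.0]

    @pytest.mark.parametrize("seed", [0, 1])
    @pytest.mark.parametrize("w", [2, 4, 7])
    def test_matches_dense_oracle_on_random_matrices(self, seed, w):
        rng = np.random.default_rng(seed)
        F = 30
        full = rng.poisson(3.0, size=(F, F)).astype(float)
        full = np.triu(full, 1)
        full = full + full.T
        scores = local_contrast(matrix_from_dense(full), uniform_fragmap(F), window_w=w)
        raw_oracle, centered_oracle = brute_force_contrast(full, w, 1.0)
        np.testing.assert_allclose([s.raw for s in scores], raw_oracle, rtol=1e-12)
        np.testing.assert_allclose([s.centered for s in scores], centered_oracle, rtol=1e-12)

    def test_median_is_exactly_one(self):
        rng = np.random.default_rng(3)
        F = 41
        full = rng.poisson(2.0, size=(F, F)).astype(float)
        full = np.triu(full, 1) + np.triu(full, 1).T
        scores = local_contrast(matrix_from_dense(full), uniform_fragmap(F), window_w=4)
        assert np.median([s.centered for s in scores]) == 1.0

    def test_scale_invariant_without_pseudocount(self):
        rng = np.random.default_rng(5)
        F = 25
        full = rng.poisson(4.0, size=(F, F)).astype(float) + 1
        full = np.triu(full, 1) + np.triu(full, 1).T
        a = local_contrast(matrix_from_dense(full), uniform_fragmap(F),
                           window_w=4, pseudocount=0.0)
        b = local_contrast(matrix_from_dense(full * 7), uniform_fragmap(F),
                           window_w=4, pseudocount=0.0)
        np.testing.assert_allclose([s.raw for s in b], [s.raw for s in a], rtol=1e-12)
        np.testing.assert_allclose([s.centered for s in b], [s.centered for s in a], rtol=1e-12)

    def test_all_zero_matrix_rejected(self):
        F = 12
        cm = ContactMatrix.from_triplets("chr1", [0], [1], [0.0], F)
        with pytest.raises(ValueError, match="degenerate"):
            local_contrast(cm, uniform_fragmap(F), window_w=3)

    def test_small_window_rejected(self):
        F = 12
        cm = ContactMatrix.from_triplets("chr1", [0], [1], [1.0], F)
        with pytest.raises(ValueError):
            local_contrast(cm, uniform_fragmap(F), window_w=1)


class TestDelineation:
    def _setup(self):
        fragmap = uniform_fragmap(30, frag_len=1000)  # chr1: 0..30kb
        tads = TADSet([
            Interval("chr1", 0, 10_000),
            Interval("chr1", 10_000, 20_000),
            Interval("chr1", 20_000, 30_000),
        ])
        return fragmap, tads  # borders at 10 kb and 20 kb

    def test_high_apbs_in_adjacent_fragment_labels_high(self):
        fragmap, tads = self._setup()
        apbs = [make_apbs("chr1", 9_200, 9_600, 8)]
        labels, pct = delineate_borders(tads, apbs, fragmap, "one_cut_site")
        assert labels[0] == "high" and labels[1] == "none"
        assert pct["high"] == 50.0 and pct["none"] == 50.0

    def test_no_apbs_yields_none_labels(self):
        fragmap, tads = self._setup()
        labels, pct = delineate_borders(tads, [], fragmap, "one_cut_site")
        assert labels == ["none", "none"] and pct["none"] == 100.0

    def test_best_class_wins(self):
        fragmap, tads = self._setup()
        apbs = [make_apbs("chr1", 9_200, 9_600, 2), make_apbs("chr1", 10_100, 10_500, 5)]
        labels, _ = delineate_borders(tads, apbs, fragmap, "one_cut_site")
        assert labels[0] == "medium"

    def test_bp_window_mode(self):
        _, tads = self._setup()
        apbs = [make_apbs("chr1", 11_500, 11_900, 7)]
        labels, _ = delineate_borders(tads, apbs, None, 2_000)
        assert labels[0] == "high"
        labels, _ = delineate_borders(tads, apbs, None, 1_000)
        assert labels[0] == "none"

    def test_percentages_sum_to_100(self):
        fragmap, tads = self._setup()
        apbs = [make_apbs("chr1", 9_200, 9_600, 8), make_apbs("chr1", 19_500, 19_900, 2)]
        _, pct = delineate_borders(tads, apbs, fragmap, "one_cut_site")
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.5)


class TestStrengthByOccupancy:
    def _scores(self, values, frag_len=1000):
        from apbskit.borders import BorderScore

        return [
            BorderScore("chr1", i + 1, (i + 1) * frag_len, v, v / np.median(values))
            for i, v in enumerate(values)
        ]

    def test_constant_scores_give_unit_means(self):
        scores = self._scores([1.0] * 10)
        apbs = [make_apbs("chr1", 1000 * i + 900, 1000 * i + 1100, k)
                for i, k in enumerate([2, 5, 8], start=1)]
        table = strength_by_occupancy(apbs, scores, max_dist=5000)
        assert (table["mean_strength"] == 1.0).all()
        assert set(table["k"]) == {2, 5, 8}

    def test_distant_apbs_excluded_and_counted(self):
        scores = self._scores([1.0, 2.0, 1.0])
        apbs = [make_apbs("chr1", 900, 1100, 3), make_apbs("chr1", 900_000, 900_200, 5)]
        table = strength_by_occupancy(apbs, scores, max_dist=5000)
        assert table.attrs["excluded"] == 1
        assert set(table["k"]) == {3}


class TestTadSize:
    def test_equal_sizes_give_equal_medians_and_zero_correlation(self):
        tads = TADSet([Interval("chr1", i * 10_000, (i + 1) * 10_000) for i in range(6)])
        apbs = [make_apbs("chr1", 10_000 * i + 100, 10_000 * i + 500, 3) for i in range(3)]
        out = tad_size_by_apbs(tads, apbs)
        assert len(set(out["median_size_by_stratum"].values())) == 1
        assert out["spearman_rho"] == 0.0

    def test_dense_high_k_regions_have_smaller_tads(self):
        # small TADs packed with border APBSs, large TADs bare
        domains, apbs = [], []
        pos = 0
        for _ in range(8):
            domains.append(Interval("chr1", pos, pos + 20_000))
            apbs.append(make_apbs("chr1", pos + 100, pos + 500, 8))
            apbs.append(make_apbs("chr1", pos + 19_000, pos + 19_400, 8))
            pos += 20_000
        for _ in range(8):
            domains.append(Interval("chr1", pos, pos + 150_000))
            pos += 150_000
        out = tad_size_by_apbs(TADSet(domains), apbs, density_radius=10_000)
        med = out["median_size_by_stratum"]
        assert med[max(med)] < med[min(med)]
        assert out["spearman_rho"] < 0


class TestContactIO:
    def test_triplet_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        F = 15
        full = rng.poisson(2.0, size=(F, F)).astype(float)
        full = np.triu(full, 1)
        cm = matrix_from_dense(full + full.T)
        path = tmp_path / "contacts.tsv"
        write_contacts_tsv([cm], path)
        fragmap = uniform_fragmap(F)
        (back,) = read_contacts_tsv(path, fragmap)
        assert (back.counts != cm.counts).nnz == 0

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            ContactMatrix.from_triplets("chr1", [0], [10], [1.0], 5)
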