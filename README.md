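# apbskit

Quantitative machinery linking architectural-protein co-occupancy to the
strength of topologically associating domain (TAD) borders.

Insulator-associated ("architectural") proteins — CTCF, BEAF-32, Su(Hw),
CP190, Mod(mdg4), DREF, Chromator, L(3)mbt, TFIIIC, and the SMC complexes
cohesin (Rad21) and condensin II (CAP-H2) — bind chromatin alone or in
clusters. The number of distinct factors bound at a locus (its *occupancy*
k) stratifies binding sites into low (1–3), medium (4–6) and high (≥7)
occupancy classes, and high-occupancy sites preferentially sit at TAD
borders and mark strong chromatin-domain separation. This package
implements the full analysis chain behind that observation, exercised
end-to-end on seeded synthetic data with planted ground truth:

- **Occupancy segmentation** (`apbskit.intervals`, `apbskit.occupancy`) —
  400 bp summit windows per factor are segmented into maximal runs of
  constant factor membership; directly adjacent runs collapse into
  architectural protein binding sites (APBSs) centred on the
  highest-occupancy segment (a 4-, 5-, 4-factor run becomes one site with
  k = 5), then classified low/medium/high.
- **Border strength** (`apbskit.borders`) — at each restriction cut site S
  with w flanking fragments per side, the local contrast
  `L_raw = mean(intra-window contacts per pair) / mean(cross-window contacts per pair)`
  is computed from a fragment-level Hi-C map and centred so the genome-wide
  median of L is exactly 1. Strong TAD borders have high L.
- **Rank-order normalization and metaprofiles** (`apbskit.tracks`) — binned
  coverage samples are re-assigned the cross-sample mean value at each
  descending rank, preserving each sample's spatial rank structure;
  anchored tag-density profiles are reported in RPM (reads per million).
- **Permutation enrichment** (`apbskit.resampling`) — chromosome- or
  span-bounded shuffling nulls preserving per-chromosome counts and
  lengths; one-sided Monte Carlo P values with the r = 0 case reported as
  the bound "P < 1/n" (e.g. "P < 0.00001" at 100,000 permutations);
  log2(observed/expected) enrichment.
- **Site ubiquity** (`apbskit.ubiquity`) — multi-experiment site catalogs
  scored by ubiquity u (number of supporting experiments), singletons
  discarded, sites < 1 kb from a neighbour with over twice their u merged
  into it, the catalog split into eight ubiquity bins, and each bin's TAD
  border localization scored against a shuffle null.
- **Synthetic data** (`apbskit.simulate`) — seeded generators for every
  input class with planted truth: clustered co-binding landscapes, Hi-C
  maps `E_ij = A (d+1)^(−α) · Πλ_b` with per-border leakage λ and Poisson
  counts, monotone-distorted coverage samples, and cell-line catalogs with
  a planted specific→constitutive border-placement gradient.

## Worked example

The published co-binding summary — of 3,728 combinatorially bound loci,
1,489, 2,124 and 1,830 overlap dTFIIIC220, CAP-H2 and Rad21 — runs through
the overlap statistic directly:

```sh
$ python analysis/02_occupancy_landscape.py --seed 1
660 APBSs from 300 planted loci (background peaks account for the excess):
 class   n
   low 538
medium  71
  high  51
planted occupancy recovered exactly at 299/300 loci (99.7%)

published co-binding worked example reproduced:
    factor  overlapping  of_loci  percent
dTFIIIC220         1489     3728       40
    CAP-H2         2124     3728       57
     Rad21         1830     3728       49
```

The percentages are `round(count / 3728 × 100)`: the three factors bind
40%, 57% and 49% of combinatorially bound sites. The synthetic landscape
above also shows the segmentation pipeline recovering the planted
occupancy k at 99.7% of loci despite 50 bp summit jitter.

Border-strength recovery on the simulated Hi-C map (20 interior borders
with leakage λ ∈ {0.1…0.9}):

```sh
$ python analysis/03_border_strength.py --seed 1
...
 window_fragments  spearman_neg_lambda_vs_L  mean_L_low_leakage  mean_L_mid_leakage  mean_L_high_leakage
                5                     0.985               7.459               2.583                1.344
               10                     0.994               7.358               2.577                1.361
               20                     0.994               6.769               2.421                1.269
```

Leakier borders (higher λ) have weaker centred contrast, and the ranking
of estimated border strengths matches the planted leakage (Spearman ≥
0.98) across analysis windows. `analysis/05_site_ubiquity.py` shows the
matching ubiquity result: eight bins from cell-type-specific to
constitutive with obs/exp border enrichment rising strictly from 0.77 to
6.5.

A `apbskit` console command exposes the same stages
(`simulate`, `classify`, `border-strength`, `delineate`, `normalize`,
`profile`, `enrich`, `ubiquity`, `run`) for file-based workflows; see
`apbskit --help`.

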