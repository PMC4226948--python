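# Methods

## Scope and data model

The package analyses the relationship between multi-factor
architectural-protein binding and chromatin-domain structure. All
coordinates are 0-based half-open (BED convention); 1-based coordinates
appear only in display output. Peaks are consumed, not called: the unit of
input is a per-factor BED of intervals with optional MACS-style summit
offsets. Where a summit is absent the interval midpoint (floor) is used.

## Occupancy segmentation and APBS classification

Each factor's peaks are reduced to fixed windows of ±200 bp around the
summit (`summit_windows`, halfwidth configurable), clipped — not dropped —
at chromosome ends. `multi_intersect` segments the union of all windows
into maximal runs of constant factor membership. Membership is boolean per
factor: overlapping windows of the same factor count once, because
occupancy is defined as the number of distinct proteins bound, not the
number of peaks. This is a deliberate resolution of an under-specified
step; the alternative (pre-merging within factors) is equivalent under
this membership rule.

`collapse_segments` merges runs of directly adjacent segments (sharing a
boundary base; any gap ≥ 1 bp separates sites) into APBSs. The collapsed
site spans the union of the run but inherits its factor set and occupancy
k from the highest-k segment, with ties broken leftmost; a 4-, 5-,
4-factor run therefore becomes one site with k = 5 centred on the
five-factor segment. Classes are low (1 ≤ k ≤ 3), medium (4 ≤ k ≤ 6) and
high (k ≥ 7); the thresholds partition ℕ≥1 with no gaps.

Two occupancy summaries are provided for anchor-style analyses.
`anchor_occupancy` counts, per anchor, the distinct partner *groups* with
a peak whose nearest edge lies within 500 bp (default) of the anchor
centre; factors mapped to the same group (e.g. multiple TFIIIC or
condensin subunits) count once. `region_occupancy_summary` scores a
labelled region by the maximum k among overlapping APBSs (0 when none
overlap) and reports group means to one decimal. Using the maximum (rather
than a direct per-region factor count) is a documented choice; both
quantities are computable from the catalog.

## Border strength (local contrast)

Given a fragment map (restriction cut sites) and a symmetric fragment-level
contact matrix, every interior cut site S with at least w fragments on each
side is scored. With A the w fragments left of S and B the w fragments
right:

    intra = Σ c_ij over unordered pairs within A plus within B  (diagonal excluded)
    inter = Σ c_ij over i ∈ A, j ∈ B
    L_raw = (intra / w(w−1)) / ((inter + ε) / w²)

The per-pair means remove the combinatorial imbalance between the w(w−1)
intra pairs and w² inter pairs. The comparison is implemented as a ratio —
the quantity described as the ratio of intra- versus inter-domain
interaction frequencies — and centred multiplicatively: centred scores
L = L_raw / median(L_raw) over all scored sites, polished so the
genome-wide median is exactly 1 (a second division pass absorbs the one-ULP
rounding that an even number of sites can introduce). The pseudocount
ε = 1 guards empty inter windows in sparse matrices and is configurable;
with ε = 0 the statistic is exactly invariant to global scaling of the
matrix. The window defaults to w = 10 fragments and recovery holds across
w = 5–20 (see below); windows are fixed fragment counts, not bounded by TAD
extents.

A cut site needs only w fragments per side, so chromosomes with F ≥ 2w are
scorable; shorter chromosomes are skipped with a log notice, and an
all-zero matrix is rejected as degenerate rather than silently centred.

`delineate_borders` labels each TAD border (midpoint between consecutive
domains) by the best occupancy class among APBSs within a window: mode
`one_cut_site` spans the two fragments flanking the nearest cut site —
"within one restriction cut site" — and an integer mode spans border ± bp.
Borders with no APBS are labelled `none`; class percentages sum to 100.
`strength_by_occupancy` assigns each APBS the nearest scored cut site
within `max_dist` (unassignable sites are dropped and counted) and
tabulates mean centred contrast per k and per class. `tad_size_by_apbs`
relates TAD size to the APBS count within 10 kb of its borders (density
strata are quantiles, Spearman rank correlation reported).

## Coverage tracks

`bin_coverage` assigns each read to one bin by its 5′ start (midpoint
optional), conserving totals exactly; `bin_bedgraph` apportions interval
values by overlap length, conserving base-level mass to float precision.

Rank-order normalization operates genome-wide over all bins, zeros
included. All samples' values are sorted; the reference distribution is
the across-sample mean at each rank; each sample's bins are re-assigned
the reference value at their own rank. Within a sample, tied values share
the mean of the reference values their rank span covers — the stable
average-tie rule — so the map is well defined and order-preserving, and
the operation is idempotent. Strict equality of sorted value vectors
across samples holds whenever tie structures agree (notably for
tie-free data and for monotone distortions of one latent track); samples
with different tie structures agree up to tie handling, which is the
precision the procedure can promise.

`anchored_profile` extracts per-anchor rows over centre ± flank in RPM
(value × 10⁶ / library total; the total is caller-supplied metadata).
Anchors running off a chromosome are NaN-padded and excluded from column
means rather than zero-filled, which would bias edge columns downward.
Strand is ignored: anchors are summits/APBS centres, unstranded.

## Shuffling nulls and permutation tests

`shuffle_sites` preserves, per chromosome, the site count and length
multiset, drawing new starts uniformly in [0, chrom_len − len]
(`chrom_bounded`) or in the span actually occupied by the input sites
(`span_bounded`, which also carries auxiliary attributes such as ubiquity).
Shuffled sites may overlap each other: placements are independent, since a
non-overlap constraint would bias dense chromosomes. Inter-site spacing is
not preserved.

`perm_test` draws n null statistics (default 100,000) from a
caller-supplied callable and reports the one-sided empirical
P = #{null ≥ observed}/n. Zero exceedances are never reported as P = 0:
the result carries the bound 1/n with a flag and displays in decimal form
("P < 0.00001" at n = 100,000). `label_perm_test` permutes site labels
with positions fixed; "as extreme as" is one-sided ≥ by default, with a
two-sided option doubling the smaller tail. Enrichment is
log2(observed / null mean), flagged undefined when the null mean is 0.
Every randomized operation takes an explicit seed; identical seeds give
bit-identical results.

## Site ubiquity

`build_catalog` clusters sites across experiments by single-linkage
chaining on centre distance (≤ 200 bp by default — the cross-experiment
matching radius is a free parameter of this implementation, exposed and
documented). A composite's ubiquity u is the number of distinct supporting
experiments; u = 1 composites are discarded as failed replications.
`ubiquity_merge` absorbs any site whose centre lies strictly within
1,000 bp of a site with strictly more than twice its u, iterating to a
fixed point in descending-u order (ties leftmost) so cascades are
deterministic; the dominant site keeps its coordinates and u.
`bin_by_ubiquity` sorts by u and cuts at u-level boundaries nearest the
ideal quantiles — a u level is never split, so bins are only approximately
equal in count. `border_localization` scores each bin's fraction of sites
within 20 kb (inclusive at exactly 20 kb) of a TAD border against a
span-bounded shuffle null (ubiquity preserved), reporting obs, exp,
obs/exp and an empirical P. The null is drawn by a vectorized placement
identical in distribution to `shuffle_sites`.

## Synthetic study conditions

The generators in `apbskit.simulate` are pure functions of
(configuration, seed) and default to the conditions used throughout the
tests and the reproduction script:

- **Peak landscapes**: 300 loci on 2 × 16 Mb chromosomes with ≥ 3 kb
  spacing; occupancy k drawn from a distribution skewed toward low k over
  1–11 factors; summits jittered by a truncated Gaussian (sd 50 bp, well
  inside the 200 bp window halfwidth); 1 background peak/Mb/factor. Under
  these conditions the pipeline recovers planted k at ≥ 99% of loci; the
  background rate is the dominant failure mode (cross-factor collisions),
  which is why it is kept low relative to the planted landscape.
- **Contact maps**: 21 equal domains of 40 fragments (fragment lengths
  exponential, mean 2 kb, floor 500 bp); expected counts
  E_ij = A (d_ij + 1)^(−α) · Π λ_b with A = 100, α = 1, and the 20
  interior borders cycling λ over {0.1, …, 0.9}; Poisson counts (negative
  binomial exposed for overdispersion studies). Leakage is multiplicative
  per crossed border, so crossing two borders attenuates more than one.
- **Tracks**: a latent background-plus-Gaussian-bump signal with bump
  amplitude proportional to planted k, passed through per-sample monotone
  distortions (power-law exponents 0.8–1.2, scales 0.5–2): samples differ
  in value scale but share rank structure by construction.
- **Cell-line catalogs**: 4,000 sites across 20 experiments; ubiquity
  uniform over 2–20 plus a 5% constitutive clump at u = 20;
  border-placement probability linear in u over (0.02, 0.9) toward 100
  planted borders; planted sites kept ≥ 1.1 kb apart so cross-experiment
  clustering recovers them one-to-one and the 1 kb merge rule cannot
  rewire the planted axis. The scale gives ~500 sites per ubiquity bin —
  a desk-scale analog of the published design of roughly 15,000 sites per
  bin — which is what makes strict per-bin monotonicity statistically
  resolvable.

What the generators do *not* emulate: mappability and GC bias, read-level
noise (no FASTQ), distance-dependent Hi-C artefacts beyond the power-law
decay, matrix balancing, inter-chromosomal contacts, and correlated
binding between factors beyond shared locus membership. Passing tests
therefore demonstrate correctness of the statistics and the recovery of
planted structure under idealized noise, not robustness to every artefact
of real ChIP-seq or Hi-C data.

## Problem sizes and numerical choices

The test suite and reproduction script run at desk scale: 200 random toy
landscapes for the segmentation oracle; one contact map (840 fragments,
~820 scored cut sites) per recovery run, repeated at windows 5, 10 and 20;
500 calibration replicates at 1,000 permutations over a dense 100 kb null
landscape (dense enough that total overlap bp has no atom at zero, so
empirical P values are continuous and uniform under the null); 100
catalog replicates for the ubiquity recovery with 60-shuffle nulls. These
sizes were chosen as the smallest at which the planted effects are
statistically resolvable with comfortable margin.

Tie-breaks and degenerate inputs are handled explicitly: highest-k ties in
collapse go leftmost; u-ties in merging go leftmost; bins never split a u
level; zero-length windows, empty locus lists, single-class label tests,
all-zero contact matrices, and off-chromosome coordinates raise errors
rather than propagating silently.

## Known limitations

- The border-strength window is a fixed fragment count; a TAD-bounded
  window mode is not claimed to reproduce any published variant.
- `overlap_fraction` counts ≥ 1 bp intersection; no minimum-overlap
  fraction is implemented.
- The cross-experiment match radius (200 bp) and the treatment of the
  dominant-neighbour merge as a fixed-point iteration are implementation
  choices where the original procedure is under-specified.
- No multiple-testing correction is applied to permutation P values;
  results are emitted raw.

One estimator detail in `border_localization`: under the span-bounded null
a site's at-border probability depends only on its chromosome, so the
reported per-bin expected pools null hits across the whole catalog per
chromosome and re-weights by the bin's chromosome composition. This
estimates the same expectation as the bin's own null fractions with far
less Monte Carlo noise; the per-bin empirical P still compares the
observed fraction against the bin's own null draws.
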