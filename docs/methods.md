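# Methods

## Model and assumptions

loopscout frames loop detection in a binned intrachromosomal contact map
as binary classification of pixels. The working assumptions are:

* a loop appears as a local, roughly point-like enrichment spanning one to
  a few bins, superimposed on a background that decays with genomic
  distance;
* an orthogonal interaction list (ChIA-PET/HiChIP/Capture Hi-C BEDPE)
  marks a subset of true loops well enough to serve as positive labels,
  after removing interactions the Hi-C map does not support;
* the local window around a pixel carries enough information to separate
  loops from background — no genome-wide background model is fitted.

Only cis (intrachromosomal) contacts are considered. Counts are used raw
by default; balancing weights from a cooler file can be applied on request
(`use_balanced`), and the choice is recorded in the model metadata so
training and scoring cannot silently mix conventions. Raw counts are the
default because binomial depth thinning is defined on integers and the
classifier's rank/ratio features make balancing largely immaterial.

## Featurization

For window radius `n` (default 5) the feature vector of pixel `(i, j)` is
`[values | ranks | P2LL]`, length `2(2n+1)² + 1` (243 at `n = 5`):

* **values** — the `(2n+1)²` window counts in row-major order, rows
  indexing the first (smaller-coordinate) anchor;
* **ranks** — average ranks of each count within the window (ties
  averaged), divided by `(2n+1)²`. Scaled average ranks were chosen
  because they are bounded in (0, 1] and invariant under any strictly
  monotone transform of the counts, which is what makes models usable
  across sequencing depths. Under a full tie (e.g., an all-zero window)
  every rank is `(N+1)/2N`, marginally above 0.5;
* **P2LL** — centre count over the mean of the lower-left quadrant, the
  `n×n` block at rows `i+1..i+n`, columns `j−n..j−1`: the region between
  the anchors, elevated for genuine dots relative to loop-free windows.
  A zero quadrant mean (common in sparse maps) is replaced by 1, so the
  ratio degrades to the centre count — a finite, monotone sentinel.

The quadrant orientation follows the stated row convention; it is the
region between the two anchors, closer to the diagonal, which is the
convention used when contact maps are drawn with the diagonal running
lower-left to upper-right.

## Training set

Positives: each BEDPE row is mapped to a bin pair via anchor-interval
midpoints (edge ties round down), deduplicated, and kept only if the
window is in bounds, the centre count is nonzero, and P2LL ≥ `min_p2ll`
(default 0.1, i.e., the interaction is rejected if its Hi-C value is under
10% of the mean between its anchors).

Negatives (default count: equal to the positives): a mixture of

* distance-matched contacts — draw a positive's distance, then a random
  unused nonzero pixel at that distance (±1 bin when exhausted), and
* long-range noise — uniform draws among nonzero pixels farther than the
  longest positive,

mixed at `long_range_frac` (default 0.5; the split between the two
populations is a free parameter of the design). Sampling is without
replacement, never returns a positive pixel, and is seeded. If candidates
run out, fewer negatives are returned with a warning.

## Classifier

One forest of exactly 100 CART trees per hold-out chromosome. Each tree is
fitted on a bootstrap resample (redrawn, up to 100 attempts, if a resample
loses a class) and considers `k` randomly chosen features at every split,
with `k` drawn once per tree uniformly from 15–20 (≈ √243). An alternative
reading — restricting each whole tree to a fixed 15–20-feature subspace —
was implemented and rejected: with only a handful of informative features
per window, most subspace trees never see one, the ensemble's vote
fractions plateau far below the P > 0.9 candidate regime, and the caller
goes silent. Per-split subsampling is also how standard random-forest
implementations behave.

Hyperparameters are selected by seeded, label-stratified 3-fold
cross-validation over split criterion {gini, entropy}, maximum depth
{10, 15, 20, unlimited}, and class weights {none, balanced}, scored by
mean Matthews correlation coefficient; ties keep the first grid point in
that declared order, and the winner is refitted on the full table. MCC is
computed from the confusion matrix with the usual zero-marginal → 0
convention.

Hold-out scheme: the forest scoring chromosome `c` is trained on labeled
pixels from every chromosome except `c` (asserted structurally and
recorded in the bundle metadata), so called loops were never seen in
training. Bundles serialize via joblib with a JSON sidecar (resolution,
window radius, feature order, thresholds, training depth, seed); loading
against a mismatched resolution or radius is refused.

## Calling

Scoring covers nonzero pixels with in-bounds windows and genomic distance
in [`min_dist`, `max_dist`] = [30 kb, 3 Mb] by default; the span is an
engineering default, exposed as flags. Pooling then proceeds in two
steps:

1. **anchor regions** — per-bin profile counting candidate pixels
   (P > 0.9) with either anchor in the bin; summits from
   `scipy.signal.find_peaks` with prominence ≥ 1 (the profile is
   zero-padded so boundary summits are detected), widths at
   half-prominence via `peak_widths`, overlapping regions merged;
2. **clustering** — candidates linking each ordered anchor-region pair
   are clustered with DBSCAN (Chebyshev metric, `eps = 2` bins,
   `min_samples = 2`, matching the ±2-bin anchor tolerance used for loop
   comparisons throughout the field); DBSCAN noise points survive as
   singleton clusters. Candidates falling in no anchor region are
   clustered by the same rule (a flag can drop them instead). Each
   cluster emits its maximum-probability pixel, ties broken to the
   lexicographically smallest `(i, j)`; calls below `call_threshold`
   (default 0.9; tighten post hoc to taste — the published practice uses
   0.92–0.97 on deep maps) are dropped, and output is sorted.

Because clustering happens on the candidate set and only the final filter
depends on `call_threshold`, raising the threshold can only remove calls —
the subset property holds structurally.

## Depth down-sampling

`binomial_thin` replaces every stored count `m` with an independent
`Binomial(m, α)` draw (zeros stay zero; pixels thinned to zero are
dropped), the standard way to emulate an `α`-fraction sequencing depth
without re-mapping. It requires integer (raw) counts and a seed.

## Evaluation utilities

* **APA** — each call's `(2k+1)²` window (default `k = 5`) is normalized
  by its own window mean, then windows are averaged element-wise. The
  scalar centre-enrichment divides the aggregate centre by the mean of
  the four `k×k` corner quadrants (a flat map scores exactly 1; the
  corner-based denominator was chosen because APA heat-maps are usually
  shown without a scalar). Per-window normalization makes the statistic
  invariant to global rescaling of the map.
* **Shuffled controls** — each of `n_controls` (default 50) controls
  preserves, per chromosome, the multiset of loop distances; anchors are
  re-drawn uniformly with the interval between the two anchors required
  to avoid assembly-gap intervals, with a 1,000-draw retry budget per
  loop (unplaceable loops are dropped with a warning).
* **Fold enrichment** — non-redundant anchors (deduplicated across calls)
  overlapping ≥ 1 peak (0-based half-open, ≥ 1 bp), divided by the mean
  of the same count over the controls; a zero control mean reports an
  infinity sentinel with a flag.
* **Distance summary** — counts and fractions per distance stratum for
  user-supplied break points.

## Synthetic data generator

`simulate_map` draws independent Poisson counts around
`λ(i, j) = base_intensity · exp(−(j−i)/decay_scale)` (a power-law option
exists), multiplied by a per-loop factor at planted dots. Defaults emulate
a deeply sequenced 10-kb human map — `base_intensity = 250` at the
diagonal with `decay_scale = 30` bins gives hundreds of counts at short
range and ~10 at 1 Mb, the magnitude profile of a multi-billion-read
experiment — with planted dots 10× the local expectation (the strength of
clear CTCF-class loops) at log-uniform distances of 10–100 bins
(100 kb–1 Mb). Training fixtures blur each dot over ±1 bin by default
(Gaussian weights, σ ≈ 0.75 bins): real anchors are not bin-aligned and
punctate enrichments span 2–3 bins at 10 kb, which is also why high-
probability pixels arrive in clusters the pooling stage must collapse.
Single-pixel dots remain available (`blur=False`) but starve the
classifier of the multi-pixel structure real dots carry. Planted loops
keep ≥ 6 bins Chebyshev separation and a margin from the matrix edge.

What the simulator does *not* reproduce: TADs and compartments, balancing
artefacts, mappability/gap structure, anchor-sharing loop networks, and
the heavy-tailed noise of real libraries. Passing the recovery tests
therefore shows the pipeline is correct and sensitive under its own
assumptions, not that it matches published loop lists on real data.

## Reference evaluation setup

The test suite's end-to-end check uses two simulated 400-bin chromosomes
at 10 kb with 50 planted loops each, half of the truth used as the
training list, hold-out training with the default grid, and default
thresholds. Measured on the held-out half at ±2-bin tolerance, recall and
precision are required to reach 0.8 (precision is measured against all
planted loops, because calls legitimately include the training loops),
and calls from an `α = 0.5`-thinned, independently retrained run must
overlap ≥ 70% of the full-depth calls. These problem sizes keep the whole
suite small enough to run routinely while still exercising every stage.

## Numerical choices and degenerate inputs

* Duplicate triplet entries are summed; lower-triangle entries are
  mirrored; negative counts are rejected.
* Windows crossing the matrix boundary return a `None` sentinel and are
  skipped (and counted) everywhere.
* `alpha` outside (0, 1] and non-integer counts are rejected by thinning.
* Ranks use `scipy.stats.rankdata(method="average")`; all tie handling
  follows from that.
* All stochastic steps (simulation, negative sampling, CV splits, tree
  seeds, shuffles) derive from explicit integer seeds; identical seeds
  give bit-identical outputs, including written BEDPE.

## Known limitations

* Per-chromosome dense windows are materialized for batch featurization;
  at 10 kb this is fine into the tens of thousands of bins per chromosome
  but would need tiling for chromosome-scale maps at ≤ 1 kb resolution.
* The minimal cooler reader handles the standard single-resolution layout
  (and `::/resolutions/<res>` URIs); exotic cooler variants are not
  supported.
* No FDR estimate is attached to calls; the probability threshold is the
  only knob.
* Training lists must match the map's assembly and chromosome naming; no
  lift-over is performed.
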