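# Methods notes

This note records the model conventions, parameter choices and numerical
decisions behind tilechrom, and what the synthetic-data tests do and do
not demonstrate about real arrays.

## Coordinates and containers

All intervals are 0-based half-open `[start, end)`. A gene's TSS is
stored as the half-open boundary coordinate flanking its first
transcribed base (`start` on +, `end` on −), so a 400-bp promoter is
`[tss−400, tss)` on + and `[tss, tss+400)` on − without special-casing.
Probe tracks are per-chromosome sorted position/value arrays with NaN
for missing probes; binarization and segmentation live on a fixed window
grid of `floor(length / 50)` windows per chromosome (partial trailing
windows are dropped).

## Preprocessing

Normalization subtracts the Tukey biweight mean of each sample's
log₂(Cy5/Cy3) ratios. The estimator uses tuning constant c = 5 with MAD
scale (held fixed at the initial median), iterated to a 1e-6 tolerance
with a 50-iteration cap; a `one_step` switch reproduces the one-pass
convention used by some array-scaling software, since the two differ
only in the third decimal on realistic data and the original choice is
not recoverable. MAD = 0 degenerates to the median. Smoothing is a
position-centered running median over ±75 bp, endpoints inclusive;
probes whose window holds fewer than three probes with non-missing,
nonzero values become missing and are excluded from thresholding.
"Nonzero" is interpreted as non-missing and ≠ 0. A consequence worth
knowing: the median over a 3-probe window is a majority filter, so an
isolated single-window signal spike cannot survive smoothing.

## Null estimation and cher calling

The mode m₀ of the smoothed intensities is the argmax of a binned
Gaussian-kernel density (1024 bins, parabolic peak refinement). The
bandwidth is 2× the Silverman rule: the mode's variance scales as
1/(n·h³), so oversmoothing stabilizes it markedly, and the bias is
negligible for a locally symmetric peak (verified against the
half-normal closed form in the acceptance suite). The null sample is the
reflection {m₀ + (m₀ − y) : y < m₀}; thresholds are its empirical
quantiles, so for a Normal(0, σ) null y₀(0.99) → 2.576σ and
y₀(0.95) → 1.960σ. Calibration is therefore one-sided: among probes on
the enriched side of the mode, a fraction (1 − q) exceeds y₀(q).

Exceedance is strict (y > y₀), which makes the all-equal degenerate
track yield zero calls. Candidate runs need ≥ 2 probes (configurable);
runs are discarded before merging; two surviving regions merge when the
gap between them is < 50 bp (strictly). A region spans first to last
qualifying probe position + 1 — probe-span inflation by the probe
spacing is deliberately avoided. Replicate combination intersects
coordinates of overlapping 95%-level regions from every replicate pair
and keeps intersections with ≥ 1 bp of 99%-level support in any
replicate; a single-replicate sample passes its 95% calls through with a
warning. For broad, low-enrichment marks (H3K27me3 by default) the
caller is re-run at the 75% quantile and the result is unioned with the
replicate-combined calls; `broad_mode` can instead replace them or be
switched off, since which variant fed the original binarization is not
determinable.

## The chromatin-state model

`BernoulliHMM` is built from one binary matrix per tissue sharing a mark
ordering; every chromosome of every tissue is an independent observation
sequence under one parameter set ("joint learning"). Emissions are
product-Bernoulli per mark. Estimation is Baum–Welch EM with a scaled
forward–backward recursion (compiled kernel, with an identical
pure-numpy reference path used when numba is unavailable); per-window
emission likelihoods are row-rescaled by their max before scaling, so
sequences with many marks cannot underflow. Emissions are floored at
1e-6 from 0/1 to keep the likelihood finite; initial parameters are the
data marginals perturbed uniformly in ±0.25 per state, transitions
uniform with a 0.8 diagonal, π uniform. Five random restarts by default,
tolerance 1e-4 on the log-likelihood gain, 500-iteration cap; the
best-likelihood restart wins. Decoding is the forward–backward posterior
argmax per window (Viterbi offered as an option); ties break to the
lowest state index everywhere.

Fold enrichment is computed entirely on the window grid: a window
belongs to a feature if it overlaps it by ≥ 1 bp; empty states or
features report NaN with a warning. Feature assignment uses fold ≥ 2 and
main marks use emission ≥ 0.5, both inclusive at the boundary. State
correspondence between independently fitted models is the minimum-total
L1 Hungarian assignment on emission rows.

## Synthetic data: what it emulates, and what it does not

The generator plants truth directly on the 50-bp binarization grid: a
sticky Markov chain (default 5 states, self-probability 0.9 → mean
domains of ~10 windows, i.e. the sub-kilobase regime of a compact
genome), per-window Bernoulli mark presence from well-separated
emissions in {0.05, 0.95}, and probe values equal to a two-component
Gaussian signal (means 2.0 present / 0.0 absent, σ = 0.5, two
replicates with independent noise). The default toy genome is 1 Mb in
three chromosomes (A/X/Y) with compact gene models (intron scale 47 bp,
intergenic scale 400 bp), a quarter of genes in operons (all
trans-spliced, topped up to a 39% trans-spliced fraction), and TEs placed
with a 10× density multiplier on the gene-poor Y chromosome with order
labels from the usual retro/DNA-element vocabulary. A single global seed
feeds named substreams, so every artefact is byte-reproducible while
replicates stay independent.

Deliberately not modelled: probe GC/sequence bias, dye bias and spatial
array artefacts, TE sequence content, and any dependence of probe noise
on signal. Passing tests therefore demonstrate the correctness of the
algorithms under the stated signal model — thresholding calibration,
exact interval arithmetic, identifiability and recovery of planted
states — not robustness to array-specific systematics, which the
normalization stage only partially absorbs.

Probe spacing defaults to 50 bp (one probe per binarization window);
the original array's spacing is not published, so this is an assumption,
and the spacing is a config field.

## End-to-end zero-noise identity

With noise 0 and deterministic (0/1) emissions, the pipeline recovers
the planted mark presence and state path *exactly* when run in the
configuration the identity logically requires: smoothing disabled (the
3-probe median is a majority filter and erases single-window domains),
`min_probes = 1` (a single-window domain holds exactly one probe at
50-bp spacing), and a fixed threshold strictly between the two signal
means. These are ordinary config axes, and the acceptance suite runs the
identity that way; with the defaults (smoothing on, ≥ 2 probes) recovery
is exact only for domains of ≥ 2 windows, which is the expected
behaviour, not a defect.

## Downstream statistics

Expression specificity is 1 − H/log₂(n) with 0·log 0 := 0; all-zero
vectors are missing. Gene expression classes: "silent" is ≤ 0 expression
units by default — the cutoff is a config value reported in outputs,
since no published definition exists — and "high" is the top quartile
among expressed genes (≥ the 75th percentile, ties included). GC deciles
take exactly ⌊0.1 n⌋ genes per tail after a stable sort, so ties resolve
by gene-id order. Meta-profiles exclude genes shorter than 1 kb or with
either flank (to the nearest gene or the chromosome end) under 1.1 kb,
average per-gene bin means, and use a 1.96·SE normal-approximation 95%
band.

Chi-squared tests are Pearson without continuity correction uniformly
(including 2×2), with expected counts and standardized residuals
reported and a warning when an expected cell is < 1; a table with an
empty margin raises instead of returning a 0/0. Mann–Whitney U is exact
for tie-free samples of ≤ 50 per group, otherwise the tie-corrected
normal approximation; the median-ratio statistic accompanies the test.
GO-subset clustering uses 1 − Pearson distance with average linkage
(the linkage is a config option; only the distance is prescribed by
convention), pairwise-complete correlations, rows with < 3 finite values
dropped, constant rows assigned distance 1, and cluster labels numbered
by first occurrence so output is row-order stable. "Constitutively
expressed" means nonzero in every stage column. X:A ratios average
linear expression by default with a log-scale option.

## Problem sizes

The test and acceptance workloads are sized for a laptop-class single
core: 10⁶-probe null calibration, 1000-track caller-oracle replay,
exhaustive path summation at K ≤ 3 and n ≤ 12, 2×10⁴-window planted
recovery at K = 5 / M = 8, and a 330k-bp three-chromosome zero-noise
pipeline run. The full suite completes in well under a minute of compute
per stage; all sizes are config fields and scale up unchanged.

## Known limitations

* The cher score is the maximum smoothed value, not an area statistic;
  ranking long domains against sharp peaks is not meaningful.
* The HMM assumes mark calls are conditionally independent given the
  state; correlated binarization errors (shared input DNA) violate this.
* Replicate combination with > 2 replicates coalesces overlapping
  pairwise intersections, which is slightly more permissive than a
  strict "≥ 2 of n" coverage count on pathological overlap patterns.
* GO clustering treats terms as flat gene sets; no DAG propagation and
  no multiple-testing correction across subsets.
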