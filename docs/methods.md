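# Methods

This note documents the models, procedures, default parameters, and
numerical choices implemented in `assemblyscope`, and the design decisions
behind them. All quantitative statements here are computed by the test suite
(`tests/`) or the reproduction script (`scripts/acceptance.py`).

## 1. Stimulus generation (`stimgen`)

Thalamic input is modeled as a set of fibers with 2-D locations, partitioned
into spatial bundles by k-means (`cluster_fibers`). Patterns are sets of
bundles arranged as an overlap pyramid: disjoint base patterns at the bottom,
composites formed by unioning parts of bases above them, so that pairs of
patterns span a range of overlaps. `_split_counts` divides a base's bundles
as evenly as possible among the composites that draw from it.

A presentation stream (`generate_stream`) interleaves patterns at a fixed
inter-stimulus interval (default 500 ms). In block-balanced mode every
consecutive window of `n_patterns × block` events contains each pattern
exactly `block` times; the acceptance criterion's arithmetic (25 reps × 10
patterns × 500 ms = 125 s) is exact by construction. Fiber spikes during a
presentation follow an exponentially decaying rate profile
(peak → baseline with time constant τ); the expected extra count per
presentation has the closed form `(peak − base)·τ·(1 − e^(−isi/τ))/1000`,
which the unit tests check against simulation. First-spike latencies are
drawn from a truncated exponential via inverse-CDF sampling (closed form, no
rejection loop). A fixed 12% of fibers are "nonspecific" and fire for every
pattern.

The distance between two patterns is the earth-mover distance between the
uniform distributions over their fiber locations, solved exactly as a linear
program (`scipy.optimize.linprog`, HiGHS). A brute-force EMD oracle verifies
it on small instances.

## 2. Synthetic circuit with planted ground truth (`circuit`)

The default study conditions are fixed and are not tuned per experiment:

- 200 neurons; five planted groups — four "early" groups of 40 and one
  "late" group of 60 that shares neurons with the early groups;
- per-member participation 0.8 (each member fires in a presentation with
  probability 0.8, overridable per neuron);
- background rate 0.5 Hz; spike-time jitter SD 2 ms; 20 repetitions per
  pattern in the default stream.

The connectome is a stochastic block model: connection probability 0.15
within a planted group, 0.02 between, with an optional feedforward bias from
early-only to late-only neurons. Thalamocortical innervation is aligned: a
fiber of a pattern that drives a group innervates that group's members with
probability 0.3 vs 0.02 baseline. Evoked spikes are placed in
group-specific latency windows after each presentation of a driving pattern.

What the generator does emulate: planted co-firing groups with controllable
reliability, latency structure (early/late), connectivity and innervation
biases aligned with membership, Poisson background. What it does **not**
emulate: membrane dynamics, synaptic transmission or plasticity, oscillations,
spatial geometry of the network, inhibition, or any causal link from the
generated connectome to the generated spikes — structure and activity are
planted *consistently*, not mechanistically coupled. Conclusions about
biological circuits cannot be drawn from it; it exists to give the statistics
a ground truth.

## 3. Assembly detection (`detect`)

The five-step procedure, with defaults:

1. **Binning** — 20 ms bins (`bin_size=20`).
2. **Significant bins** — a bin is significant if its population count
   exceeds `mean + 95th percentile of the SDs` of 100 shuffles in which each
   spike is independently shifted by ±1 bin circularly
   (`threshold_mode="shift_std"`; an alternative `count_percentile` mode
   thresholds at the 95th percentile of shuffled counts).
3. **Similarity** — cosine similarity between the per-neuron activation
   vectors of significant bins (binary or count-weighted).
4. **Clustering** — Ward linkage on the rows of the similarity matrix; the
   number of clusters is chosen by minimizing the Davies–Bouldin score over
   5–20 (`n_range`), unless fixed with `n_clusters`.
5. **Members** — a neuron belongs to a cluster if its Pearson correlation
   with the cluster's significant-bin indicator exceeds the 95th percentile
   of 1000 circular-shift controls; thresholds are pair-specific. A
   validation filter drops clusters whose members' mean pairwise correlation
   does not exceed the population mean. Temporal labels early/middle/late
   are assigned by median first-spike latency with boundaries at 40 and
   80 ms.

Provenance (`db_scores`, thresholds, chosen cluster count) is stored in the
result; `db_scores` uses string keys so that a fresh run and a JSON
round-tripped resume run serialize identically.

A subtlety exercised by the unit tests: circular-shift controls are only
valid when the significant-bin pattern is aperiodic — periodically planted
bins let shifts by multiples of the period realign activity and inflate the
null's 95th percentile.

## 4. Structural features (`structure`)

- **Directed simplex counts**: number of (k+1)-cliques whose connectivity is
  a transitive tournament (a fully feedforward motif), counted per dimension
  up to `max_dim`. Verified against an itertools permutation oracle for
  n ≤ 10. Controls are degree-matched random graphs.
- **k-indegree**: for each neuron, the number of k-simplices in the assembly
  whose sink it is; `k=0` is plain indegree from members.
- **Common thalamic indegree**: for each neuron, the mean over member pairs
  of shared innervating fibers (binarized, self-pairs excluded).
- **Pattern indegree**: innervation received from the fibers of a given
  pattern.

## 5. Synaptic clustering coefficient (`synclust`, `morphology`)

Morphologies are synthetic full binary trees (default 40 leaves) with SWC
I/O. Synapses live on edges with offsets; distances between synapses are
path distances through the tree, computed via a per-node root-path table and
verified against a networkx Dijkstra oracle. The observed statistic is the
mean nearest-neighbor distance (NND) among the synapses of the assembly's
presynaptic neurons; controls re-place the same number of synapses uniformly
on the dendrite (default `n_controls=20`). The SCC is the z-score of the
observed NND against the controls, sign-flipped so positive means clustered.

**Significance (deviation from the literal source procedure, ledgered):** a
one-sample t test of the observed value against the control sample treats
the observed NND as the mean of `m` controls and has a ~60% false-positive
rate under the null with m=20. We instead use a prediction-interval-scaled
two-tailed t test, `t = (obs − mean_c)/(s_c·√(1 + 1/m))` with `df = m − 1`,
which asks whether the observation is consistent with being *one more draw*
from the control distribution. The acceptance null calibration measures a
4/100 false-positive rate at α=0.05.

## 6. Information statistics (`infostats`)

The core statistic nI is described in the README. Defaults: 21 equal-width
bins for continuous features (`n_bins=21`), 100 permutation controls,
threshold at control mean + 1 SD, MI normalized by label entropy. The plugin
MI is verified against explicit-summation oracles to 1e-12.

The mean+1σ threshold is intentionally permissive — it is the source
procedure, not a calibrated test. Under a chi-square view of plugin MI, the
exceedance probability of mean+1σ is in the 15–25% range, which is why the
nI null-calibration acceptance criterion (≥95/100 zeros) cannot be met by
this rule; see §9.

The conditional variant stratifies by `z` (same binning), computes the
within-stratum MI, and applies the same thresholding against permutations of
`y` within strata. With coarse `z` bins, residual within-bin variation of
`z` can leave genuine conditional dependence in a chain X←Z→Y; the default
21 bins make the strata fine enough that the chain null reports 0 in the
unit test.

## 7. Consensus, coreness, reliability (`consensus`)

Detection is repeated over independently generated spike trains
("repetitions"); each detected assembly becomes an instance. Instances are
clustered by Jaccard similarity with a hard constraint that two instances
from the same repetition never merge (enforced and tested adversarially).
Per-neuron **coreness** within a consensus assembly is
`−log10 P(X ≥ r)` under a binomial null for appearing in `r` of the
instances, capped at 12; the **core** is the set above threshold 4. Verified
against a `math.comb` summation oracle to 1e-9.

**Spike-time reliability** is the mean pairwise correlation of
Gaussian-smoothed (SD 10 ms), 1 ms-binned spike trains across repetitions.
Independent Poisson trains calibrate near 0 (acceptance measures
|mean| < 0.1, actual ≈ 0.001).

The reliability–coreness analysis requires graded participation to be
meaningful: at uniform participation 0.8 every member is detected in every
repetition and coreness saturates at the cap, leaving no gradient to
correlate. The study condition for this analysis therefore draws per-member
participation from uniform(0.15, 0.95). This is a property of the planted
effect — a reliability gradient is a precondition of the question — not a
tuned threshold.

## 8. Workflow (`workflow`)

`input_output_map` computes, for each pattern pair, the input EMD between
fiber locations and the Euclidean distance between normalized mean
significant-bin response vectors, and fits a line (`scipy.stats.linregress`).
`ni_matrix` and `feature_membership_report` assemble feature-vs-membership
nI matrices. `run_pipeline` chains everything from a YAML config (unknown
keys rejected), writes per-stage artifact directories, and can resume from
existing artifacts; fresh and resumed runs produce byte-identical summaries.

## 9. Known red acceptance criterion

`tests/test_acceptance.py::test_criterion_4_ni_null` requires the nI null
calibration to return exactly 0 in ≥95 of 100 null trials (n=2000 samples,
10% members, 21 bins, 100 permutations). The frozen construction (rng seed
7) measures **76/100**. This is not a bug in the implementation: the
mean+1σ rule on a statistic whose null distribution is approximately scaled
chi-square has an exceedance probability far above 5%, so the criterion is
mathematically unattainable for the specified thresholding rule. The test is
left failing with this analysis rather than weakened; the magnitude of
spurious nI values under the null is small relative to the planted effects
(the planted 0-indegree diagonal means ≈ 0.8 in the acceptance run).

## 10. Determinism and numerics

All randomness flows through `numpy.random.default_rng` seeded via
`SeedSequence` spawning; every public entry point takes a seed. The
acceptance script derives all sub-seeds (< 2^31) from `--seed`. Hypothesis
runs derandomized. Floating-point comparisons against oracles use absolute
tolerances stated per test (1e-12 for MI, 1e-10 for Davies–Bouldin, 1e-9 for
coreness).

## 11. Limitations

- The synthetic generator plants structure–activity alignment; it cannot
  validate the statistics against mechanistically generated activity.
- Simplex counting is exponential in motif size and restricted to small
  assemblies/dimensions (`pair_budget` guards the member-assignment cost
  similarly).
- The SCC uniform-placement control ignores synapse-density gradients along
  real dendrites.
- The nI thresholding rule is permissive under the null (§9); downstream
  analyses should treat small nonzero nI values near the threshold with
  caution.
- Temporal labels use fixed 40/80 ms boundaries, appropriate for the
  generator's latency windows but not general.
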