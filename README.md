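# assemblyscope

Detection of cortical cell assemblies from spike trains, and the statistics
that relate assembly membership to the underlying structural connectivity —
evaluated end to end on synthetic circuits with planted ground truth.

## What this package does

Groups of neurons that repeatedly fire together within tens of milliseconds
("cell assemblies") are a candidate unit of cortical computation. This package
implements a complete pipeline for studying them:

1. **Stimulus generation** (`assemblyscope.stimgen`) — spatially bundled
   thalamic input fibers, base/composite spike-train patterns arranged in an
   overlap pyramid, block-balanced presentation streams, and an
   earth-mover-distance (EMD) metric between the fiber locations of two
   patterns.
2. **Synthetic circuit with planted ground truth**
   (`assemblyscope.circuit`) — a 200-neuron network with four early assembly
   groups of 40 neurons, one shared late group of 60, a stochastic block-model
   connectome, pattern-aligned thalamocortical innervation, and evoked spike
   trains with controllable per-neuron participation.
3. **Assembly detection** (`assemblyscope.detect`) — the five-step procedure:
   20 ms binning; significant bins against spike-shift shuffles; cosine
   similarity of significant-bin activation vectors; Ward clustering with
   Davies–Bouldin model selection; member assignment against circular-shift
   controls; coherence validation; early/middle/late temporal labels.
4. **Structural features** (`assemblyscope.structure`,
   `assemblyscope.morphology`, `assemblyscope.synclust`) — directed simplex
   counts vs degree-matched controls, k-indegree, common thalamic indegree,
   pattern indegree, and the synaptic clustering coefficient (SCC) on
   dendritic morphologies.
5. **Statistics** (`assemblyscope.infostats`, `assemblyscope.consensus`) —
   the core statistic (below), consensus assemblies across detection
   repetitions, a binomial coreness score, and spike-time reliability.
6. **Workflow** (`assemblyscope.workflow`) — feature-vs-membership nI
   matrices, the input–output map (input EMD vs evoked-response distance),
   and a resumable, YAML-configured end-to-end pipeline.

### Core statistic: signed thresholded normalized mutual information (nI)

For a per-neuron structural feature `x` and a binary membership label `y`,
`normalized_mi(x, y)` computes the plugin mutual information of the binned
joint distribution, normalizes it by the label entropy, and compares it to
permutation controls: if the observed value does not exceed the control mean
plus one control standard deviation, nI is reported as exactly 0; otherwise
its magnitude is kept and its sign is set by the direction of association
(positive when members have larger feature values). A conditional variant
`conditional_normalized_mi(x, y, z)` stratifies by a third variable to ask
whether `x` carries information about membership beyond `z`.

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
artifacts to `results/`. Running them in order (`python analysis/01_... `
through `07_...`, each seeded, ~30 s total) prints, among other things:

```
# 03_detect_assemblies.py — detection on the default planted study (seed 0)
significant bins: 356 (threshold 10.1)
chosen cluster count: 5
planted group 0 (n=40): best Jaccard 1.000 with assembly 4 (early, median latency 10.0 ms)
planted group 4 (n=60): best Jaccard 0.967 with assembly 0 (late, median latency 120.0 ms)
mean best-match Jaccard: 0.893

# 04_structural_features.py — structure vs membership
assembly 0 (n=58) simplex counts: [58, 497, 622, 108]
matched-control mean:            [58.0, 174.2, 45.9, 1.6]
nI[0-indegree] diagonal: [0.761, 0.421, 0.757, 0.862, 0.942]

# 05_synaptic_clustering.py — SCC, planted clustered vs uniform placement
clustered: mean SCC 5.17, significant 10/10
uniform: mean SCC -0.37, significant 1/10

# 06_consensus_reliability.py — graded participation, 5 detection repetitions
consensus assemblies: 5
reliability vs coreness: Spearman rho 0.507, p 1.76e-14

# 07_input_output_map.py — input EMD predicts output distance
fit: slope 0.00103, Pearson r 0.931, p 0.0070
```

Detection recovers the planted groups (group 3 scores 0.5 only because it
shares neurons with the late group and the two merge into one 58-neuron
assembly plus remainder); assemblies are far richer in high-dimensional
simplices than degree-matched controls; indegree from fellow members carries
information about membership (positive nI diagonal); planted dendritic
clustering is detected with no false positives from uniform placement except
at the nominal rate; and more reliable neurons sit deeper in the consensus
core.

## Reproduction

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the package's main computations (stream arithmetic, planted recovery,
nI/SCC/reliability null calibrations, planted-effect recovery, bin-size
robustness) in ~1 minute and writes each headline quantity as
`{"name": {"value": ..., "n": ...}}`. All randomness derives from `--seed`.

## Layout

```
src/assemblyscope/   library (all logic lives here)
analysis/            numbered thin driver scripts writing to results/
scripts/acceptance.py  seeded end-to-end reproduction script
tests/               pytest suite (unit, property, acceptance)
docs/methods.md      model, parameters, numerical choices, limitations
```
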