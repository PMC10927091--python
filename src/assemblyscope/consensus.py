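"""Consensus assemblies across repetitions, coreness, and spike-time
reliability.

Assemblies detected in repeated runs of the same stimulus stream are pooled
and clustered by the Jaccard distance of their member sets, with
same-repetition pairs forced apart, under the constraint that no consensus
group contains two instances from one repetition. A neuron's coreness is
the negative log tail probability of its instance count under a binomial
chance model; neurons above a coreness threshold form the core. Spike-time
reliability is the mean pairwise cosine similarity of mean-centered,
Gaussian-smoothed single-repetition spike trains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter1d
from scipy.stats import binom

from .containers import BinnedSpikes, SpikeData

CORENESS_CAP = 12.0  # -log10 of the 1e-12 survival-probability floor


@dataclass
class AssemblyInstance:
    neurons: np.ndarray
    repetition: int
    label: Optional[object] = None

    def __post_init__(self) -> None:
        self.neurons = np.unique(np.asarray(self.neurons, dtype=np.int64))
        if self.neurons.size == 0:
            raise ValueError("empty assembly instance")


@dataclass
class ConsensusAssembly:
    instances: List[AssemblyInstance]
    union: np.ndarray = None
    instance_counts: np.ndarray = None  # r per union neuron
    fractions: np.ndarray = None  # r / n_instances
    coreness: np.ndarray = None
    core: np.ndarray = None

    def __post_init__(self) -> None:
        reps = [i.repetition for i in self.instances]
        if len(reps) != len(set(reps)):
            raise ValueError("two instances share a repetition id")
        if self.union is None:
            self.union = np.unique(np.concatenate([i.neurons for i in self.instances]))
        if self.instance_counts is None:
            counts = np.zeros(self.union.size, dtype=np.int64)
            pos = {int(n): k for k, n in enumerate(self.union)}
            for inst in self.instances:
                for n in inst.neurons:
                    counts[pos[int(n)]] += 1
            self.instance_counts = counts
        if self.fractions is None:
            self.fractions = self.instance_counts / len(self.instances)

    @property
    def n_instances(self) -> int:
        return len(self.instances)


@dataclass
class ReliabilityResult:
    values: np.ndarray  # per neuron in [-1, 1]; NaN if silent everywhere
    neuron_ids: np.ndarray
    bin_size: float
    kernel_sd: float
    n_pairs: np.ndarray  # valid repetition pairs used per neuron


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = set(a.tolist()), set(b.tolist())
    return 1.0 - len(sa & sb) / len(sa | sb)


def assembly_distance_matrix(instances: Sequence[AssemblyInstance]) -> np.ndarray:
    """Jaccard distances between instance member sets, with same-repetition
    pairs overwritten by twice the matrix maximum so they never merge."""
    if len(instances) < 2:
        raise ValueError("need at least 2 instances")
    n = len(instances)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = jaccard_distance(instances[i].neurons, instances[j].neurons)
    penalty = 2.0 * D.max() if D.max() > 0 else 2.0
    for i in range(n):
        for j in range(i + 1, n):
            if instances[i].repetition == instances[j].repetition:
                D[i, j] = D[j, i] = penalty
    return D


def cluster_instances(instances: Sequence[AssemblyInstance]) -> List[ConsensusAssembly]:
    """Ward-cluster the modified distance matrix; return the cut with the
    lowest cluster count in which no cluster holds two instances from the
    same repetition."""
    instances = list(instances)
    reps = {i.repetition for i in instances}
    if len(instances) == 1 or len(reps) == 1:
        return [ConsensusAssembly([i]) for i in instances]
    D = assembly_distance_matrix(instances)
    with warnings.catch_warnings():
        # rows of the (modified) distance matrix are deliberately used as
        # the Euclidean embedding, consistent with the detection stage
        warnings.filterwarnings("ignore", message=".*uncondensed distance matrix.*")
        Z = linkage(D, method="ward")
    n = len(instances)
    for k in range(2, n):
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
        ok = True
        for c in np.unique(labels):
            rr = [instances[i].repetition for i in np.where(labels == c)[0]]
            if len(rr) != len(set(rr)):
                ok = False
                break
        if ok:
            return [
                ConsensusAssembly([instances[i] for i in np.where(labels == c)[0]])
                for c in np.unique(labels)
            ]
    warnings.warn("no valid cut found: falling back to singleton consensus assemblies")
    return [ConsensusAssembly([i]) for i in instances]


def coreness(ca: ConsensusAssembly, tail_mode: str = "gt") -> np.ndarray:
    """Per-neuron coreness: -log10 of the binomial tail probability of the
    neuron's instance count.

    The chance model is Binomial(n = number of instances, p = mean instance
    size / union size). The literal rule uses the survival probability
    P(X > r) (``tail_mode='gt'``); ``'ge'`` uses P(X >= r). The tail is
    floored at 1e-12, capping coreness at 12.
    """
    if ca.n_instances < 1:
        raise ValueError("need at least one instance")
    if ca.union.size == 0:
        raise ValueError("empty union")
    n = ca.n_instances
    p = float(np.mean([i.neurons.size for i in ca.instances])) / ca.union.size
    p = min(p, 1.0)
    r = ca.instance_counts
    if tail_mode == "gt":
        tail = binom.sf(r, n, p)  # 1 - B(r) = P(X > r)
    elif tail_mode == "ge":
        tail = binom.sf(r - 1, n, p)
    else:
        raise ValueError("tail_mode must be 'gt' or 'ge'")
    vals = -np.log10(np.maximum(tail, 10.0 ** (-CORENESS_CAP)))
    ca.coreness = vals
    return vals


def core(ca: ConsensusAssembly, threshold: float = 4.0) -> np.ndarray:
    """Neurons whose coreness exceeds the threshold."""
    if ca.coreness is None:
        coreness(ca)
    out = ca.union[ca.coreness > threshold]
    ca.core = out
    return out


def average_binned_spikes(binned_list: Sequence[BinnedSpikes]) -> BinnedSpikes:
    """Element-wise mean of aligned binned-spike matrices (trial average);
    the result is real-valued and flows through detection unchanged."""
    first = binned_list[0]
    for b in binned_list[1:]:
        if b.matrix.shape != first.matrix.shape or b.bin_size != first.bin_size or b.t0 != first.t0:
            raise ValueError("binned inputs must share shape, bin size and origin")
    M = np.mean([b.matrix for b in binned_list], axis=0)
    return BinnedSpikes(M, first.bin_size, first.t0, first.units)


def spike_time_reliability(
    spikes_per_rep: Sequence[SpikeData],
    bin_size: float = 1.0,
    kernel_sd: float = 10.0,
) -> ReliabilityResult:
    """Mean pairwise cosine similarity of mean-centered Gaussian-smoothed
    spike trains across repetitions.

    Trains are binned at ``bin_size`` ms, convolved with a Gaussian kernel
    (sd ``kernel_sd`` ms, truncated at 4 sd), mean-centered, and compared
    per repetition pair; pairs with a zero-norm signal are skipped and
    counted. A neuron silent in every repetition gets NaN.
    """
    if len(spikes_per_rep) < 2:
        raise ValueError("need at least 2 repetitions")
    durations = {s.duration for s in spikes_per_rep}
    if len(durations) != 1:
        raise ValueError("repetitions must have equal duration")
    units = spikes_per_rep[0].units
    from .detect import bin_spikes  # late import: avoids a module cycle

    R = len(spikes_per_rep)
    smoothed = []
    for s in spikes_per_rep:
        M = bin_spikes(s, bin_size).matrix
        S = gaussian_filter1d(M, sigma=kernel_sd / bin_size, axis=1, mode="constant", truncate=4.0)
        S = S - S.mean(axis=1, keepdims=True)
        smoothed.append(S)

    n_units = units.size
    values = np.full(n_units, np.nan)
    n_pairs = np.zeros(n_units, dtype=np.int64)
    norms = np.array([np.linalg.norm(S, axis=1) for S in smoothed])  # (R, n_units)
    for u in range(n_units):
        sims = []
        for i in range(R):
            for j in range(i + 1, R):
                if norms[i, u] == 0 or norms[j, u] == 0:
                    continue
                sims.append(
                    float(np.dot(smoothed[i][u], smoothed[j][u]) / (norms[i, u] * norms[j, u]))
                )
        if sims:
            values[u] = np.mean(sims)
            n_pairs[u] = len(sims)
    return ReliabilityResult(values, units, bin_size, kernel_sd, n_pairs)
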