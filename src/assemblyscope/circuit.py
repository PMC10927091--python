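"""Synthetic circuits with planted ground truth.

The generators plant co-firing neuron groups (an "assembly plan") into every
substrate the downstream analyses consume: a directed connectome whose edge
probabilities are elevated within groups (and optionally along the temporal
order of activation), a thalamo-cortical innervation aligned with the input
pattern that recruits each group, network spike trains in which group members
fire in pattern-specific post-onset windows over Poisson background, and
dendritic synapse placements that are either clustered or dispersed (see
:mod:`.morphology`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .containers import SpikeData
from .stimgen import FiberSet, PatternSet, StimulusStream, generate_stream

TemporalClass = str  # "early" | "middle" | "late"


@dataclass
class AssemblyPlan:
    """Ground truth: which neurons co-fire, when, and how reliably.

    ``schedule`` maps a pattern label to the ordered list of (group id,
    latency window in ms relative to stimulus onset) activated by that
    pattern. Groups may overlap in neurons. ``participation_p`` is the
    probability that a member fires in its window at a given presentation;
    per-neuron overrides allow graded reliability.
    """

    groups: Dict[int, np.ndarray]
    temporal_class: Dict[int, TemporalClass]
    schedule: Dict[object, List[Tuple[int, Tuple[float, float]]]]
    participation_p: float = 0.8
    background_rate: float = 0.5  # Hz
    participation_overrides: Dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.groups = {g: np.asarray(m, dtype=np.int64) for g, m in self.groups.items()}
        if not 0.0 <= self.participation_p <= 1.0:
            raise ValueError("participation_p must be a probability")

    def group_of(self) -> Dict[int, List[int]]:
        """neuron id -> list of group ids containing it."""
        out: Dict[int, List[int]] = {}
        for g, members in self.groups.items():
            for n in members:
                out.setdefault(int(n), []).append(g)
        return out

    def early_groups(self) -> List[int]:
        return [g for g, c in self.temporal_class.items() if c == "early"]

    def participation_of(self, neuron: int) -> float:
        return self.participation_overrides.get(int(neuron), self.participation_p)


@dataclass
class Connectome:
    """Directed binary adjacency (row = presynaptic) plus neuron metadata."""

    adj: sp.csr_matrix
    meta: pd.DataFrame  # index: neuron id; columns: cell_type, layer, x, y

    def __post_init__(self) -> None:
        self.adj = sp.csr_matrix(self.adj, dtype=np.int8)
        if self.adj.shape[0] != self.adj.shape[1]:
            raise ValueError("adjacency must be square")
        if self.adj.diagonal().any():
            raise ValueError("self-loops are not allowed")
        if len(self.meta) != self.adj.shape[0]:
            raise ValueError("metadata must cover every neuron")

    @property
    def n_neurons(self) -> int:
        return self.adj.shape[0]

    @property
    def neuron_ids(self) -> np.ndarray:
        return self.meta.index.to_numpy()

    def dense(self) -> np.ndarray:
        return np.asarray(self.adj.todense(), dtype=bool)

    def save(self, mtx_path, meta_path) -> None:
        mmwrite(str(mtx_path), self.adj.tocoo())
        self.meta.rename_axis("neuron_id").to_csv(meta_path, sep="\t")

    @classmethod
    def load(cls, mtx_path, meta_path) -> "Connectome":
        adj = sp.csr_matrix(mmread(str(mtx_path)))
        meta = pd.read_csv(meta_path, sep="\t", index_col="neuron_id")
        return cls(adj, meta)


@dataclass
class ThalamoCorticalInnervation:
    """Bipartite fibers x neurons matrix; entries are synapse counts."""

    matrix: sp.csr_matrix
    fiber_ids: np.ndarray
    neuron_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.fiber_ids = np.asarray(self.fiber_ids, dtype=np.int64)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        if self.matrix.shape != (self.fiber_ids.size, self.neuron_ids.size):
            raise ValueError("matrix shape must match fiber/neuron registries")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("synapse counts must be nonnegative")

    def binarized(self) -> sp.csr_matrix:
        b = self.matrix.copy()
        b.data = (b.data > 0).astype(np.int64)
        return b

    def save(self, mtx_path, fiber_path) -> None:
        mmwrite(str(mtx_path), self.matrix.tocoo())
        pd.DataFrame({"fiber_id": self.fiber_ids}).to_csv(fiber_path, sep="\t", index=False)


DEFAULT_LAYERS = ("L23", "L4", "L5", "L6")
DEFAULT_LAYER_P = (0.3, 0.2, 0.3, 0.2)


def _schedule_precedence(plan: AssemblyPlan) -> set:
    """(gi, gj) pairs where gi's window starts before gj's in some pattern."""
    prec = set()
    for seq in plan.schedule.values():
        for a, (ga, wa) in enumerate(seq):
            for gb, wb in seq[a + 1 :]:
                if wa[0] < wb[0] and ga != gb:
                    prec.add((ga, gb))
    return prec


def generate_connectome(
    n_neurons: int,
    plan: AssemblyPlan,
    p_within: float = 0.15,
    p_between: float = 0.02,
    p_feedforward_bias: float = 0.0,
    seed: int = 0,
    layers=DEFAULT_LAYERS,
    layer_p=DEFAULT_LAYER_P,
) -> Connectome:
    """Directed Erdős–Rényi-style connectome with elevated within-group
    probability and an optional feed-forward bias along the activation order.
    """
    for p in (p_within, p_between, p_feedforward_bias):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    if p_within < p_between:
        raise ValueError("need p_within >= p_between")
    rng = np.random.default_rng(seed)
    member = np.zeros((len(plan.groups), n_neurons), dtype=bool)
    gids = sorted(plan.groups)
    for k, g in enumerate(gids):
        member[k, plan.groups[g]] = True

    shared = (member.T.astype(np.int64) @ member.astype(np.int64)) > 0  # i,j share a group
    P = np.where(shared, p_within, p_between).astype(float)

    if p_feedforward_bias > 0:
        prec = _schedule_precedence(plan)
        for ga, gb in prec:
            ia = member[gids.index(ga)]
            ib = member[gids.index(gb)]
            P[np.ix_(ia, ib)] += p_feedforward_bias
    if P.max() > 1.0:
        raise ValueError("edge probability exceeds 1 for some pair class")
    np.fill_diagonal(P, 0.0)
    A = (rng.random((n_neurons, n_neurons)) < P).astype(np.int8)

    meta = pd.DataFrame(
        {
            "layer": rng.choice(layers, size=n_neurons, p=layer_p),
            "x": rng.random(n_neurons) * 1000.0,
            "y": rng.random(n_neurons) * 1000.0,
        },
        index=pd.RangeIndex(n_neurons),
    )
    meta["cell_type"] = meta["layer"] + "_EXC"
    return Connectome(sp.csr_matrix(A), meta[["cell_type", "layer", "x", "y"]])


def generate_tc_innervation(
    fibers: FiberSet,
    patterns: PatternSet,
    plan: AssemblyPlan,
    p_aligned: float = 0.3,
    p_baseline: float = 0.02,
    n_neurons: int = None,
    seed: int = 0,
    synapse_count: int = 1,
) -> ThalamoCorticalInnervation:
    """Fibers innervate neurons with elevated probability when the fiber
    belongs to the pattern that recruits the neuron's early group."""
    for lab in plan.schedule:
        if lab not in patterns.labels:
            raise ValueError(f"schedule references unknown pattern {lab!r}")
    if n_neurons is None:
        n_neurons = 1 + max(int(m.max()) for m in plan.groups.values())
    rng = np.random.default_rng(seed)
    id_to_idx = {fid: i for i, fid in enumerate(fibers.fiber_ids)}

    # pattern label(s) recruiting each early group
    early = set(plan.early_groups())
    group_patterns: Dict[int, List] = {g: [] for g in early}
    for lab, seq in plan.schedule.items():
        for g, _ in seq:
            if g in early:
                group_patterns[g].append(lab)

    aligned = np.zeros((fibers.n_fibers, n_neurons), dtype=bool)
    for g in early:
        members = plan.groups[g]
        for lab in group_patterns[g]:
            fidx = [id_to_idx[f] for f in patterns.fibers(lab)]
            aligned[np.ix_(fidx, members)] = True

    P = np.where(aligned, p_aligned, p_baseline)
    M = (rng.random(P.shape) < P).astype(np.int64) * synapse_count
    return ThalamoCorticalInnervation(
        sp.csr_matrix(M), fibers.fiber_ids, np.arange(n_neurons)
    )


def generate_network_spikes(
    plan: AssemblyPlan,
    stream: StimulusStream,
    n_neurons: int,
    jitter_sd: float = 2.0,
    seed: int = 0,
) -> SpikeData:
    """Planted network activity: scheduled group members emit one spike per
    presentation (with probability ``participation_p``) uniformly in their
    latency window plus truncated Gaussian jitter, over Poisson background.
    """
    if stream.n_events == 0:
        raise ValueError("empty stimulus stream")
    for members in plan.groups.values():
        if members.size and members.max() >= n_neurons:
            raise ValueError("group neuron ids must be < n_neurons")
    rng = np.random.default_rng(seed)
    ids, times = [], []

    for onset, lab in zip(stream.onsets, stream.labels):
        for g, (lo, hi) in plan.schedule.get(lab, []):
            members = plan.groups[g]
            p = np.array([plan.participation_of(m) for m in members])
            fire = rng.random(members.size) < p
            who = members[fire]
            t_rel = rng.uniform(lo, hi, size=who.size)
            if jitter_sd > 0:
                t_rel = t_rel + rng.normal(0.0, jitter_sd, size=who.size)
            t_rel = np.clip(t_rel, 0.0, np.nextafter(stream.isi, 0.0))
            ids.append(who)
            times.append(onset + t_rel)

    lam = plan.background_rate * stream.duration / 1000.0
    bg_counts = rng.poisson(lam, size=n_neurons)
    ids.append(np.repeat(np.arange(n_neurons), bg_counts))
    times.append(rng.random(int(bg_counts.sum())) * stream.duration)

    return SpikeData(
        np.concatenate(ids), np.concatenate(times), np.arange(n_neurons), stream.duration
    )


# ---------------------------------------------------------------------------
# Default study conditions: the planted dataset the whole pipeline is
# exercised on (200 neurons; 4 early groups of 40 recruited by one pattern
# each; one shared late group of 60 active after every pattern; 5 patterns
# presented block-balanced at 500 ms ISI).
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    fibers: FiberSet
    patterns: PatternSet
    plan: AssemblyPlan
    stream: StimulusStream
    spikes: SpikeData
    n_neurons: int


def default_plan(
    n_neurons: int = 200,
    group_size: int = 40,
    late_size: int = 60,
    participation_p: float = 0.8,
    background_rate: float = 0.5,
    early_window: Tuple[float, float] = (10.0, 30.0),
    late_window: Tuple[float, float] = (100.0, 140.0),
    pattern_labels=("P0", "P1", "P2", "P3", "P4"),
) -> AssemblyPlan:
    """4 disjoint early groups + one shared late group (overlapping the last
    early group), each early group recruited by one pattern; the late group
    follows every pattern, and the last pattern drives only the late group."""
    groups = {i: np.arange(i * group_size, (i + 1) * group_size) for i in range(4)}
    groups[4] = np.arange(n_neurons - late_size, n_neurons)
    temporal_class = {0: "early", 1: "early", 2: "early", 3: "early", 4: "late"}
    schedule = {}
    for i, lab in enumerate(pattern_labels):
        seq = []
        if i < 4:
            seq.append((i, early_window))
        seq.append((4, late_window))
        schedule[lab] = seq
    return AssemblyPlan(groups, temporal_class, schedule, participation_p, background_rate)


def default_study(
    seed: int,
    n_neurons: int = 200,
    reps_per_pattern: int = 20,
    isi: float = 500.0,
    n_fibers: int = 200,
    n_fiber_clusters: int = 20,
    plan: AssemblyPlan = None,
    jitter_sd: float = 2.0,
) -> SyntheticStudy:
    """Assemble the default planted dataset for one seed.

    Fibers sit on a synthetic flat map; five disjoint patterns of 4 bundles
    each recruit the plan's groups via the stream. Sub-seeds are derived so
    each generator gets an independent stream.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    if plan is None:
        plan = default_plan(n_neurons=n_neurons)

    rng = np.random.default_rng(sub[0])
    positions = rng.random((n_fibers, 2)) * 1000.0
    from .stimgen import cluster_fibers  # local import to avoid cycle confusion

    fibers = cluster_fibers(positions, n_fiber_clusters, seed=sub[0])
    labels = list(plan.schedule)
    bundle_ids = np.unique(fibers.bundle_ids)
    per = len(bundle_ids) // len(labels)
    bundles = {
        lab: bundle_ids[i * per : (i + 1) * per] for i, lab in enumerate(labels)
    }
    fiber_sets = {lab: np.sort(fibers.fibers_of_bundles(b)) for lab, b in bundles.items()}
    patterns = PatternSet(labels, bundles, fiber_sets, base_labels=tuple(labels))

    stream = generate_stream(
        labels, reps_per_pattern, isi=isi, block_balanced=False, seed=sub[1]
    )
    spikes = generate_network_spikes(plan, stream, n_neurons, jitter_sd=jitter_sd, seed=sub[2])
    return SyntheticStudy(fibers, patterns, plan, stream, spikes, n_neurons)
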