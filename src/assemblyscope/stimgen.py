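"""Thalamic input construction: fiber bundles, overlapping patterns, stimulus
streams and fiber spike trains.

The stimulus design mimics whisker-like thalamic drive: fibers on a 2-D
flat-map plane are grouped into bundles by k-means; ten input patterns are
built from four disjoint base bundle groups (A-D) plus six composites with a
pyramid of overlaps (E-G combine two bases, H-I three, J all four); a stream
presents the patterns at a fixed inter-stimulus interval, optionally balanced
in blocks; and each presentation drives the pattern's fibers with a firing
rate that jumps to a peak and decays exponentially back to baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .containers import SpikeData

# fixed composition of the ten-pattern scheme: label -> constituent bases
PATTERN_SCHEME = {
    "A": ("A",),
    "B": ("B",),
    "C": ("C",),
    "D": ("D",),
    "E": ("A", "B"),
    "F": ("B", "C"),
    "G": ("C", "D"),
    "H": ("A", "B", "C"),
    "I": ("B", "C", "D"),
    "J": ("A", "B", "C", "D"),
}
BASE_LABELS = ("A", "B", "C", "D")


@dataclass
class FiberSet:
    """Thalamic fibers with 2-D flat-map positions and a bundle assignment."""

    fiber_ids: np.ndarray
    positions: np.ndarray  # (n, 2), micrometres
    bundle_ids: np.ndarray

    def __post_init__(self) -> None:
        self.fiber_ids = np.asarray(self.fiber_ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.bundle_ids = np.asarray(self.bundle_ids, dtype=np.int64)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("fiber positions must be finite")
        if not (len(self.fiber_ids) == len(self.positions) == len(self.bundle_ids)):
            raise ValueError("misaligned fiber arrays")

    @property
    def n_fibers(self) -> int:
        return int(self.fiber_ids.size)

    @property
    def n_bundles(self) -> int:
        return int(np.unique(self.bundle_ids).size)

    def fibers_of_bundles(self, bundles: Sequence[int]) -> np.ndarray:
        mask = np.isin(self.bundle_ids, np.asarray(list(bundles)))
        return self.fiber_ids[mask]

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "fiber_id": self.fiber_ids,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "bundle_id": self.bundle_ids,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FiberSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            df["fiber_id"].to_numpy(), df[["x", "y"]].to_numpy(), df["bundle_id"].to_numpy()
        )


@dataclass
class PatternSet:
    """Ordered input patterns: label -> bundle ids (and the induced fibers)."""

    labels: list
    bundles: dict  # label -> np.ndarray of bundle ids
    fiber_sets: dict  # label -> np.ndarray of fiber ids
    base_labels: tuple = BASE_LABELS

    def fibers(self, label) -> np.ndarray:
        return self.fiber_sets[label]

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "labels": list(self.labels),
                    "base_labels": list(self.base_labels),
                    "bundles": {k: np.asarray(v).tolist() for k, v in self.bundles.items()},
                },
                f,
                indent=1,
            )

    @classmethod
    def from_json(cls, path, fibers: FiberSet) -> "PatternSet":
        with open(path) as f:
            d = json.load(f)
        bundles = {k: np.asarray(v, dtype=np.int64) for k, v in d["bundles"].items()}
        fiber_sets = {k: fibers.fibers_of_bundles(v) for k, v in bundles.items()}
        return cls(d["labels"], bundles, fiber_sets, tuple(d["base_labels"]))


@dataclass
class StimulusStream:
    """Ordered (onset, pattern label) events at a fixed inter-stimulus interval."""

    onsets: np.ndarray  # ms, strictly increasing
    labels: np.ndarray  # pattern labels, aligned to onsets
    duration: float  # ms
    isi: float  # ms

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.onsets.size > 1:
            gaps = np.diff(self.onsets)
            if not np.allclose(gaps, self.isi):
                raise ValueError("onsets must be spaced by exactly isi")

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"time_ms": self.onsets, "pattern": self.labels}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, isi: float) -> "StimulusStream":
        df = pd.read_csv(path, sep="\t")
        onsets = df["time_ms"].to_numpy(dtype=float)
        return cls(onsets, df["pattern"].to_numpy(), float(onsets[-1] + isi), isi)


def cluster_fibers(positions, n_bundles: int, seed: int) -> FiberSet:
    """Group fibers into bundles by k-means on their flat-map positions."""
    positions = np.asarray(positions, dtype=np.float64)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must be (n, 2)")
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite fiber coordinates")
    n = len(positions)
    if n_bundles < 1 or n_bundles > n:
        raise ValueError(f"n_bundles must be in [1, {n}]")
    km = KMeans(n_clusters=n_bundles, n_init=10, random_state=seed)
    labels = km.fit_predict(positions)
    return FiberSet(np.arange(n), positions, labels)


def _split_counts(total: int, k: int) -> list:
    """Split ``total`` into k near-equal integers, remainder to the first parts."""
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def build_patterns(fibers: FiberSet, base_fraction: float = 0.12, seed: int = 0) -> PatternSet:
    """Build the ten-pattern overlap pyramid from disjoint base bundle groups.

    Four disjoint bases of ``s = round(base_fraction * n_bundles)`` bundles
    each; composites keep size ``s`` and draw equal-sized random bundle
    subsets from each constituent base, so e.g. a two-base composite shares
    ``s/2`` bundles with each of its bases.
    """
    if base_fraction * 4 > 1:
        raise ValueError("bases cannot be disjoint: base_fraction * 4 > 1")
    n_bundles = fibers.n_bundles
    s = int(round(base_fraction * n_bundles))
    if s < 4:
        raise ValueError("base pattern size must be >= 4 bundles")
    rng = np.random.default_rng(seed)
    all_bundles = np.unique(fibers.bundle_ids)
    chosen = rng.choice(all_bundles, size=4 * s, replace=False)
    bases = {lab: np.sort(chosen[i * s : (i + 1) * s]) for i, lab in enumerate(BASE_LABELS)}

    bundles = {}
    for label in PATTERN_SCHEME:
        parts = PATTERN_SCHEME[label]
        if len(parts) == 1:
            bundles[label] = bases[parts[0]]
        else:
            counts = _split_counts(s, len(parts))
            draw = [
                rng.choice(bases[b], size=c, replace=False) for b, c in zip(parts, counts)
            ]
            bundles[label] = np.sort(np.concatenate(draw))
    fiber_sets = {k: np.sort(fibers.fibers_of_bundles(v)) for k, v in bundles.items()}
    return PatternSet(list(PATTERN_SCHEME), bundles, fiber_sets)


def generate_stream(
    pattern_labels: Sequence,
    reps_per_pattern: int,
    isi: float = 500.0,
    block_balanced: bool = False,
    block_reps: int = 6,
    seed: int = 0,
) -> StimulusStream:
    """Random presentation order; optionally balanced within blocks.

    In block-balanced mode every pattern occurs exactly ``block_reps`` times
    within each consecutive window of ``n_patterns * block_reps`` events.
    """
    if reps_per_pattern < 1:
        raise ValueError("reps_per_pattern must be >= 1")
    labels = list(pattern_labels)
    rng = np.random.default_rng(seed)
    if block_balanced:
        if reps_per_pattern % block_reps:
            raise ValueError("reps_per_pattern must be divisible by block_reps")
        order = []
        for _ in range(reps_per_pattern // block_reps):
            block = np.repeat(labels, block_reps)
            rng.shuffle(block)
            order.append(block)
        order = np.concatenate(order)
    else:
        order = np.repeat(labels, reps_per_pattern)
        rng.shuffle(order)
    onsets = np.arange(len(order)) * isi
    return StimulusStream(onsets, order, float(len(order) * isi), isi)


def _evoked_spike_times(rng, onset, isi, n_fibers, peak, base, tau):
    """Extra (above-baseline) spikes in one presentation window.

    The above-baseline rate component is ``(peak-base) * exp(-t/tau)`` on
    ``[0, isi)``; its integral gives the expected extra count and its
    normalized CDF inverts in closed form (truncated exponential).
    """
    lam = (peak - base) * tau * (1.0 - np.exp(-isi / tau)) / 1000.0  # rates in Hz, t in ms
    counts = rng.poisson(lam, size=n_fibers)
    total = int(counts.sum())
    u = rng.random(total)
    trunc = 1.0 - np.exp(-isi / tau)
    times = -tau * np.log1p(-u * trunc) + onset
    fiber_idx = np.repeat(np.arange(n_fibers), counts)
    return fiber_idx, times


def generate_fiber_spikes(
    stream: StimulusStream,
    patterns: PatternSet,
    fibers: FiberSet,
    peak_rate: float = 30.0,
    base_rate: float = 1.0,
    decay_tau: float = 20.0,
    seed: int = 0,
    nonspecific: bool = False,
    nonspecific_fraction: float = 0.12,
) -> SpikeData:
    """Inhomogeneous-Poisson fiber spike trains for a stimulus stream.

    During a presentation, fibers of the presented pattern fire at
    ``base + (peak - base) * exp(-(t - onset)/tau)``; all other fibers (and
    all fibers outside their pattern's windows) fire at ``base_rate``. In
    ``nonspecific`` mode one fixed random fiber subset is driven at every
    presentation instead (the non-specific-thalamus analogue; pass the halved
    peak rate explicitly).
    """
    if decay_tau <= 0:
        raise ValueError("decay_tau must be positive")
    if not peak_rate > base_rate >= 0:
        raise ValueError("need peak_rate > base_rate >= 0")
    rng = np.random.default_rng(seed)
    n = fibers.n_fibers
    id_to_idx = {fid: i for i, fid in enumerate(fibers.fiber_ids)}

    # homogeneous baseline over the whole recording, all fibers
    lam0 = base_rate * stream.duration / 1000.0
    counts0 = rng.poisson(lam0, size=n)
    base_times = rng.random(int(counts0.sum())) * stream.duration
    base_idx = np.repeat(np.arange(n), counts0)

    if nonspecific:
        k = max(1, int(round(nonspecific_fraction * n)))
        fixed = rng.choice(n, size=k, replace=False)
        driven = {lab: fixed for lab in patterns.labels}
    else:
        driven = {
            lab: np.array([id_to_idx[f] for f in patterns.fibers(lab)], dtype=np.int64)
            for lab in patterns.labels
        }

    all_idx = [base_idx]
    all_times = [base_times]
    for onset, lab in zip(stream.onsets, stream.labels):
        idx = driven[lab]
        loc, t = _evoked_spike_times(
            rng, onset, stream.isi, len(idx), peak_rate, base_rate, decay_tau
        )
        all_idx.append(idx[loc])
        all_times.append(t)
    idx = np.concatenate(all_idx)
    times = np.clip(np.concatenate(all_times), 0.0, stream.duration)
    return SpikeData(fibers.fiber_ids[idx], times, fibers.fiber_ids, stream.duration)


def earth_mover_distance(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """EMD between two uniform-mass point clouds (Euclidean ground distance).

    Equal-size clouds reduce to a minimum-cost perfect matching; unequal
    sizes solve the transportation LP.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    cost = cdist(a, b)
    na, nb = len(a), len(b)
    if na == nb:
        r, c = linear_sum_assignment(cost)
        return float(cost[r, c].sum() / na)
    # transportation problem with masses 1/na and 1/nb
    c_flat = cost.ravel()
    A_eq = []
    b_eq = []
    for i in range(na):
        row = np.zeros(na * nb)
        row[i * nb : (i + 1) * nb] = 1
        A_eq.append(row)
        b_eq.append(1.0 / na)
    for j in range(nb):
        row = np.zeros(na * nb)
        row[j::nb] = 1
        A_eq.append(row)
        b_eq.append(1.0 / nb)
    res = linprog(c_flat, A_eq=np.array(A_eq), b_eq=np.array(b_eq), method="highs")
    if not res.success:
        raise RuntimeError("EMD transportation LP failed")
    return float(res.fun)


def pattern_distances(patterns: PatternSet, fibers: FiberSet):
    """Pairwise pattern distances: fiber-level Hamming and Earth mover.

    Hamming is the symmetric-difference size ``|P1| + |P2| - 2 |P1 ∩ P2|``;
    EMD transports uniform mass between the patterns' fiber flat-map
    locations.
    """
    labels = list(patterns.labels)
    pos = {fid: fibers.positions[i] for i, fid in enumerate(fibers.fiber_ids)}
    sets = {}
    for lab in labels:
        fs = patterns.fibers(lab)
        if len(fs) == 0:
            raise ValueError(f"pattern {lab} is empty")
        sets[lab] = set(int(f) for f in fs)
    k = len(labels)
    ham = np.zeros((k, k))
    emd = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            si, sj = sets[labels[i]], sets[labels[j]]
            ham[i, j] = ham[j, i] = len(si) + len(sj) - 2 * len(si & sj)
            pi = np.array([pos[f] for f in sorted(si)])
            pj = np.array([pos[f] for f in sorted(sj)])
            emd[i, j] = emd[j, i] = earth_mover_distance(pi, pj)
    return pd.DataFrame(ham, index=labels, columns=labels), pd.DataFrame(
        emd, index=labels, columns=labels
    )
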