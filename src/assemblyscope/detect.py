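"""Cell assembly detection from spike trains.

Five steps: (1) bin spikes; (2) select time bins whose population spike
count exceeds a shuffle-derived threshold; (3) build the cosine-similarity
matrix of the significant bins' activation vectors; (4) Ward-cluster the
similarity matrix, choosing the cluster count by minimum Davies-Bouldin
index; (5) associate neurons to each bin cluster by correlating their spike
counts with the cluster's activation sequence against circular-shift
controls, then keep only clusters whose members are more correlated with
each other than the population at large. Time bins (not neurons) are
clustered, so a neuron may belong to several assemblies while each
significant bin carries exactly one assembly label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import davies_bouldin_score

from .containers import BinnedSpikes, SpikeData
from .stimgen import StimulusStream


@dataclass
class SignificantBins:
    indices: np.ndarray  # indices of significant bins
    threshold: float  # spikes per bin
    population_counts: np.ndarray  # per-bin population count, all bins
    shuffle_stds: np.ndarray  # per-shuffle std of shuffled counts

    @property
    def n_sig(self) -> int:
        return int(self.indices.size)


@dataclass
class Assembly:
    id: int
    neurons: np.ndarray
    temporal_class: Optional[str] = None
    median_latency: Optional[float] = None

    def __post_init__(self) -> None:
        self.neurons = np.asarray(self.neurons, dtype=np.int64)
        if self.neurons.size == 0:
            raise ValueError("assembly must be nonempty")


@dataclass
class AssemblyGroup:
    """Detected assemblies plus full provenance of the detection run."""

    assemblies: List[Assembly]
    bin_labels: np.ndarray  # cluster label per significant bin
    sig: SignificantBins
    correlations: np.ndarray  # (n_units, n_clusters)
    thresholds: np.ndarray  # (n_units, n_clusters) pair-specific
    units: np.ndarray
    config: dict = field(default_factory=dict)
    dropped_clusters: List[int] = field(default_factory=list)
    excluded_units: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    @property
    def n_assemblies(self) -> int:
        return len(self.assemblies)

    def membership_matrix(self) -> np.ndarray:
        """(n_units, n_assemblies) binary membership, aligned to ``units``."""
        pos = {u: i for i, u in enumerate(self.units)}
        M = np.zeros((self.units.size, len(self.assemblies)), dtype=np.int8)
        for k, a in enumerate(self.assemblies):
            M[[pos[n] for n in a.neurons], k] = 1
        return M


@dataclass
class DetectConfig:
    bin_size: float = 20.0  # ms
    n_shuffles_bins: int = 100
    n_shuffles_members: int = 1000
    pct: float = 95.0
    n_clusters: Optional[int] = None  # fixed cluster count; None = scan
    n_range: Tuple[int, int] = (5, 20)
    boundaries: Tuple[float, float] = (40.0, 80.0)  # early/middle/late (ms)
    pair_budget: int = 1_000_000
    threshold_mode: str = "std_percentile"  # or "count_percentile"
    binary_activation: bool = False
    seed: int = 0


def bin_spikes(spikes: SpikeData, bin_size: float) -> BinnedSpikes:
    """Count spikes of every unit into half-open ``bin_size`` ms bins.

    A spike exactly at the duration boundary lands in the last bin.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = max(1, int(np.ceil(spikes.duration / bin_size)))
    if spikes.n_spikes == 0:
        warnings.warn("empty SpikeData: returning all-zero matrix")
    unit_pos = {u: i for i, u in enumerate(spikes.units)}
    rows = np.array([unit_pos[u] for u in spikes.unit_ids], dtype=np.int64)
    cols = np.minimum((spikes.times // bin_size).astype(np.int64), n_bins - 1)
    M = np.zeros((spikes.n_units, n_bins))
    np.add.at(M, (rows, cols), 1.0)
    return BinnedSpikes(M, bin_size, 0.0, spikes.units)


def _shuffled_population_counts(matrix: np.ndarray, n_shuffles: int, rng) -> np.ndarray:
    """Population counts per bin under the ±1-bin spike shift null
    (independent fair coin per spike, circular wrap).

    For integer matrices the per-spike coins collapse to binomial splits of
    the per-bin population counts; real-valued (averaged) inputs move each
    unit-bin mass wholly forward or backward instead.
    """
    counts = matrix.sum(axis=0)
    if np.allclose(matrix, np.round(matrix)):
        c = np.round(counts).astype(np.int64)
        fwd = rng.binomial(np.broadcast_to(c, (n_shuffles, c.size)), 0.5)
        bwd = c[None, :] - fwd
        return np.roll(fwd, 1, axis=1) + np.roll(bwd, -1, axis=1)
    out = np.empty((n_shuffles, matrix.shape[1]))
    for s in range(n_shuffles):
        coin = rng.random(matrix.shape) < 0.5
        fwd = np.where(coin, matrix, 0.0)
        bwd = matrix - fwd
        out[s] = (np.roll(fwd, 1, axis=1) + np.roll(bwd, -1, axis=1)).sum(axis=0)
    return out


def find_significant_bins(
    binned: BinnedSpikes,
    n_shuffles: int = 100,
    pct: float = 95.0,
    seed: int = 0,
    threshold_mode: str = "std_percentile",
) -> SignificantBins:
    """Bins whose population count exceeds the shuffle-derived threshold.

    Default rule: threshold = mean population count + ``pct``-th percentile
    of the per-shuffle standard deviations of the shuffled counts. The
    alternative ``count_percentile`` mode thresholds at the ``pct``-th
    percentile of the pooled shuffled per-bin counts.
    """
    if binned.n_bins < 3:
        raise ValueError("need at least 3 bins")
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    counts = binned.matrix.sum(axis=0)
    if not counts.any():
        warnings.warn("all-zero spike matrix: no significant bins")
        return SignificantBins(np.array([], dtype=np.int64), np.inf, counts, np.array([]))
    rng = np.random.default_rng(seed)
    shuffled = _shuffled_population_counts(binned.matrix, n_shuffles, rng)
    stds = shuffled.std(axis=1)
    if threshold_mode == "std_percentile":
        threshold = counts.mean() + np.percentile(stds, pct)
    elif threshold_mode == "count_percentile":
        threshold = np.percentile(shuffled.ravel(), pct)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    idx = np.where(counts > threshold)[0]
    return SignificantBins(idx, float(threshold), counts, stds)


def similarity_matrix(
    binned: BinnedSpikes, sig: SignificantBins, binary: bool = False
) -> np.ndarray:
    """Cosine similarity between the activation vectors of significant bins."""
    if sig.n_sig < 2:
        raise ValueError("need at least 2 significant bins")
    X = binned.matrix[:, sig.indices]
    if binary:
        X = (X > 0).astype(float)
    norms = np.linalg.norm(X, axis=0)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero activation vectors; similarities set to 0")
    norms = np.where(zero, 1.0, norms)
    Xn = X / norms
    S = Xn.T @ Xn
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    np.fill_diagonal(S, 1.0)
    return np.clip(S, -1.0, 1.0)


def cluster_bins(sim: np.ndarray, n_range=(5, 20)):
    """Ward-cluster rows of the similarity matrix; choose the cluster count
    with the lowest Davies-Bouldin index (ties favor fewer clusters).

    ``n_range`` may be an (lo, hi) interval to scan or a fixed integer.
    Returns (labels, chosen_n, {n: DB score}).
    """
    n_bins = sim.shape[0]
    Z = linkage(sim, method="ward")
    if isinstance(n_range, (int, np.integer)):
        labels = fcluster(Z, t=int(n_range), criterion="maxclust") - 1
        return labels, int(n_range), {}
    lo, hi = int(n_range[0]), int(n_range[1])
    if hi >= n_bins:
        warnings.warn("fewer significant bins than cluster range: clamping")
        lo, hi = max(2, min(lo, n_bins - 1)), n_bins - 1
        lo = min(lo, hi)
    scores: Dict[int, float] = {}
    best_n, best = None, np.inf
    for n in range(lo, hi + 1):
        labels = fcluster(Z, t=n, criterion="maxclust") - 1
        if np.unique(labels).size < 2:
            continue
        score = davies_bouldin_score(sim, labels)
        scores[n] = score
        if score < best - 1e-12:
            best, best_n = score, n
    if best_n is None:
        best_n = lo
    labels = fcluster(Z, t=best_n, criterion="maxclust") - 1
    return labels, best_n, scores


def _center_normalize_rows(X: np.ndarray):
    Xc = X - X.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=-1, keepdims=True)
    ok = norms[..., 0] > 0
    norms = np.where(norms == 0, 1.0, norms)
    return Xc / norms, ok


def assign_members(
    binned: BinnedSpikes,
    sig: SignificantBins,
    labels: np.ndarray,
    n_shuffles: int = 1000,
    pct: float = 95.0,
    seed: int = 0,
    chunk: int = 100,
):
    """Candidate members per bin cluster.

    A neuron is a candidate member of cluster ``c`` if the Pearson
    correlation between its spike counts over the significant bins and the
    cluster's binary activation sequence exceeds the ``pct``-th percentile
    of correlations obtained after circularly shifting the neuron's full
    binned spike train by a uniform random offset (pair-specific threshold).

    Returns (candidates: {cluster: unit ids}, correlations, thresholds,
    excluded unit ids).
    """
    rng = np.random.default_rng(seed)
    T = binned.n_bins
    sig_idx = sig.indices
    K = int(labels.max()) + 1
    X = binned.matrix[:, sig_idx]
    Xn, ok = _center_normalize_rows(X)

    ind = np.zeros((sig_idx.size, K))
    ind[np.arange(sig_idx.size), labels] = 1.0
    In, _ = _center_normalize_rows(ind.T)
    In = In.T  # (n_sig, K), centered + normalized columns

    corr = Xn @ In  # (n_units, K)
    corr[~ok] = 0.0

    n_units = binned.n_units
    null = np.empty((n_units, K, n_shuffles))
    done = 0
    M = binned.matrix
    while done < n_shuffles:
        s = min(chunk, n_shuffles - done)
        offsets = rng.integers(0, T, size=(n_units, s))
        cols = (sig_idx[None, None, :] - offsets[:, :, None]) % T
        vals = M[np.arange(n_units)[:, None, None], cols]  # (n_units, s, n_sig)
        Vn, vok = _center_normalize_rows(vals)
        nc = Vn @ In  # (n_units, s, K)
        nc[~vok] = 0.0
        null[:, :, done : done + s] = nc.transpose(0, 2, 1)
        done += s
    thresholds = np.percentile(null, pct, axis=2)

    candidates = {}
    for c in range(K):
        mask = ok & (corr[:, c] > thresholds[:, c])
        candidates[c] = binned.units[mask]
    excluded = binned.units[~ok]
    return candidates, corr, thresholds, excluded


def _population_mean_correlation(Xn, ok, pair_budget, seed) -> float:
    """Mean pairwise Pearson correlation over all (valid) neuron pairs,
    subsampled to at most ``pair_budget`` pairs."""
    idx = np.where(ok)[0]
    n = idx.size
    n_pairs = n * (n - 1) // 2
    if n_pairs <= pair_budget:
        C = Xn[idx] @ Xn[idx].T
        iu = np.triu_indices(n, k=1)
        return float(C[iu].mean())
    rng = np.random.default_rng(seed)
    a = rng.integers(0, n, size=pair_budget)
    b = rng.integers(0, n - 1, size=pair_budget)
    b = np.where(b >= a, b + 1, b)
    return float(np.einsum("ij,ij->i", Xn[idx[a]], Xn[idx[b]]).mean())


def validate_assemblies(
    binned: BinnedSpikes,
    sig: SignificantBins,
    candidates: Dict[int, np.ndarray],
    pair_budget: int = 1_000_000,
    seed: int = 0,
):
    """Keep a candidate cluster iff its members' mean pairwise correlation
    (over significant bins) exceeds the population mean pairwise correlation.

    Guards against a cluster whose "members" are two unrelated co-active
    groups. Returns (assemblies, dropped cluster ids, population mean).
    """
    if not candidates:
        raise ValueError("no candidate clusters")
    X = binned.matrix[:, sig.indices]
    Xn, ok = _center_normalize_rows(X)
    pop_mean = _population_mean_correlation(Xn, ok, pair_budget, seed)
    unit_pos = {u: i for i, u in enumerate(binned.units)}

    assemblies, dropped = [], []
    for c in sorted(candidates):
        members = candidates[c]
        rows = np.array([unit_pos[u] for u in members], dtype=np.int64)
        rows = rows[ok[rows]]
        if rows.size < 2:
            dropped.append(c)
            continue
        C = Xn[rows] @ Xn[rows].T
        iu = np.triu_indices(rows.size, k=1)
        if C[iu].mean() > pop_mean:
            assemblies.append(Assembly(id=c, neurons=binned.units[rows]))
        else:
            dropped.append(c)
    return assemblies, dropped, pop_mean


def temporal_labels(
    assemblies: List[Assembly],
    bin_labels: np.ndarray,
    sig: SignificantBins,
    binned: BinnedSpikes,
    stream: StimulusStream,
    boundaries: Tuple[float, float] = (40.0, 80.0),
) -> List[Assembly]:
    """Label each assembly early/middle/late by the median latency of its
    significant bins relative to the most recent stimulus onset."""
    mids = binned.t0 + (sig.indices + 0.5) * binned.bin_size
    onset_idx = np.searchsorted(stream.onsets, mids, side="right") - 1
    for a in assemblies:
        mask = (bin_labels == a.id) & (onset_idx >= 0)
        if not mask.any():
            a.temporal_class, a.median_latency = None, None
            continue
        lat = mids[mask] - stream.onsets[onset_idx[mask]]
        med = float(np.median(lat))
        a.median_latency = med
        if med < boundaries[0]:
            a.temporal_class = "early"
        elif med < boundaries[1]:
            a.temporal_class = "middle"
        else:
            a.temporal_class = "late"
    return assemblies


def detect(
    spikes: SpikeData, stream: Optional[StimulusStream] = None, config: DetectConfig = None
) -> AssemblyGroup:
    """Run the full five-step detection pipeline."""
    cfg = config or DetectConfig()
    ss = np.random.SeedSequence(cfg.seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]

    binned = bin_spikes(spikes, cfg.bin_size)
    sig = find_significant_bins(
        binned, cfg.n_shuffles_bins, cfg.pct, seeds[0], cfg.threshold_mode
    )
    sim = similarity_matrix(binned, sig, binary=cfg.binary_activation)
    n_arg = cfg.n_clusters if cfg.n_clusters is not None else cfg.n_range
    labels, chosen_n, scores = cluster_bins(sim, n_arg)
    candidates, corr, thr, excluded = assign_members(
        binned, sig, labels, cfg.n_shuffles_members, cfg.pct, seeds[1]
    )
    assemblies, dropped, pop_mean = validate_assemblies(
        binned, sig, candidates, cfg.pair_budget, seeds[2]
    )
    if stream is not None:
        assemblies = temporal_labels(assemblies, labels, sig, binned, stream, cfg.boundaries)

    provenance = asdict(cfg)
    provenance.update(
        chosen_n=int(chosen_n),
        # string keys: survive a JSON round-trip unchanged (resume runs)
        db_scores={str(int(k)): float(v) for k, v in scores.items()},
        population_mean_correlation=pop_mean,
        stage_seeds=seeds,
    )
    return AssemblyGroup(
        assemblies=assemblies,
        bin_labels=labels,
        sig=sig,
        correlations=corr,
        thresholds=thr,
        units=binned.units,
        config=provenance,
        dropped_clusters=dropped,
        excluded_units=excluded,
    )
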