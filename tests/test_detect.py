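import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage

from _oracles import best_match_jaccard, davies_bouldin
from assemblyscope.circuit import default_study
from assemblyscope.containers import BinnedSpikes, SpikeData
from assemblyscope.detect import (
    DetectConfig,
    _shuffled_population_counts,
    assign_members,
    bin_spikes,
    cluster_bins,
    detect,
    find_significant_bins,
    similarity_matrix,
    temporal_labels,
    validate_assemblies,
)

# ---------------------------------------------------------------- binning


def test_bin_spikes_hand_example():
    sd = SpikeData([0, 0, 1, 1], [5.0, 25.0, 25.0, 60.0], units=[0, 1], duration=60.0)
    b = bin_spikes(sd, 20.0)
    assert b.matrix.shape == (2, 3)
    assert np.array_equal(b.matrix, [[1, 1, 0], [0, 1, 1]])  # boundary spike in last bin


def test_bin_spikes_conserves_counts():
    rng = np.random.default_rng(0)
    sd = SpikeData(
        rng.integers(0, 20, 500), rng.random(500) * 1000.0, units=np.arange(20), duration=1000.0
    )
    for bs in (7.0, 20.0, 33.3):
        assert bin_spikes(sd, bs).matrix.sum() == 500


@given(st.integers(0, 10_000), st.sampled_from([10.0, 20.0, 40.0]))
def test_bin_spikes_conservation_property(seed, bs):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 200))
    sd = SpikeData(
        rng.integers(0, 5, n), rng.random(n) * 500.0, units=np.arange(5), duration=500.0
    )
    binned = bin_spikes(sd, bs)
    assert binned.matrix.sum() == n
    assert np.array_equal(binned.matrix.sum(axis=1), np.bincount(sd.unit_ids, minlength=5))


# ---------------------------------------------------------------- shuffles


def test_shuffle_preserves_total_count():
    rng = np.random.default_rng(1)
    M = rng.poisson(1.0, size=(10, 50)).astype(float)
    sh = _shuffled_population_counts(M, 20, rng)
    assert sh.shape == (20, 50)
    assert np.allclose(sh.sum(axis=1), M.sum())


def test_shuffle_real_valued_path():
    rng = np.random.default_rng(2)
    M = rng.random((5, 30))  # non-integer: averaged-raster path
    sh = _shuffled_population_counts(M, 10, rng)
    assert np.allclose(sh.sum(axis=1), M.sum())


# ---------------------------------------------------------------- significant bins


def test_significant_bins_planted():
    rng = np.random.default_rng(3)
    M = rng.poisson(0.2, size=(30, 200)).astype(float)
    planted = [10, 77, 150]
    M[:, planted] += 3.0  # population burst far above the shuffle threshold
    sig = find_significant_bins(BinnedSpikes(M, 20.0, 0.0), seed=0)
    assert set(planted) <= set(sig.indices.tolist())
    assert sig.n_sig <= len(planted) + 8
    assert np.all(sig.population_counts[sig.indices] > sig.threshold)


def test_significant_bins_modes_differ():
    rng = np.random.default_rng(4)
    M = rng.poisson(0.5, size=(20, 300)).astype(float)
    a = find_significant_bins(BinnedSpikes(M, 20.0, 0.0), seed=0, threshold_mode="std_percentile")
    b = find_significant_bins(
        BinnedSpikes(M, 20.0, 0.0), seed=0, threshold_mode="count_percentile"
    )
    assert a.threshold != b.threshold
    with pytest.raises(ValueError):
        find_significant_bins(BinnedSpikes(M, 20.0, 0.0), threshold_mode="nope")


def test_significant_bins_empty_matrix_warns():
    with pytest.warns(UserWarning):
        sig = find_significant_bins(BinnedSpikes(np.zeros((3, 10)), 20.0, 0.0))
    assert sig.n_sig == 0


# ---------------------------------------------------------------- similarity


def test_similarity_hand_example():
    M = np.array([[1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    from assemblyscope.detect import SignificantBins

    sig = SignificantBins(np.array([0, 1]), 0.0, M.sum(axis=0), np.array([]))
    S = similarity_matrix(BinnedSpikes(M, 20.0, 0.0), sig)
    # activation vectors (1,0,1) and (1,1,0): cosine = 1/2
    assert S[0, 1] == pytest.approx(0.5)
    assert np.allclose(np.diag(S), 1.0)
    assert np.allclose(S, S.T)


def test_similarity_binary_flag():
    M = np.array([[3.0, 1.0], [0.0, 1.0], [3.0, 0.0]])
    from assemblyscope.detect import SignificantBins

    sig = SignificantBins(np.array([0, 1]), 0.0, M.sum(axis=0), np.array([]))
    S = similarity_matrix(BinnedSpikes(M, 20.0, 0.0), sig, binary=True)
    assert S[0, 1] == pytest.approx(0.5)  # counts collapse to indicators


# ---------------------------------------------------------------- clustering


def _blob_similarity(seed=0):
    rng = np.random.default_rng(seed)
    centers = np.eye(3).repeat(12, axis=0)
    X = centers + rng.normal(0, 0.05, size=centers.shape)
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
    return Xn @ Xn.T, np.repeat([0, 1, 2], 12)


def test_cluster_bins_recovers_blobs():
    S, truth = _blob_similarity()
    labels, n, scores = cluster_bins(S, (2, 6))
    assert n == 3
    # same partition up to relabeling
    for c in range(3):
        assert np.unique(truth[labels == c]).size == 1


def test_davies_bouldin_matches_oracle():
    S, _ = _blob_similarity(seed=5)
    Z = linkage(S, method="ward")
    _, _, scores = cluster_bins(S, (2, 6))
    for n, score in scores.items():
        labels = fcluster(Z, t=n, criterion="maxclust") - 1
        assert score == pytest.approx(davies_bouldin(S, labels), abs=1e-10)


def test_cluster_bins_fixed_n():
    S, _ = _blob_similarity()
    labels, n, scores = cluster_bins(S, 4)
    assert n == 4 and np.unique(labels).size == 4 and scores == {}


def test_cluster_bins_clamps_range():
    S, _ = _blob_similarity()
    with pytest.warns(UserWarning):
        labels, n, _ = cluster_bins(S[:8, :8], (5, 20))
    assert n < 8


# ---------------------------------------------------------------- members


def _planted_binned(seed=0, n_units=30, n_bins=400):
    """Two planted groups firing in disjoint recurring bins over noise."""
    rng = np.random.default_rng(seed)
    M = rng.poisson(0.05, size=(n_units, n_bins)).astype(float)
    # aperiodic bin placement: a periodic layout would let circular shifts
    # realign the planted activity and inflate the null correlations
    chosen = rng.choice(n_bins, size=40, replace=False)
    bins_a, bins_b = np.sort(chosen[:20]), np.sort(chosen[20:])
    M[np.ix_(range(0, 10), bins_a)] += 1.0
    M[np.ix_(range(10, 20), bins_b)] += 1.0
    sig_idx = np.sort(np.concatenate([bins_a, bins_b]))
    labels = (np.isin(sig_idx, bins_b)).astype(int)
    from assemblyscope.detect import SignificantBins

    binned = BinnedSpikes(M, 20.0, 0.0)
    sig = SignificantBins(sig_idx, 0.0, M.sum(axis=0), np.array([]))
    return binned, sig, labels


def test_assign_members_recovers_planted():
    binned, sig, labels = _planted_binned()
    candidates, corr, thr, excluded = assign_members(binned, sig, labels, 500, seed=0)
    # planted members must all pass; the 95th-percentile rule admits ~5%
    # of unrelated neurons by construction, so allow a few extras
    assert set(range(0, 10)) <= set(candidates[0].tolist())
    assert set(range(10, 20)) <= set(candidates[1].tolist())
    assert len(candidates[0]) <= 15 and len(candidates[1]) <= 15
    assert corr.shape == thr.shape == (30, 2)


def test_validate_drops_incoherent_cluster():
    binned, sig, labels = _planted_binned()
    # cluster 1's "candidates" mix two unrelated co-active groups, the
    # guard case: they anti-correlate across the significant bins
    candidates = {0: np.arange(0, 10), 1: np.arange(5, 15)}
    assemblies, dropped, pop_mean = validate_assemblies(binned, sig, candidates)
    assert [a.id for a in assemblies] == [0]
    assert dropped == [1]
    assert np.isfinite(pop_mean)


# ---------------------------------------------------------------- end to end


def test_detect_recovers_planted_groups(small_study, detected):
    truth = list(small_study.plan.groups.values())
    found = [a.neurons for a in detected.assemblies]
    assert best_match_jaccard(truth, found) >= 0.7


def test_detect_temporal_labels(small_study, detected):
    classes = {a.temporal_class for a in detected.assemblies}
    assert "early" in classes and "late" in classes
    for a in detected.assemblies:
        if a.temporal_class == "early":
            assert a.median_latency < 40.0
        elif a.temporal_class == "late":
            assert a.median_latency >= 80.0


def test_detect_deterministic(small_study, detected):
    again = detect(small_study.spikes, small_study.stream, DetectConfig(seed=0))
    assert again.n_assemblies == detected.n_assemblies
    for a, b in zip(again.assemblies, detected.assemblies):
        assert np.array_equal(a.neurons, b.neurons)
    assert np.array_equal(again.sig.indices, detected.sig.indices)


def test_detect_provenance_recorded(detected):
    cfg = detected.config
    assert cfg["bin_size"] == 20.0
    assert 5 <= cfg["chosen_n"] <= 20
    assert len(cfg["stage_seeds"]) == 3
    assert detected.membership_matrix().shape == (200, detected.n_assemblies)
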