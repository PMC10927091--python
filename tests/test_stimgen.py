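import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import emd_brute
from assemblyscope.stimgen import (
    PATTERN_SCHEME,
    FiberSet,
    PatternSet,
    StimulusStream,
    _split_counts,
    build_patterns,
    cluster_fibers,
    earth_mover_distance,
    generate_fiber_spikes,
    generate_stream,
    pattern_distances,
)


def _fibers(n=120, n_bundles=40, seed=0):
    rng = np.random.default_rng(seed)
    return cluster_fibers(rng.random((n, 2)) * 1000.0, n_bundles, seed=seed)


# ---------------------------------------------------------------- fibers


def test_cluster_fibers_partition():
    fs = _fibers()
    assert fs.n_fibers == 120
    assert fs.n_bundles == 40
    assert np.array_equal(np.unique(fs.bundle_ids), np.arange(40))


def test_cluster_fibers_validation():
    with pytest.raises(ValueError):
        cluster_fibers(np.zeros((5, 3)), 2, 0)
    with pytest.raises(ValueError):
        cluster_fibers(np.full((5, 2), np.nan), 2, 0)
    with pytest.raises(ValueError):
        cluster_fibers(np.zeros((5, 2)), 6, 0)


# ---------------------------------------------------------------- patterns


def test_split_counts():
    assert _split_counts(5, 2) == [3, 2]
    assert _split_counts(6, 3) == [2, 2, 2]
    assert _split_counts(7, 4) == [2, 2, 2, 1]


def test_pattern_pyramid_structure():
    fs = _fibers()
    ps = build_patterns(fs, seed=3)
    s = len(ps.bundles["A"])
    assert s == round(0.12 * fs.n_bundles)
    # bases disjoint
    for a, b in (("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")):
        assert not set(ps.bundles[a]) & set(ps.bundles[b])
    # composites keep size s and draw only from their constituent bases
    for label, parts in PATTERN_SCHEME.items():
        assert len(ps.bundles[label]) == s
        allowed = set().union(*(set(ps.bundles[p]) for p in parts))
        assert set(ps.bundles[label]) <= allowed
        counts = _split_counts(s, len(parts))
        for part, c in zip(parts, counts):
            assert len(set(ps.bundles[label]) & set(ps.bundles[part])) == c
    # fiber sets follow bundle membership
    for label in ps.labels:
        assert set(ps.fibers(label)) == set(fs.fibers_of_bundles(ps.bundles[label]))


def test_pattern_json_roundtrip(tmp_path):
    fs = _fibers()
    ps = build_patterns(fs, seed=3)
    ps.to_json(tmp_path / "p.json")
    back = PatternSet.from_json(tmp_path / "p.json", fs)
    assert back.labels == ps.labels
    for lab in ps.labels:
        assert np.array_equal(np.sort(back.bundles[lab]), np.sort(ps.bundles[lab]))


def test_build_patterns_validation():
    fs = _fibers()
    with pytest.raises(ValueError):
        build_patterns(fs, base_fraction=0.3)
    with pytest.raises(ValueError):
        build_patterns(fs, base_fraction=0.01)


# ---------------------------------------------------------------- streams


def test_stream_counts_and_spacing():
    labels = list("ABCDEFGHIJ")
    stream = generate_stream(labels, 25, isi=500.0, seed=0)
    assert stream.n_events == 250
    assert stream.duration == 125_000.0
    for lab in labels:
        assert np.sum(stream.labels == lab) == 25
    assert np.allclose(np.diff(stream.onsets), 500.0)


def test_stream_block_balance():
    labels = list("ABCDEFGHIJ")
    stream = generate_stream(labels, 24, isi=500.0, block_balanced=True, seed=1)
    block = len(labels) * 6  # 60 events = one 30 s window
    for start in range(0, stream.n_events, block):
        window = stream.labels[start : start + block]
        for lab in labels:
            assert np.sum(window == lab) == 6
    with pytest.raises(ValueError):
        generate_stream(labels, 25, block_balanced=True)


def test_stream_onset_spacing_enforced():
    with pytest.raises(ValueError):
        StimulusStream(np.array([0.0, 400.0]), np.array(["A", "B"]), 1000.0, 500.0)


# ---------------------------------------------------------------- fiber spikes


def test_fiber_spike_counts_match_closed_form():
    fs = _fibers(n=150, n_bundles=40, seed=2)
    ps = build_patterns(fs, seed=2)
    stream = generate_stream(ps.labels, 20, isi=500.0, seed=2)
    spikes = generate_fiber_spikes(stream, ps, fs, peak_rate=30.0, base_rate=1.0, seed=4)
    # expected total = baseline + per-presentation evoked mass
    tau, isi = 20.0, 500.0
    extra = (30.0 - 1.0) * tau * (1.0 - np.exp(-isi / tau)) / 1000.0
    expected = 1.0 * stream.duration / 1000.0 * fs.n_fibers + sum(
        extra * len(ps.fibers(lab)) for lab in stream.labels
    )
    assert abs(spikes.n_spikes - expected) < 4 * np.sqrt(expected)
    assert spikes.times.min() >= 0 and spikes.times.max() <= stream.duration


def test_evoked_times_follow_truncated_exponential():
    fs = _fibers(n=100, n_bundles=40, seed=5)
    ps = build_patterns(fs, seed=5)
    stream = generate_stream(ps.labels, 30, isi=500.0, seed=5)
    spikes = generate_fiber_spikes(stream, ps, fs, peak_rate=60.0, base_rate=0.0, seed=6)
    # with zero baseline every spike is evoked; latencies pool across windows
    lat = spikes.times % 500.0
    tau, isi = 20.0, 500.0
    trunc = 1.0 - np.exp(-isi / tau)
    mean_expected = tau - isi * np.exp(-isi / tau) / trunc
    assert abs(lat.mean() - mean_expected) < 1.0  # ms
    assert np.percentile(lat, 99) < 5 * tau


def test_nonspecific_mode_drives_fixed_subset():
    fs = _fibers(n=100, n_bundles=40, seed=7)
    ps = build_patterns(fs, seed=7)
    stream = generate_stream(ps.labels, 12, isi=500.0, seed=7)
    spikes = generate_fiber_spikes(
        stream, ps, fs, peak_rate=15.0, base_rate=0.0, seed=8, nonspecific=True
    )
    driven = np.unique(spikes.unit_ids)
    assert driven.size == round(0.12 * fs.n_fibers)


def test_fiber_spike_validation():
    fs = _fibers()
    ps = build_patterns(fs, seed=0)
    stream = generate_stream(ps.labels, 6, seed=0)
    with pytest.raises(ValueError):
        generate_fiber_spikes(stream, ps, fs, peak_rate=1.0, base_rate=2.0)
    with pytest.raises(ValueError):
        generate_fiber_spikes(stream, ps, fs, decay_tau=0.0)


# ---------------------------------------------------------------- distances


def test_emd_trivial_cases():
    a = np.array([[0.0, 0.0], [1.0, 0.0]])
    assert earth_mover_distance(a, a) == pytest.approx(0.0)
    b = a + [0.0, 2.0]
    assert earth_mover_distance(a, b) == pytest.approx(2.0)


def test_emd_matches_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(5):
        a = rng.random((3, 2))
        b = rng.random((3, 2))
        assert earth_mover_distance(a, b) == pytest.approx(emd_brute(a, b), abs=1e-9)


def test_emd_unequal_sizes():
    a = np.array([[0.0, 0.0]])
    b = np.array([[1.0, 0.0], [3.0, 0.0]])
    # half the mass moves 1, half moves 3
    assert earth_mover_distance(a, b) == pytest.approx(2.0, abs=1e-6)


def test_pattern_distances_tables():
    fs = _fibers()
    ps = build_patterns(fs, seed=1)
    ham, emd = pattern_distances(ps, fs)
    assert np.allclose(np.diag(ham), 0) and np.allclose(np.diag(emd), 0)
    assert np.allclose(ham, ham.T) and np.allclose(emd, emd.T)
    a, e = set(ps.fibers("A")), set(ps.fibers("E"))
    assert ham.loc["A", "E"] == len(a) + len(e) - 2 * len(a & e)
    # disjoint bases are farther apart than a base and its composite
    assert ham.loc["A", "B"] == len(ps.fibers("A")) + len(ps.fibers("B"))


@given(st.integers(1, 30), st.integers(1, 8))
def test_split_counts_property(total, k):
    parts = _split_counts(total, k)
    assert sum(parts) == total and len(parts) == k
    assert max(parts) - min(parts) <= 1
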