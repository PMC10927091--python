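import json

import numpy as np
import pytest

from assemblyscope.circuit import (
    AssemblyPlan,
    default_plan,
    generate_connectome,
    generate_network_spikes,
    generate_tc_innervation,
)
from assemblyscope.detect import DetectConfig, SignificantBins, detect
from assemblyscope.stimgen import FiberSet, PatternSet, StimulusStream, generate_stream
from assemblyscope.structure import k_indegree
from assemblyscope.workflow import (
    PipelineConfig,
    feature_membership_report,
    input_output_map,
    ni_matrix,
    run_pipeline,
)

# ---------------------------------------------------------------- config


def test_config_yaml_roundtrip(tmp_path):
    cfg = PipelineConfig(seed=7, bin_size=10.0, n_repetitions=3)
    cfg.to_yaml(tmp_path / "c.yaml")
    back = PipelineConfig.from_yaml(tmp_path / "c.yaml")
    assert back == cfg


def test_config_rejects_unknown_keys(tmp_path):
    (tmp_path / "c.yaml").write_text("seed: 1\nnot_a_knob: 2\n")
    with pytest.raises(ValueError):
        PipelineConfig.from_yaml(tmp_path / "c.yaml")


def test_config_defaults_are_canonical():
    cfg = PipelineConfig()
    assert cfg.bin_size == 20.0
    assert cfg.n_shuffles_bins == 100 and cfg.n_shuffles_members == 1000
    assert cfg.pct == 95.0 and cfg.n_range == (5, 20)
    assert cfg.n_feature_bins == 21 and cfg.ni_controls == 100
    assert cfg.scc_controls == 20 and cfg.scc_alpha == 0.05
    assert cfg.coreness_threshold == 4.0
    assert cfg.reliability_bin == 1.0 and cfg.reliability_kernel_sd == 10.0
    assert cfg.isi == 500.0 and cfg.peak_rate == 30.0 and cfg.nonspecific_rate == 15.0


# ---------------------------------------------------------------- io map


def _fake_group(bin_labels, sig_indices, n_units=10):
    from assemblyscope.detect import Assembly, AssemblyGroup

    sig = SignificantBins(np.asarray(sig_indices), 0.0, np.zeros(100), np.array([]))
    return AssemblyGroup(
        assemblies=[Assembly(0, [0])],
        bin_labels=np.asarray(bin_labels),
        sig=sig,
        correlations=np.zeros((n_units, 2)),
        thresholds=np.zeros((n_units, 2)),
        units=np.arange(n_units),
        config={"bin_size": 20.0},
    )


def _two_pattern_setup():
    pos = np.array([[0.0, 0.0], [10.0, 0.0], [500.0, 0.0], [510.0, 0.0]])
    fibers = FiberSet(np.arange(4), pos, np.array([0, 0, 1, 1]))
    bundles = {"A": np.array([0]), "B": np.array([1])}
    fsets = {k: fibers.fibers_of_bundles(v) for k, v in bundles.items()}
    patterns = PatternSet(["A", "B"], bundles, fsets, base_labels=("A", "B"))
    stream = StimulusStream(
        np.arange(4) * 500.0, np.array(["A", "B", "A", "B"]), 2000.0, 500.0
    )
    return fibers, patterns, stream


def test_io_map_identical_outputs_zero_distance():
    fibers, patterns, stream = _two_pattern_setup()
    # one significant bin per presentation, all in cluster 0 -> identical vectors
    sig_idx = (stream.onsets / 20.0).astype(int) + 1
    group = _fake_group([0, 0, 0, 0], sig_idx)
    df, fit = input_output_map(patterns, fibers, group, group.sig, stream)
    assert df["output_dist"].iloc[0] == pytest.approx(0.0)


def test_io_map_orthogonal_outputs_sqrt2():
    fibers, patterns, stream = _two_pattern_setup()
    sig_idx = (stream.onsets / 20.0).astype(int) + 1
    # pattern A bins in cluster 0, pattern B bins in cluster 1
    group = _fake_group([0, 1, 0, 1], sig_idx)
    df, fit = input_output_map(patterns, fibers, group, group.sig, stream)
    assert df["output_dist"].iloc[0] == pytest.approx(np.sqrt(2.0))


def test_io_map_planted_slope_positive():
    # PA and PB share nearby fibers and drive the same group; PC and PD sit
    # far away and drive their own groups -> input EMD predicts output distance
    for seed in (0, 1):
        rng = np.random.default_rng(seed)
        corners = np.array([[0, 0], [1000, 0], [0, 1000], [1000, 1000]], float)
        pos = np.concatenate([c + rng.normal(0, 30, size=(40, 2)) for c in corners])
        fibers = FiberSet(np.arange(160), pos, np.repeat(np.arange(8), 20))
        bsets = {
            "PA": np.array([0]),
            "PB": np.array([1]),
            "PC": np.array([2, 3]),
            "PD": np.array([4, 5]),
        }
        fsets = {k: np.sort(fibers.fibers_of_bundles(v)) for k, v in bsets.items()}
        patterns = PatternSet(list(bsets), bsets, fsets, base_labels=tuple(bsets))
        groups = {0: np.arange(0, 40), 1: np.arange(40, 80), 2: np.arange(80, 120)}
        schedule = {
            "PA": [(0, (10.0, 30.0))],
            "PB": [(0, (10.0, 30.0))],
            "PC": [(1, (10.0, 30.0))],
            "PD": [(2, (10.0, 30.0))],
        }
        plan = AssemblyPlan(groups, {0: "early", 1: "early", 2: "early"}, schedule, 0.8, 0.5)
        stream = generate_stream(list(bsets), 12, seed=seed)
        spikes = generate_network_spikes(plan, stream, 120, seed=seed + 50)
        group = detect(spikes, stream, DetectConfig(seed=seed))
        df, fit = input_output_map(patterns, fibers, group, group.sig, stream)
        assert fit is not None and fit.slope > 0
        assert fit.pvalue < 0.05


# ---------------------------------------------------------------- nI matrices


def test_ni_matrix_membership_indicator_diagonal_one():
    rng = np.random.default_rng(0)
    memberships = {}
    features = {}
    for a in range(3):
        y = np.zeros(600, dtype=int)
        y[rng.choice(600, 120, replace=False)] = 1
        memberships[a] = y
        features[a] = y.astype(float)
    M, results = ni_matrix(features, memberships, seed=0)
    assert np.allclose(np.abs(np.diag(M.values)), 1.0, atol=1e-9)


def test_ni_matrix_pooled_mode():
    rng = np.random.default_rng(1)
    y = np.zeros(600, dtype=int)
    y[rng.choice(600, 120, replace=False)] = 1
    features = {"f": y + rng.normal(0, 0.1, 600)}
    memberships = {"a": y}
    M, results = ni_matrix(features, memberships, pooled=True, seed=0)
    assert M.loc["f", "a"] > 0.5
    # zeros exactly where significance failed
    for (s, t), r in results.items():
        assert (M.loc[s, t] == 0.0) == (not r.significant)


def test_feature_membership_report_planted(small_study):
    plan = small_study.plan
    conn = generate_connectome(200, plan, seed=3)
    innerv = generate_tc_innervation(
        small_study.fibers, small_study.patterns, plan, n_neurons=200, seed=4
    )
    assemblies = {g: plan.groups[g] for g in sorted(plan.groups)}
    out = feature_membership_report(
        assemblies, conn=conn, innerv=innerv, patterns=small_study.patterns, seed=0
    )
    M0 = out["0-indegree"][0]
    assert np.all(np.diag(M0.values) > 0)
    assert "common_tc_indegree" in out and "pattern_indegree" in out


def test_feature_membership_report_scc_conditional(small_study):
    from assemblyscope.structure import FeatureVector

    plan = small_study.plan
    conn = generate_connectome(200, plan, seed=5)
    rng = np.random.default_rng(6)
    assemblies = {0: plan.groups[0]}
    scc_values = {
        0: FeatureVector(rng.normal(size=200), np.arange(200), name="scc")
    }
    out = feature_membership_report(assemblies, conn=conn, scc_values=scc_values, seed=0)
    assert "scc" in out and "scc_given_0indegree" in out


# ---------------------------------------------------------------- pipeline


@pytest.fixture(scope="module")
def pipeline_runs(tmp_path_factory):
    cfg = PipelineConfig(seed=3, reps_per_pattern=6, n_repetitions=2, ni_controls=25)
    out1 = tmp_path_factory.mktemp("run1")
    out2 = tmp_path_factory.mktemp("run2")
    r1 = run_pipeline(cfg, out1)
    r2 = run_pipeline(cfg, out2)
    return cfg, out1, out2, r1, r2


def test_run_pipeline_artifacts(pipeline_runs):
    _, out1, _, r1, _ = pipeline_runs
    for sub in ("stimuli", "circuit", "spikes", "assemblies", "features", "report"):
        assert (out1 / sub).is_dir()
    assert (out1 / "report" / "summary.json").exists()
    assert (out1 / "assemblies" / "consensus.h5").exists()
    assert r1["n_assemblies"] > 0
    assert r1["n_consensus_assemblies"] > 0


def test_run_pipeline_deterministic(pipeline_runs):
    _, out1, out2, _, _ = pipeline_runs
    s1 = (out1 / "report" / "summary.json").read_bytes()
    s2 = (out2 / "report" / "summary.json").read_bytes()
    assert s1 == s2


def test_run_pipeline_resume(pipeline_runs):
    cfg, out1, _, r1, _ = pipeline_runs
    r3 = run_pipeline(cfg, out1, resume=True)
    assert json.dumps(r1, default=float, sort_keys=True) == json.dumps(
        r3, default=float, sort_keys=True
    )
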