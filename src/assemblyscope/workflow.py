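"""Orchestration: configuration-driven end-to-end runs, the stimulus
input → assembly output map, and the feature-vs-membership nI report."""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.stats import linregress

from . import io as asio
from .circuit import (
    AssemblyPlan,
    default_plan,
    default_study,
    generate_connectome,
    generate_tc_innervation,
    generate_network_spikes,
)
from .consensus import (
    AssemblyInstance,
    cluster_instances,
    core,
    coreness,
    spike_time_reliability,
)
from .detect import AssemblyGroup, DetectConfig, SignificantBins, detect
from .infostats import NIResult, bin_feature, conditional_normalized_mi, normalized_mi
from .stimgen import FiberSet, PatternSet, StimulusStream, earth_mover_distance
from .structure import FeatureVector, common_tc_indegree, k_indegree, pattern_indegree


@dataclass
class PipelineConfig:
    """All stage parameters with their canonical defaults.

    Defaults follow the reference protocol: 20 ms bins, 100/1000 shuffle
    controls at the 95th percentile, 5-20 cluster scan, 21 feature bins
    between the 1st and 99th percentiles, 20 SCC controls at alpha 0.05,
    coreness threshold 4, reliability at 1 ms bins with a 10 ms kernel, and
    500 ms inter-stimulus intervals with 30/1 Hz specific (15 Hz
    non-specific) fiber rates.
    """

    seed: int = 0
    # synthetic study
    n_neurons: int = 200
    reps_per_pattern: int = 20
    isi: float = 500.0
    participation_p: float = 0.8
    background_rate: float = 0.5
    p_within: float = 0.15
    p_between: float = 0.02
    p_aligned: float = 0.3
    p_baseline: float = 0.02
    peak_rate: float = 30.0
    base_rate: float = 1.0
    nonspecific_rate: float = 15.0
    # detection
    bin_size: float = 20.0
    n_shuffles_bins: int = 100
    n_shuffles_members: int = 1000
    pct: float = 95.0
    n_clusters: Optional[int] = None
    n_range: Tuple[int, int] = (5, 20)
    boundaries: Tuple[float, float] = (40.0, 80.0)
    # information statistics
    n_feature_bins: int = 21
    ni_controls: int = 100
    ni_pooled: bool = False
    # SCC
    scc_controls: int = 20
    scc_alpha: float = 0.05
    # consensus / reliability
    n_repetitions: int = 1
    coreness_threshold: float = 4.0
    reliability_bin: float = 1.0
    reliability_kernel_sd: float = 10.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("n_range", "boundaries"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["n_range"] = list(d["n_range"])
        d["boundaries"] = list(d["boundaries"])
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=True)

    def detect_config(self, seed: Optional[int] = None) -> DetectConfig:
        return DetectConfig(
            bin_size=self.bin_size,
            n_shuffles_bins=self.n_shuffles_bins,
            n_shuffles_members=self.n_shuffles_members,
            pct=self.pct,
            n_clusters=self.n_clusters,
            n_range=self.n_range,
            boundaries=self.boundaries,
            seed=self.seed if seed is None else seed,
        )


def input_output_map(
    patterns: PatternSet,
    fibers: FiberSet,
    group: AssemblyGroup,
    sig: SignificantBins,
    stream: StimulusStream,
    bin_size: Optional[float] = None,
):
    """Does stimulus similarity predict response similarity?

    Input distance between two patterns is the Earth-mover distance of their
    fiber flat-map locations. The output of a pattern is the vector counting
    its evoked significant bins per assembly cluster; the output distance is
    the Euclidean distance between the L2-normalized count vectors. Returns
    (pairs DataFrame, linregress result over all included pairs).
    """
    if bin_size is None:
        bin_size = float(group.config.get("bin_size", 20.0))
    mids = (sig.indices + 0.5) * bin_size
    onset_idx = np.searchsorted(stream.onsets, mids, side="right") - 1
    K = int(group.bin_labels.max()) + 1

    pos = {fid: i for i, fid in enumerate(fibers.fiber_ids)}
    out_vec: Dict[object, np.ndarray] = {}
    for lab in patterns.labels:
        v = np.zeros(K)
        in_pattern = np.array(
            [i >= 0 and stream.labels[i] == lab for i in onset_idx], dtype=bool
        )
        for c, n in zip(group.bin_labels[in_pattern], np.ones(int(in_pattern.sum()))):
            v[c] += n
        out_vec[lab] = v

    rows = []
    labels = list(patterns.labels)
    excluded = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            va, vb = out_vec[a], out_vec[b]
            if np.linalg.norm(va) == 0 or np.linalg.norm(vb) == 0:
                excluded.append((a, b))
                continue
            out_d = float(
                np.linalg.norm(va / np.linalg.norm(va) - vb / np.linalg.norm(vb))
            )
            pa = fibers.positions[[pos[f] for f in patterns.fibers(a)]]
            pb = fibers.positions[[pos[f] for f in patterns.fibers(b)]]
            rows.append(
                {"a": a, "b": b, "input_emd": earth_mover_distance(pa, pb), "output_dist": out_d}
            )
    if excluded:
        warnings.warn(f"{len(excluded)} pattern pairs excluded (no significant bins)")
    df = pd.DataFrame(rows)
    fit = linregress(df["input_emd"], df["output_dist"]) if len(df) >= 3 else None
    return df, fit


def ni_matrix(
    features: Dict[object, FeatureVector],
    memberships: Dict[object, np.ndarray],
    n_bins: int = 21,
    n_controls: int = 100,
    pooled: bool = False,
    seed: int = 0,
):
    """nI for every (feature source, target assembly) pair.

    ``pooled=True`` reproduces the matrix-wide scheme: one membership
    shuffle per pair, thresholded at mean + 1 std over all pairs' controls;
    otherwise each pair gets its own ``n_controls``-permutation threshold.
    Returns (nI DataFrame, {pair: NIResult}).
    """
    src = list(features)
    tgt = list(memberships)
    results: Dict[tuple, NIResult] = {}
    if not pooled:
        M = np.zeros((len(src), len(tgt)))
        for i, s in enumerate(src):
            xb = bin_feature(features[s], n_bins)
            for j, t in enumerate(tgt):
                r = normalized_mi(
                    features[s], memberships[t], n_bins, n_controls,
                    seed=seed + 977 * i + j, xb=xb,
                )
                results[(s, t)] = r
                M[i, j] = r.ni
        return pd.DataFrame(M, index=src, columns=tgt), results

    # pooled: compute raws and one shuffle per pair, common threshold
    from .infostats import _entropy_bits, _plugin_mi_bits, _weighted_slope

    rng = np.random.default_rng(seed)
    raws = np.zeros((len(src), len(tgt)))
    shuf = np.zeros_like(raws)
    binned = {s: bin_feature(features[s], n_bins) for s in src}
    for i, s in enumerate(src):
        xb = binned[s]
        n_codes = int(xb.codes.max()) + 1
        for j, t in enumerate(tgt):
            y = np.asarray(memberships[t], dtype=np.int64)
            raws[i, j] = _plugin_mi_bits(xb.codes, y, n_codes)
            shuf[i, j] = _plugin_mi_bits(xb.codes, rng.permutation(y), n_codes)
    threshold = float(shuf.mean() + shuf.std(ddof=0))
    M = np.zeros_like(raws)
    for i, s in enumerate(src):
        xb = binned[s]
        for j, t in enumerate(tgt):
            y = np.asarray(memberships[t], dtype=np.int64)
            H = _entropy_bits(y)
            if raws[i, j] > threshold and H > 0 and not xb.degenerate:
                slope = _weighted_slope(xb, y)
                sign = -1.0 if slope < 0 else 1.0
                ni = sign * raws[i, j] / H
                results[(s, t)] = NIResult(ni, raws[i, j], H, threshold, slope, True, xb.edges)
            else:
                ni = 0.0
                results[(s, t)] = NIResult(0.0, raws[i, j], H, threshold, 0.0, False, xb.edges)
            M[i, j] = ni
    return pd.DataFrame(M, index=src, columns=tgt), results


def feature_membership_report(
    assemblies: Dict[object, np.ndarray],
    conn=None,
    innerv=None,
    patterns: Optional[PatternSet] = None,
    scc_values: Optional[Dict[object, FeatureVector]] = None,
    registry: Optional[np.ndarray] = None,
    n_bins: int = 21,
    n_controls: int = 100,
    pooled: bool = False,
    seed: int = 0,
    k_values: Tuple[int, ...] = (0,),
):
    """nI summary matrices of connectivity features vs assembly membership.

    ``assemblies`` maps assembly id -> member neuron ids. Computes, where
    the corresponding substrate is given: k-indegree (per k), mean common
    thalamic indegree, pattern indegree, SCC, and the conditional nI of SCC
    given 0-indegree. Returns {matrix name: (DataFrame, results dict)}.
    """
    if registry is None:
        if conn is not None:
            registry = conn.neuron_ids
        elif innerv is not None:
            registry = innerv.neuron_ids
        else:
            raise ValueError("a neuron registry is required")
    memberships = {
        a: np.isin(registry, members).astype(np.int64) for a, members in assemblies.items()
    }
    out = {}
    indeg0: Dict[object, FeatureVector] = {}
    if conn is not None:
        for k in k_values:
            feats = {a: k_indegree(conn, assemblies[a], k) for a in assemblies}
            if k == 0:
                indeg0 = feats
            out[f"{k}-indegree"] = ni_matrix(feats, memberships, n_bins, n_controls, pooled, seed)
    if innerv is not None:
        feats = {a: common_tc_indegree(innerv, assemblies[a]) for a in assemblies}
        out["common_tc_indegree"] = ni_matrix(
            feats, memberships, n_bins, n_controls, pooled, seed + 1
        )
        if patterns is not None:
            pfeats = {
                lab: pattern_indegree(innerv, patterns.fibers(lab)) for lab in patterns.labels
            }
            out["pattern_indegree"] = ni_matrix(
                pfeats, memberships, n_bins, n_controls, pooled, seed + 2
            )
    if scc_values is not None:
        out["scc"] = ni_matrix(scc_values, memberships, n_bins, n_controls, pooled, seed + 3)
        if indeg0:
            cond = {}
            for a in scc_values:
                if a not in indeg0:
                    continue
                r = conditional_normalized_mi(
                    scc_values[a], memberships[a], indeg0[a], n_bins, n_controls, seed + 4
                )
                cond[a] = r
            out["scc_given_0indegree"] = (
                pd.DataFrame(
                    {a: [cond[a].ni] for a in cond}, index=["conditional_nI"]
                ).T,
                cond,
            )
    return out


def _stage_done(path: Path) -> bool:
    return path.exists()


def run_pipeline(config: PipelineConfig, out_dir, resume: bool = False) -> dict:
    """End-to-end run on the default planted study: stimuli → circuit →
    spikes → detection → features → nI → (consensus + reliability if
    ``n_repetitions > 1``) → report. Deterministic for a fixed config."""
    out = Path(out_dir)
    for sub in ("stimuli", "circuit", "spikes", "assemblies", "features", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    ss = np.random.SeedSequence(config.seed).spawn(6)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]

    plan = default_plan(
        n_neurons=config.n_neurons,
        participation_p=config.participation_p,
        background_rate=config.background_rate,
    )
    study = default_study(
        seeds[0],
        n_neurons=config.n_neurons,
        reps_per_pattern=config.reps_per_pattern,
        isi=config.isi,
        plan=plan,
    )
    study.fibers.to_tsv(out / "stimuli" / "fibers.tsv")
    study.patterns.to_json(out / "stimuli" / "patterns.json")
    study.stream.to_tsv(out / "stimuli" / "stream.tsv")
    study.spikes.to_tsv(out / "spikes" / "network_spikes.tsv")

    conn = generate_connectome(
        config.n_neurons, plan, config.p_within, config.p_between, seed=seeds[1]
    )
    innerv = generate_tc_innervation(
        study.fibers, study.patterns, plan,
        config.p_aligned, config.p_baseline, config.n_neurons, seed=seeds[2],
    )
    conn.save(out / "circuit" / "connectome.mtx", out / "circuit" / "neurons.tsv")
    innerv.save(out / "circuit" / "innervation.mtx", out / "circuit" / "fibers.tsv")

    group_path = out / "assemblies" / "assemblies.h5"
    if resume and _stage_done(group_path):
        group = asio.load_assembly_group(group_path)
    else:
        group = detect(study.spikes, study.stream, config.detect_config(seeds[3]))
        asio.save_assembly_group(group, group_path)

    assemblies = {a.id: a.neurons for a in group.assemblies}
    report = {"config_seed": config.seed, "n_assemblies": group.n_assemblies}
    if assemblies:
        matrices = feature_membership_report(
            assemblies,
            conn=conn,
            innerv=innerv,
            patterns=study.patterns,
            n_bins=config.n_feature_bins,
            n_controls=config.ni_controls,
            pooled=config.ni_pooled,
            seed=seeds[4],
        )
        for name, (df, _) in matrices.items():
            df.to_csv(out / "features" / f"nI_{name}.tsv", sep="\t")
        report["ni_matrices"] = {
            name: df.to_dict() for name, (df, _) in matrices.items()
        }
        io_df, fit = input_output_map(
            study.patterns, study.fibers, group, group.sig, study.stream, config.bin_size
        )
        io_df.to_csv(out / "report" / "input_output_map.tsv", sep="\t", index=False)
        if fit is not None:
            report["input_output_fit"] = {
                "slope": fit.slope, "r": fit.rvalue, "p": fit.pvalue
            }

    if config.n_repetitions > 1:
        instances, reps_spikes = [], []
        for r in range(config.n_repetitions):
            sp = generate_network_spikes(
                plan, study.stream, config.n_neurons, seed=seeds[5] + r
            )
            reps_spikes.append(sp)
            g = detect(sp, study.stream, config.detect_config(seeds[3] + r))
            for a in g.assemblies:
                instances.append(AssemblyInstance(a.neurons, repetition=r))
        cas = cluster_instances(instances)
        for ca in cas:
            coreness(ca)
            core(ca, config.coreness_threshold)
        asio.save_consensus(cas, out / "assemblies" / "consensus.h5")
        rel = spike_time_reliability(
            reps_spikes, config.reliability_bin, config.reliability_kernel_sd
        )
        asio.save_reliability(rel, out / "report" / "reliability.tsv")
        report["n_consensus_assemblies"] = len(cas)

    report["assembly_summary"] = asio.assembly_group_summary(group)
    with open(out / "report" / "summary.json", "w") as f:
        json.dump(report, f, indent=1, default=float, sort_keys=True)
    return report
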