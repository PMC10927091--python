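"""Consensus assemblies across repetitions, coreness, and the relation
between spike-time reliability and coreness under graded participation."""

from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

from assemblyscope import io as asio
from assemblyscope.circuit import default_plan, default_study, generate_network_spikes
from assemblyscope.consensus import (
    AssemblyInstance,
    cluster_instances,
    core,
    coreness,
    spike_time_reliability,
)
from assemblyscope.detect import DetectConfig, detect

SEED = 0
N_REPETITIONS = 5
OUT = Path(__file__).resolve().parent.parent / "results" / "06_consensus"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    plan = default_plan()
    members = np.unique(np.concatenate(list(plan.groups.values())))
    plan.participation_overrides = {
        int(m): float(rng.uniform(0.15, 0.95)) for m in members
    }
    study = default_study(seed=SEED, reps_per_pattern=10, plan=plan)

    instances, reps = [], []
    for r in range(N_REPETITIONS):
        spikes = generate_network_spikes(plan, study.stream, 200, seed=SEED + 31 * (r + 1))
        reps.append(spikes)
        g = detect(spikes, study.stream, DetectConfig(seed=SEED + r))
        for a in g.assemblies:
            instances.append(AssemblyInstance(a.neurons, r))

    cas = cluster_instances(instances)
    for ca in cas:
        coreness(ca)
        core(ca)
    asio.save_consensus(cas, OUT / "consensus.h5")
    rel = spike_time_reliability(reps)
    asio.save_reliability(rel, OUT / "reliability.tsv")

    print(f"instances: {len(instances)} over {N_REPETITIONS} repetitions")
    print(f"consensus assemblies: {len(cas)}")
    for k, ca in enumerate(cas):
        print(
            f"  consensus {k}: {ca.n_instances} instances, union {ca.union.size}, "
            f"core {ca.core.size}"
        )
    cor = np.zeros(200)
    for ca in cas:
        for n, v in zip(ca.union, ca.coreness):
            cor[n] = max(cor[n], v)
    ok = np.isfinite(rel.values)
    res = spearmanr(cor[ok], rel.values[ok])
    print(f"reliability vs coreness: Spearman rho {res.statistic:.3f}, p {res.pvalue:.2e}")


if __name__ == "__main__":
    main()
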