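"""Structural features of the detected assemblies and their nI with
membership: simplex counts vs matched controls, k-indegree, common thalamic
indegree and pattern indegree."""

from pathlib import Path

import numpy as np

from assemblyscope import io as asio
from assemblyscope.circuit import default_plan, default_study, generate_connectome, generate_tc_innervation
from assemblyscope.structure import control_simplex_counts, simplex_counts
from assemblyscope.workflow import feature_membership_report

SEED = 0
ASSEMBLIES = Path(__file__).resolve().parent.parent / "results" / "03_assemblies" / "assemblies.h5"
OUT = Path(__file__).resolve().parent.parent / "results" / "04_features"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    plan = default_plan()
    study = default_study(seed=SEED, plan=plan)
    conn = generate_connectome(200, plan, seed=SEED + 1)
    innerv = generate_tc_innervation(
        study.fibers, study.patterns, plan, n_neurons=200, seed=SEED + 2
    )
    group = asio.load_assembly_group(ASSEMBLIES)
    assemblies = {a.id: a.neurons for a in group.assemblies}

    a0 = group.assemblies[0]
    sc = simplex_counts(conn, a0.neurons, max_dim=3)
    controls = control_simplex_counts(conn, a0.neurons, n_controls=20, seed=SEED, max_dim=3)
    ctrl = np.array([c.counts for c in controls])
    print(f"assembly {a0.id} (n={a0.neurons.size}) simplex counts: {sc.counts.tolist()}")
    print(f"matched-control mean:            {ctrl.mean(axis=0).round(1).tolist()}")

    out = feature_membership_report(
        assemblies,
        conn=conn,
        innerv=innerv,
        patterns=study.patterns,
        seed=SEED,
        k_values=(0, 1),
    )
    for name, (df, _) in out.items():
        df.to_csv(OUT / f"nI_{name}.tsv", sep="\t")
        print(f"nI[{name}] diagonal: {np.round(np.diag(df.values), 3).tolist()}")


if __name__ == "__main__":
    main()
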