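"""Generate the default planted study: stimulus stream, network spikes,
connectome with elevated within-group connectivity, and pattern-aligned
thalamo-cortical innervation."""

from pathlib import Path

from assemblyscope.circuit import (
    default_plan,
    default_study,
    generate_connectome,
    generate_tc_innervation,
)

SEED = 0
OUT = Path(__file__).resolve().parent.parent / "results" / "02_circuit"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    plan = default_plan()
    study = default_study(seed=SEED, plan=plan)
    conn = generate_connectome(200, plan, seed=SEED + 1)
    innerv = generate_tc_innervation(
        study.fibers, study.patterns, plan, n_neurons=200, seed=SEED + 2
    )

    study.fibers.to_tsv(OUT / "fibers.tsv")
    study.stream.to_tsv(OUT / "stream.tsv")
    study.spikes.to_tsv(OUT / "network_spikes.tsv")
    conn.save(OUT / "connectome.mtx", OUT / "neurons.tsv")
    innerv.save(OUT / "innervation.mtx", OUT / "tc_fibers.tsv")

    density = conn.adj.nnz / (200 * 199)
    print(f"groups: {[len(m) for m in plan.groups.values()]}")
    print(f"stream: {study.stream.n_events} events, {study.stream.duration / 1000:.0f} s")
    print(f"network spikes: {study.spikes.n_spikes}")
    print(f"connectome density: {density:.4f}")
    print(f"innervation synapses: {innerv.matrix.nnz}")


if __name__ == "__main__":
    main()
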