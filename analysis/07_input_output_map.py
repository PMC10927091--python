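"""Input-output map: does the Earth-mover distance between the fiber
locations of two input patterns predict the distance between their evoked
assembly responses?"""

from pathlib import Path

import numpy as np

from assemblyscope.circuit import AssemblyPlan, generate_network_spikes
from assemblyscope.detect import DetectConfig, detect
from assemblyscope.stimgen import FiberSet, PatternSet, generate_stream
from assemblyscope.workflow import input_output_map

SEED = 0
OUT = Path(__file__).resolve().parent.parent / "results" / "07_io_map"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    # two nearby patterns (PA, PB) drive one shared group; two distant
    # patterns drive their own groups
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
    plan = AssemblyPlan(
        {0: np.arange(0, 40), 1: np.arange(40, 80), 2: np.arange(80, 120)},
        {0: "early", 1: "early", 2: "early"},
        {
            "PA": [(0, (10.0, 30.0))],
            "PB": [(0, (10.0, 30.0))],
            "PC": [(1, (10.0, 30.0))],
            "PD": [(2, (10.0, 30.0))],
        },
        0.8,
        0.5,
    )
    stream = generate_stream(list(bsets), 12, seed=SEED)
    spikes = generate_network_spikes(plan, stream, 120, seed=SEED + 50)
    group = detect(spikes, stream, DetectConfig(seed=SEED))
    df, fit = input_output_map(patterns, fibers, group, group.sig, stream)
    df.to_csv(OUT / "pairs.tsv", sep="\t", index=False)

    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(
        f"fit: slope {fit.slope:.5f}, Pearson r {fit.rvalue:.3f}, p {fit.pvalue:.4f}"
    )


if __name__ == "__main__":
    main()
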