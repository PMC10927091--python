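"""Build the thalamic input side: fiber bundles, the ten-pattern overlap
pyramid, a block-balanced stimulus stream, and evoked fiber spike trains."""

from pathlib import Path

import numpy as np

from assemblyscope.stimgen import (
    build_patterns,
    cluster_fibers,
    generate_fiber_spikes,
    generate_stream,
    pattern_distances,
)

SEED = 0
OUT = Path(__file__).resolve().parent.parent / "results" / "01_stimuli"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    fibers = cluster_fibers(rng.random((300, 2)) * 1000.0, 100, seed=SEED)
    patterns = build_patterns(fibers, seed=SEED)
    stream = generate_stream(
        patterns.labels, 24, isi=500.0, block_balanced=True, seed=SEED
    )
    spikes = generate_fiber_spikes(stream, patterns, fibers, seed=SEED)

    fibers.to_tsv(OUT / "fibers.tsv")
    patterns.to_json(OUT / "patterns.json")
    stream.to_tsv(OUT / "stream.tsv")
    spikes.to_tsv(OUT / "fiber_spikes.tsv")
    ham, emd = pattern_distances(patterns, fibers)
    ham.to_csv(OUT / "pattern_hamming.tsv", sep="\t")
    emd.to_csv(OUT / "pattern_emd.tsv", sep="\t")

    print(f"fibers: {fibers.n_fibers} in {fibers.n_bundles} bundles")
    print(f"stream: {stream.n_events} events, {stream.duration / 1000:.0f} s")
    print(f"fiber spikes: {spikes.n_spikes}")
    print(f"pattern A size: {len(patterns.fibers('A'))} fibers")
    print(f"EMD A-B (disjoint bases): {emd.loc['A', 'B']:.1f} um")
    print(f"EMD A-E (base vs composite): {emd.loc['A', 'E']:.1f} um")


if __name__ == "__main__":
    main()
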