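"""On-disk artifact formats (HDF5/TSV/JSON) for detection and consensus results."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .consensus import AssemblyInstance, ConsensusAssembly, ReliabilityResult
from .detect import Assembly, AssemblyGroup, SignificantBins


def save_assembly_group(group: AssemblyGroup, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(group.config)
        f.create_dataset("units", data=group.units)
        f.create_dataset("bin_labels", data=group.bin_labels)
        f.create_dataset("correlations", data=group.correlations)
        f.create_dataset("thresholds", data=group.thresholds)
        f.create_dataset("membership", data=group.membership_matrix())
        f.create_dataset("dropped_clusters", data=np.asarray(group.dropped_clusters, dtype=np.int64))
        f.create_dataset("excluded_units", data=group.excluded_units)
        s = f.create_group("significant_bins")
        s.create_dataset("indices", data=group.sig.indices)
        s.create_dataset("population_counts", data=group.sig.population_counts)
        s.create_dataset("shuffle_stds", data=group.sig.shuffle_stds)
        s.attrs["threshold"] = group.sig.threshold
        a = f.create_group("assemblies")
        for asm in group.assemblies:
            g = a.create_group(str(asm.id))
            g.create_dataset("neurons", data=asm.neurons)
            g.attrs["temporal_class"] = asm.temporal_class or ""
            g.attrs["median_latency"] = (
                asm.median_latency if asm.median_latency is not None else np.nan
            )


def load_assembly_group(path) -> AssemblyGroup:
    with h5py.File(path, "r") as f:
        sig = SignificantBins(
            f["significant_bins/indices"][()],
            float(f["significant_bins"].attrs["threshold"]),
            f["significant_bins/population_counts"][()],
            f["significant_bins/shuffle_stds"][()],
        )
        assemblies = []
        for key in sorted(f["assemblies"], key=int):
            g = f["assemblies"][key]
            lat = float(g.attrs["median_latency"])
            assemblies.append(
                Assembly(
                    id=int(key),
                    neurons=g["neurons"][()],
                    temporal_class=g.attrs["temporal_class"] or None,
                    median_latency=None if np.isnan(lat) else lat,
                )
            )
        return AssemblyGroup(
            assemblies=assemblies,
            bin_labels=f["bin_labels"][()],
            sig=sig,
            correlations=f["correlations"][()],
            thresholds=f["thresholds"][()],
            units=f["units"][()],
            config=json.loads(f.attrs["config"]),
            dropped_clusters=list(f["dropped_clusters"][()]),
            excluded_units=f["excluded_units"][()],
        )


def assembly_group_summary(group: AssemblyGroup) -> dict:
    return {
        "n_assemblies": group.n_assemblies,
        "n_significant_bins": int(group.sig.n_sig),
        "threshold": group.sig.threshold,
        "assemblies": [
            {
                "id": int(a.id),
                "size": int(a.neurons.size),
                "temporal_class": a.temporal_class,
                "median_latency_ms": a.median_latency,
            }
            for a in group.assemblies
        ],
        "dropped_clusters": [int(c) for c in group.dropped_clusters],
        "config": group.config,
    }


def save_consensus(cas, path) -> None:
    with h5py.File(path, "w") as f:
        for k, ca in enumerate(cas):
            g = f.create_group(f"consensus_{k}")
            g.create_dataset("union", data=ca.union)
            g.create_dataset("instance_counts", data=ca.instance_counts)
            g.create_dataset("fractions", data=ca.fractions)
            if ca.coreness is not None:
                g.create_dataset("coreness", data=ca.coreness)
            if ca.core is not None:
                g.create_dataset("core", data=ca.core)
            inst = g.create_group("instances")
            for i, a in enumerate(ca.instances):
                gi = inst.create_group(str(i))
                gi.create_dataset("neurons", data=a.neurons)
                gi.attrs["repetition"] = a.repetition


def load_consensus(path):
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f, key=lambda k: int(k.split("_")[1])):
            g = f[key]
            instances = [
                AssemblyInstance(
                    g["instances"][i]["neurons"][()], int(g["instances"][i].attrs["repetition"])
                )
                for i in sorted(g["instances"], key=int)
            ]
            ca = ConsensusAssembly(
                instances,
                union=g["union"][()],
                instance_counts=g["instance_counts"][()],
                fractions=g["fractions"][()],
            )
            if "coreness" in g:
                ca.coreness = g["coreness"][()]
            if "core" in g:
                ca.core = g["core"][()]
            out.append(ca)
    return out


def save_reliability(result: ReliabilityResult, path) -> None:
    pd.DataFrame(
        {
            "neuron_id": result.neuron_ids,
            "reliability": result.values,
            "n_pairs": result.n_pairs,
        }
    ).to_csv(path, sep="\t", index=False)
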