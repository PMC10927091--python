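"""Structural connectivity features of assemblies.

Directed k-simplices — motifs of k+1 neurons all-to-all connected in a
feed-forward fashion — are counted within assembly subgraphs and compared to
size- and cell-type-matched random controls. Per-neuron features derived
from them (k-indegree), and from the thalamo-cortical innervation (common
thalamic indegree, pattern indegree), are the inputs to the
membership-information analysis in :mod:`.infostats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .circuit import Connectome, ThalamoCorticalInnervation


@dataclass
class SimplexCounts:
    counts: np.ndarray  # index k = dimension
    subpop_id: Optional[object] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)


@dataclass
class FeatureVector:
    """A per-neuron real-valued structural feature, aligned to a registry."""

    values: np.ndarray
    neuron_ids: np.ndarray
    name: str = ""
    source: Optional[object] = None  # assembly / pattern the feature refers to
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"neuron_id": self.neuron_ids, "value": self.values}).to_csv(
            path, sep="\t", index=False
        )


def _bitmask_rows(A: np.ndarray) -> List[int]:
    """Out-neighborhoods of a dense boolean adjacency as Python int bitsets."""
    n = A.shape[0]
    masks = []
    for i in range(n):
        m = 0
        for j in np.where(A[i])[0]:
            m |= 1 << int(j)
        masks.append(m)
    return masks


def simplex_counts(conn: Connectome, subpop, max_dim: int = 5) -> SimplexCounts:
    """Count directed k-simplices in the subgraph induced on ``subpop``.

    A k-simplex is an ordered tuple (v0, ..., vk) with an edge vi -> vj for
    every i < j; each qualifying ordering is counted once. Enumeration is by
    recursive out-neighborhood intersection over bitset rows.
    """
    if max_dim < 0:
        raise ValueError("max_dim must be >= 0")
    sub = np.asarray(sorted(set(int(s) for s in subpop)), dtype=np.int64)
    id_pos = {u: i for i, u in enumerate(conn.neuron_ids)}
    rows = np.array([id_pos[u] for u in sub], dtype=np.int64)
    A = conn.dense()[np.ix_(rows, rows)]
    np.fill_diagonal(A, False)
    masks = _bitmask_rows(A)
    counts = np.zeros(max_dim + 1, dtype=np.int64)
    counts[0] = len(sub)
    if max_dim == 0:
        return SimplexCounts(counts, None)

    def rec(cand: int, dim: int) -> None:
        c = cand
        while c:
            low = c & -c
            v = low.bit_length() - 1
            c ^= low
            counts[dim] += 1
            if dim < max_dim:
                nxt = cand & masks[v]
                if nxt:
                    rec(nxt, dim + 1)

    for v in range(len(sub)):
        if masks[v]:
            rec(masks[v], 1)
    return SimplexCounts(counts, None)


def control_simplex_counts(
    conn: Connectome, assembly, n_controls: int = 20, seed: int = 0, max_dim: int = 5
) -> List[SimplexCounts]:
    """Simplex counts of random subpopulations matched in size and
    per-cell-type composition to the assembly."""
    assembly = np.asarray(sorted(set(int(a) for a in assembly)), dtype=np.int64)
    ct = conn.meta.loc[assembly, "cell_type"]
    wanted = ct.value_counts()
    pools = {t: conn.meta.index[conn.meta["cell_type"] == t].to_numpy() for t in wanted.index}
    for t, k in wanted.items():
        if len(pools[t]) < k:
            raise ValueError(f"not enough neurons of cell type {t!r} to sample controls")
    rng = np.random.default_rng(seed)
    out = []
    for c in range(n_controls):
        pick = np.concatenate(
            [rng.choice(pools[t], size=int(k), replace=False) for t, k in wanted.items()]
        )
        sc = simplex_counts(conn, pick, max_dim)
        sc.subpop_id = f"control_{c}"
        out.append(sc)
    return out


def k_indegree(
    conn: Connectome, assembly, k: int = 0, as_population: bool = False
) -> FeatureVector:
    """Number of k-simplices fully inside ``assembly`` (excluding the target
    neuron) whose every vertex innervates the target neuron.

    ``k = 0`` reduces to the plain indegree from the assembly. With
    ``as_population=True`` the value is instead the number of distinct
    neurons participating in those innervating k-simplices.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    assembly = set(int(a) for a in assembly)
    ids = conn.neuron_ids
    id_pos = {u: i for i, u in enumerate(ids)}
    A = conn.dense()
    np.fill_diagonal(A, False)
    a_rows = np.array(sorted(id_pos[u] for u in assembly), dtype=np.int64)
    values = np.zeros(ids.size)

    if k == 0 and not as_population:
        values = A[a_rows, :].sum(axis=0).astype(float)
        # exclude the neuron's own (zeroed) diagonal contribution implicitly
        return FeatureVector(values, ids, name="0-indegree", params={"k": 0})

    sub = A[np.ix_(a_rows, a_rows)]
    masks = _bitmask_rows(sub)
    innervates = A[a_rows, :]  # (|A|, n): assembly vertex -> target edges
    in_assembly_pos = {int(ids[r]): i for i, r in enumerate(a_rows)}

    for t in range(ids.size):
        pre = innervates[:, t].copy()
        tid = int(ids[t])
        if tid in in_assembly_pos:
            pre[in_assembly_pos[tid]] = False
        allowed = 0
        for j in np.where(pre)[0]:
            allowed |= 1 << int(j)
        if not allowed:
            continue
        total = 0
        participants = 0

        # choosing the vertex at depth d completes a d-simplex (d+1 vertices)
        def rec(cand: int, prefix: int, depth: int) -> None:
            nonlocal total, participants
            c = cand
            while c:
                low = c & -c
                v = low.bit_length() - 1
                c ^= low
                if depth == k:
                    total += 1
                    participants |= prefix | low
                else:
                    nxt = cand & masks[v]
                    if nxt:
                        rec(nxt, prefix | low, depth + 1)

        if k == 0:
            total = bin(allowed).count("1")
            participants = allowed
        else:
            rec(allowed, 0, 0)
        values[t] = bin(participants).count("1") if as_population else total
    name = f"{k}-indegree" + ("-population" if as_population else "")
    return FeatureVector(values, ids, name=name, params={"k": k, "as_population": as_population})


def common_tc_indegree(innerv: ThalamoCorticalInnervation, assembly) -> FeatureVector:
    """Mean over assembly members j of the number of thalamic fibers
    innervating both the target neuron and j (binarized innervation)."""
    assembly = np.asarray(sorted(set(int(a) for a in assembly)), dtype=np.int64)
    if assembly.size == 0:
        raise ValueError("assembly must be nonempty")
    B = innerv.binarized()
    pos = {u: i for i, u in enumerate(innerv.neuron_ids)}
    a_cols = np.array([pos[u] for u in assembly], dtype=np.int64)
    BA = B[:, a_cols]
    common = np.asarray((B.T @ BA).todense(), dtype=float)  # (n_neurons, |A|)
    in_assembly = np.isin(innerv.neuron_ids, assembly)
    own_fibers = np.asarray(B.multiply(B).sum(axis=0)).ravel()

    sums = common.sum(axis=1)
    denom = np.full(innerv.neuron_ids.size, float(assembly.size))
    a_pos_of = {u: j for j, u in enumerate(assembly)}
    for i, u in enumerate(innerv.neuron_ids):
        if in_assembly[i]:
            sums[i] -= own_fibers[i]  # drop the self-pair |fibers(i) ∩ fibers(i)|
            denom[i] = assembly.size - 1
    values = np.where(denom > 0, sums / np.where(denom > 0, denom, 1), np.nan)
    return FeatureVector(values, innerv.neuron_ids, name="common_tc_indegree")


def pattern_indegree(
    innerv: ThalamoCorticalInnervation, pattern_fibers, weighted: bool = False
) -> FeatureVector:
    """Indegree of every neuron from the fibers of one input pattern
    (fiber count by default; summed synapse counts in weighted mode)."""
    pattern_fibers = np.asarray(sorted(set(int(f) for f in pattern_fibers)), dtype=np.int64)
    pos = {f: i for i, f in enumerate(innerv.fiber_ids)}
    missing = [f for f in pattern_fibers if f not in pos]
    if missing:
        raise ValueError(f"pattern fibers not in registry: {missing[:5]}")
    rows = np.array([pos[f] for f in pattern_fibers], dtype=np.int64)
    M = innerv.matrix if weighted else innerv.binarized()
    if rows.size == 0:
        values = np.zeros(innerv.neuron_ids.size)
    else:
        values = np.asarray(M[rows, :].sum(axis=0)).ravel().astype(float)
    return FeatureVector(
        values, innerv.neuron_ids, name="pattern_indegree", params={"weighted": weighted}
    )
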