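"""Dendritic trees as weighted graphs, SWC round-trip, and synthetic
morphologies with planted synapse placements.

A morphology is stored as a rooted tree in parent-pointer form: node 0 is the
soma, every other node has a parent and a positive edge length (μm) to it.
Edges are identified by their child node, so a synapse location is a pair
(edge = child node id, offset μm from the parent end).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SOMA_TYPE = 1
BASAL_DENDRITE_TYPE = 3


@dataclass
class MorphologyGraph:
    """Rooted weighted tree of a dendrite (node 0 = soma)."""

    parent: np.ndarray  # parent[i] = parent node of i; -1 for the root
    length: np.ndarray  # length[i] = edge length parent[i] -> i (μm); 0 at root
    node_type: np.ndarray = None  # SWC types; default soma + basal dendrite
    positions: np.ndarray = None  # (n, 3) coordinates consistent with lengths

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=np.float64)
        n = self.parent.size
        if self.node_type is None:
            self.node_type = np.full(n, BASAL_DENDRITE_TYPE, dtype=np.int64)
            self.node_type[0] = SOMA_TYPE
        if (self.parent == -1).sum() != 1 or self.parent[0] != -1:
            raise ValueError("exactly one root required, at node 0")
        if np.any(self.length[1:] <= 0):
            raise ValueError("edge lengths must be positive")
        if self.positions is None:
            self.positions = self._embed()

    def _embed(self) -> np.ndarray:
        """Deterministic 3-D embedding whose parent-child Euclidean
        distances equal the edge lengths (needed for SWC round-trips)."""
        rng = np.random.default_rng(12345)
        n = self.n_nodes
        pos = np.zeros((n, 3))
        for i in self.preorder()[1:]:
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            pos[i] = pos[self.parent[i]] + v * self.length[i]
        return pos

    @property
    def n_nodes(self) -> int:
        return int(self.parent.size)

    @property
    def edges(self) -> np.ndarray:
        """Child node ids (one per edge)."""
        return np.arange(1, self.n_nodes)

    def children(self):
        ch = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            ch[self.parent[i]].append(i)
        return ch

    def leaves(self) -> np.ndarray:
        has_child = np.zeros(self.n_nodes, dtype=bool)
        has_child[self.parent[1:]] = True
        out = np.where(~has_child)[0]
        return out[out != 0]

    def preorder(self) -> list:
        ch = self.children()
        order, stack = [], [0]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(ch[v]))
        return order

    def depths(self) -> np.ndarray:
        """Path length (μm) from the soma to every node."""
        d = np.zeros(self.n_nodes)
        for i in self.preorder()[1:]:
            d[i] = d[self.parent[i]] + self.length[i]
        return d

    @property
    def total_length(self) -> float:
        return float(self.length[1:].sum())

    def root_path(self, node: int) -> list:
        path = [node]
        while self.parent[path[-1]] != -1:
            path.append(int(self.parent[path[-1]]))
        return path[::-1]

    # ---- SWC ---------------------------------------------------------
    def to_swc(self, path) -> None:
        with open(path, "w") as f:
            f.write("# index type x y z radius parent\n")
            for i in range(self.n_nodes):
                x, y, z = self.positions[i]
                par = self.parent[i] + 1 if self.parent[i] >= 0 else -1
                f.write(
                    f"{i + 1} {self.node_type[i]} {x:.9f} {y:.9f} {z:.9f} 0.5 {par}\n"
                )

    @classmethod
    def from_swc(cls, path) -> "MorphologyGraph":
        rows = []
        with open(path) as f:
            for line in f:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                p = line.split()
                rows.append((int(p[0]), int(p[1]), float(p[2]), float(p[3]), float(p[4]), int(p[6])))
        rows.sort()
        ids = {r[0]: k for k, r in enumerate(rows)}
        n = len(rows)
        parent = np.full(n, -1, dtype=np.int64)
        length = np.zeros(n)
        ntype = np.zeros(n, dtype=np.int64)
        pos = np.zeros((n, 3))
        for k, (sid, t, x, y, z, par) in enumerate(rows):
            ntype[k] = t
            pos[k] = (x, y, z)
            if par != -1:
                parent[k] = ids[par]
        for k in range(n):
            if parent[k] >= 0:
                length[k] = np.linalg.norm(pos[k] - pos[parent[k]])
        return cls(parent, length, ntype, pos)


@dataclass
class SynapsePlacement:
    """Per-synapse presynaptic neuron id and dendritic location."""

    pre_ids: np.ndarray  # presynaptic neuron id per synapse
    edge: np.ndarray  # child node id of the host edge
    offset: np.ndarray  # μm from the parent end, in [0, edge length]

    def __post_init__(self) -> None:
        self.pre_ids = np.asarray(self.pre_ids, dtype=np.int64)
        self.edge = np.asarray(self.edge, dtype=np.int64)
        self.offset = np.asarray(self.offset, dtype=np.float64)

    @property
    def n_synapses(self) -> int:
        return int(self.pre_ids.size)

    def validate(self, morph: MorphologyGraph) -> None:
        if np.any(self.edge < 1) or np.any(self.edge >= morph.n_nodes):
            raise ValueError("synapse on missing edge")
        if np.any(self.offset < 0) or np.any(self.offset > morph.length[self.edge] + 1e-9):
            raise ValueError("synapse offset outside its edge")

    def to_tsv(self, path, post_neuron: int = -1) -> None:
        pd.DataFrame(
            {
                "post_neuron": post_neuron,
                "pre_neuron": self.pre_ids,
                "swc_section_id": self.edge,
                "offset_um": self.offset,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SynapsePlacement":
        df = pd.read_csv(path, sep="\t")
        return cls(
            df["pre_neuron"].to_numpy(), df["swc_section_id"].to_numpy(),
            df["offset_um"].to_numpy()
        )


def generate_morphology(n_leaves: int, mean_section_len: float = 50.0, seed: int = 0) -> MorphologyGraph:
    """Random full binary dendritic tree with ``n_leaves`` terminal tips.

    The soma carries a trunk that is the root of a full binary tree, so the
    node count is exactly ``2 * n_leaves``. Section lengths are Gamma
    distributed (shape 4) with the requested mean, hence strictly positive.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    if mean_section_len <= 0:
        raise ValueError("mean_section_len must be positive")
    rng = np.random.default_rng(seed)
    parent = [-1, 0]  # soma, trunk
    leaves = [1]
    while len(leaves) < n_leaves:
        v = leaves.pop(rng.integers(len(leaves)))
        for _ in range(2):
            parent.append(v)
            leaves.append(len(parent) - 1)
    n = len(parent)
    length = np.zeros(n)
    length[1:] = rng.gamma(shape=4.0, scale=mean_section_len / 4.0, size=n - 1)
    return MorphologyGraph(np.array(parent), length)


def _point_at_arc(morph: MorphologyGraph, path: list, arc: float):
    """(edge, offset) of the point ``arc`` μm along a root-to-leaf path."""
    s = 0.0
    for node in path[1:]:
        e = morph.length[node]
        if arc <= s + e or node == path[-1]:
            return node, float(np.clip(arc - s, 0.0, e))
        s += e
    raise AssertionError("arc beyond path")


def place_synapses(
    morph: MorphologyGraph,
    presyn_ids,
    clustered_fraction: float = 0.0,
    cluster_span: float = 20.0,
    seed: int = 0,
) -> SynapsePlacement:
    """Place synapses on the dendrite, optionally clustered on one branch.

    A ``clustered_fraction`` of the synapses lands uniformly inside a random
    window of path length ``cluster_span`` along a single root-to-leaf
    branch; the remainder is placed uniformly over the whole dendritic
    length (edge chosen proportionally to its length).
    """
    if not 0.0 <= clustered_fraction <= 1.0:
        raise ValueError("clustered_fraction must be in [0, 1]")
    if cluster_span <= 0:
        raise ValueError("cluster_span must be positive")
    if cluster_span > morph.total_length:
        raise ValueError("cluster_span exceeds total dendritic length")
    presyn_ids = np.asarray(list(presyn_ids), dtype=np.int64)
    rng = np.random.default_rng(seed)
    n = presyn_ids.size
    n_clustered = int(round(clustered_fraction * n))
    perm = rng.permutation(n)
    clustered_idx, uniform_idx = perm[:n_clustered], perm[n_clustered:]

    edges = morph.edges
    lens = morph.length[edges]
    edge_out = np.zeros(n, dtype=np.int64)
    off_out = np.zeros(n)

    # uniform component: edge ~ length, offset ~ U(0, length)
    if uniform_idx.size:
        e = rng.choice(edges, size=uniform_idx.size, p=lens / lens.sum())
        edge_out[uniform_idx] = e
        off_out[uniform_idx] = rng.random(uniform_idx.size) * morph.length[e]

    if clustered_idx.size:
        depths = morph.depths()
        lv = morph.leaves()
        plens = depths[lv]
        ok = lv[plens >= cluster_span]
        if ok.size:
            leaf = int(rng.choice(ok))
        else:  # no single branch long enough: use the longest one
            leaf = int(lv[np.argmax(plens)])
        path = morph.root_path(leaf)
        span = min(cluster_span, depths[leaf])
        start = rng.random() * (depths[leaf] - span)
        arcs = start + rng.random(clustered_idx.size) * span
        for i, arc in zip(clustered_idx, arcs):
            edge_out[i], off_out[i] = _point_at_arc(morph, path, arc)

    return SynapsePlacement(presyn_ids, edge_out, off_out)
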