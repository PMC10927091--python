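"""Synaptic clustering coefficient (SCC).

For a postsynaptic neuron and an assembly, the SCC asks whether the synapses
arriving from assembly members sit closer together along the dendrite than
expected. The statistic is the negative z-score of the mean
nearest-neighbour path distance (nnd) of those synapses, relative to the
nnds of random same-size presynaptic subpopulations drawn from the neuron's
own presynaptic pool — positive SCC means clustering, negative means
avoidance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy.stats import t as t_dist

from .morphology import MorphologyGraph, SynapsePlacement


@dataclass
class SCCResult:
    scc: float  # negative z-score of the observed nnd (unitless)
    observed_nnd: float  # μm
    control_nnds: np.ndarray  # μm, one per control population
    significant: bool
    direction: str  # "clustered" | "avoiding" | "none"
    p_value: float = np.nan
    n_synapses: int = 0


def path_distance_matrix(morph: MorphologyGraph, synapses: SynapsePlacement) -> np.ndarray:
    """Pairwise path distances (μm) between synapse locations on the tree.

    Synapses are exact points on edges (edge id + offset from the parent
    end); each host edge is split at its synapse points and shortest paths
    are computed on the augmented graph. Two synapses on the same edge are
    |offset difference| apart.
    """
    if synapses.n_synapses < 2:
        raise ValueError("need at least 2 synapses")
    synapses.validate(morph)
    n_nodes = morph.n_nodes
    n_syn = synapses.n_synapses

    rows, cols, vals = [], [], []

    def add(u, v, w):
        rows.append(u)
        cols.append(v)
        vals.append(max(w, 0.0))

    by_edge = {}
    for s in range(n_syn):
        by_edge.setdefault(int(synapses.edge[s]), []).append(s)

    for child in morph.edges:
        child = int(child)
        parent = int(morph.parent[child])
        L = float(morph.length[child])
        here = by_edge.get(child, [])
        if not here:
            add(parent, child, L)
            continue
        order = sorted(here, key=lambda s: synapses.offset[s])
        prev_node, prev_off = parent, 0.0
        for s in order:
            add(prev_node, n_nodes + s, float(synapses.offset[s]) - prev_off)
            prev_node, prev_off = n_nodes + s, float(synapses.offset[s])
        add(prev_node, child, L - prev_off)

    G = sp.csr_matrix(
        (vals + vals, (rows + cols, cols + rows)), shape=(n_nodes + n_syn, n_nodes + n_syn)
    )
    D = dijkstra(G, directed=False, indices=np.arange(n_nodes, n_nodes + n_syn))
    return D[:, n_nodes:]


def nnd(D: np.ndarray, subset=None) -> float:
    """Mean nearest-neighbour distance: for each synapse in the subset, the
    distance to its closest other subset synapse, averaged."""
    if subset is None:
        sub = D
    else:
        subset = np.asarray(list(subset), dtype=np.int64)
        sub = D[np.ix_(subset, subset)]
    if sub.shape[0] < 2:
        raise ValueError("nnd undefined for fewer than 2 synapses")
    M = sub + np.diag(np.full(sub.shape[0], np.inf))
    return float(M.min(axis=1).mean())


def scc(
    morph: MorphologyGraph,
    synapses: SynapsePlacement,
    assembly,
    n_controls: int = 20,
    alpha: float = 0.05,
    min_synapses: int = 5,
    seed: int = 0,
    distance_matrix: Optional[np.ndarray] = None,
) -> SCCResult:
    """Synaptic clustering coefficient of one neuron w.r.t. one assembly.

    Controls draw random presynaptic-neuron subsets of the neuron's full
    presynaptic population, matched in neuron count to the assembly overlap
    (all synapses of the sampled neurons are used). Significance is a
    two-tailed t test of the observed nnd against the control sample at
    level ``alpha``, scaled as a prediction interval so it is calibrated
    for a single draw.
    """
    assembly = set(int(a) for a in assembly)
    pre = synapses.pre_ids
    D = distance_matrix if distance_matrix is not None else path_distance_matrix(morph, synapses)

    obs_mask = np.isin(pre, list(assembly))
    obs_idx = np.where(obs_mask)[0]
    if obs_idx.size < min_synapses:
        raise ValueError(
            f"only {obs_idx.size} assembly synapses (< min_synapses={min_synapses})"
        )
    observed = nnd(D, obs_idx)

    all_pre = np.unique(pre)
    target_pre = np.unique(pre[obs_mask])
    n_pre = target_pre.size
    if n_pre > all_pre.size:
        raise AssertionError
    rng = np.random.default_rng(seed)
    controls = np.empty(n_controls)
    for c in range(n_controls):
        pick = rng.choice(all_pre, size=n_pre, replace=False)
        idx = np.where(np.isin(pre, pick))[0]
        if idx.size < 2:  # degenerate control: single synapse
            controls[c] = np.nan
            continue
        controls[c] = nnd(D, idx)
    controls = controls[np.isfinite(controls)]
    if controls.size < 2:
        raise ValueError("too few valid control populations")

    std = controls.std(ddof=0)
    if std == 0:
        return SCCResult(np.nan, observed, controls, False, "none", np.nan, obs_idx.size)
    value = float((controls.mean() - observed) / std)
    # two-tailed t test of the observed nnd against the control sample,
    # scaled as a prediction interval (a single draw, not the control mean,
    # is the quantity under test): t = (obs - mean) / (s * sqrt(1 + 1/m))
    m = controls.size
    s = controls.std(ddof=1)
    tstat = (observed - controls.mean()) / (s * np.sqrt(1.0 + 1.0 / m))
    pvalue = float(2.0 * t_dist.sf(abs(tstat), df=m - 1))
    significant = bool(pvalue < alpha)
    if not significant:
        direction = "none"
    else:
        direction = "clustered" if value > 0 else "avoiding"
    return SCCResult(value, observed, controls, significant, direction, pvalue, obs_idx.size)
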