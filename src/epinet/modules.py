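"""Overlapping module detection by multi-topological node weighting and seed
expansion.

Each node's *connectivity* fuses neighbourhood density and degree:

    C(v) = 2 * |eN(v)| * DN(v) / (|N(v)| * (|N(v)| - 1))

where SG(v) is the subgraph induced by v plus its direct neighbours, eN(v)
its edge set, N(v) its node set, and DN(v) the density of its densest core
(MCODE-style highest-k-core surrogate; a ``dn="plain"`` option uses SG(v)'s
own density instead).  Node weights start equal (w0 = 1) and are refined for
t rounds: the weight of edge (vi, vj) combines the endpoint weights scaled
by their connectivities plus the same term summed over common neighbours,
and a node's new weight is the sum of its incident edge weights.  Weights
are rescaled by their maximum after each round; only their ranking is used
downstream, so the rescaling is behaviour-preserving.

Seeds are drawn in descending final weight; each seed grows greedily by
admitting, among the module's outside neighbours, the best-weighted
candidate that keeps the module tight (adjacency fraction, density and
weight floors).  Expanded modules are not removed from the network, so
detected modules may overlap; near-duplicates are merged by Jaccard overlap.
Modules are reported as candidate high-order epistatic interactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import SNPNetwork

__all__ = [
    "ModuleParams",
    "NodeWeightState",
    "Module",
    "connectivity",
    "iterate_weights",
    "select_seed",
    "expand_module",
    "detect_modules",
]


@dataclass
class ModuleParams:
    """Tunables of the module detection stage.

    t_max : weighting iterations (rounds of the edge/node weight refinement).
    dn : "core" for densest-core DN(v), "plain" for SG(v)'s own density.
    min_adjacency : fraction of current members a candidate must touch.
    min_density : post-admission module density floor.
    weight_ratio : candidate weight must reach this fraction of the member mean.
    min_size : smallest reportable module (below it is not high-order).
    n_max : cap on accepted modules.
    seed_floor_sigma : seeds require weight >= mean + sigma * std of final
        weights (negative values admit most nodes as seeds).
    over_prune / prune_gamma : optional removal of weakly attached members.
    dedup_jaccard : modules overlapping at or above this are merged.
    """

    t_max: int = 2
    dn: str = "core"
    min_adjacency: float = 0.5
    min_density: float = 0.6
    weight_ratio: float = 0.25
    min_size: int = 3
    n_max: int = 20
    seed_floor_sigma: float = -1.0
    over_prune: bool = False
    prune_gamma: float = 0.5
    dedup_jaccard: float = 0.8

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.dn not in ("core", "plain"):
            raise ValueError("dn must be 'core' or 'plain'")
        for name in ("min_adjacency", "min_density", "weight_ratio", "dedup_jaccard"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_size < 1:
            raise ValueError("min_size must be at least 1")
        if self.n_max < 1:
            raise ValueError("n_max must be at least 1")
        if not 0.0 <= self.prune_gamma <= 1.0:
            raise ValueError("prune_gamma must be in [0, 1]")


@dataclass
class NodeWeightState:
    """Connectivities and iterated node weights after t rounds."""

    connectivity: dict[int, float]
    weights: dict[int, float]
    t: int


@dataclass(frozen=True)
class Module:
    """An overlapping node set grown from one seed."""

    members: frozenset[int]
    seed: int
    density: float
    mean_weight: float

    def __len__(self) -> int:
        return len(self.members)


def _graph(net) -> nx.Graph:
    return net.graph if isinstance(net, SNPNetwork) else net


def connectivity(net, v: int, dn: str = "core") -> float:
    """C(v) for one node; 0 for isolated and pendant nodes.

    A node embedded in a clique attains the maximum C = 1 (the densest core
    is the clique itself, density 1, and the formula collapses).
    """
    g = _graph(net)
    if v not in g:
        raise ValueError(f"node {v} not in network")
    if g.degree(v) <= 1:
        return 0.0
    sg = g.subgraph(set(g.neighbors(v)) | {v})
    n_nodes = sg.number_of_nodes()
    n_edges = sg.number_of_edges()
    if dn == "plain":
        dens = nx.density(sg)
    elif dn == "core":
        core = nx.core_number(sg)
        kmax = max(core.values())
        core_nodes = [u for u, c in core.items() if c == kmax]
        dens = nx.density(sg.subgraph(core_nodes))
    else:
        raise ValueError("dn must be 'core' or 'plain'")
    return 2.0 * n_edges * dens / (n_nodes * (n_nodes - 1))


def iterate_weights(net, t_max: int = 2, dn: str = "core") -> NodeWeightState:
    """Run t_max rounds of the edge/node weight refinement (w0 = 1).

    After each round weights are rescaled by their maximum so the values stay
    bounded; the ranking - the only downstream use - is unaffected.  Disjoint
    components are weighted independently (the update is purely local).
    """
    g = _graph(net)
    if int(t_max) <= 0:
        raise ValueError("t_max must be a positive integer")
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    nodes = sorted(g.nodes)
    conn = {v: connectivity(g, v, dn=dn) for v in nodes}
    adj = {v: set(g.neighbors(v)) for v in nodes}
    w = {v: 1.0 for v in nodes}
    for _ in range(int(t_max)):
        wc = {v: w[v] * conn[v] for v in nodes}
        new_w: dict[int, float] = {}
        for vi in nodes:
            total = 0.0
            for vj in adj[vi]:
                ew = wc[vi] + wc[vj]
                for u in adj[vi] & adj[vj]:
                    ew += wc[u]
                total += ew
            new_w[vi] = total
        top = max(new_w.values())
        if top > 0:
            w = {v: new_w[v] / top for v in nodes}
        else:
            w = new_w
    return NodeWeightState(connectivity=conn, weights=w, t=int(t_max))


def select_seed(
    state: NodeWeightState, excluded, floor: float | None = None
) -> int | None:
    """Highest-weight node outside ``excluded`` (ties to the smallest index).

    Returns None when every node is excluded or the best remaining weight is
    below ``floor``.
    """
    excluded = set(excluded)
    best: int | None = None
    best_w = -math.inf
    for v in sorted(state.weights):
        if v in excluded:
            continue
        wv = state.weights[v]
        if wv > best_w:
            best, best_w = v, wv
    if best is None:
        return None
    if floor is not None and best_w < floor:
        return None
    return best


def _admissible(g, members, internal_edges, weights, params, candidate):
    """Admission check; returns adjacency count or None if rejected."""
    adj_count = sum(1 for m in members if g.has_edge(candidate, m))
    # strict inequality: exact-half attachment (e.g. 1 of 2) would let hub or
    # bridge nodes leak a growing module across a sparse boundary
    if adj_count <= params.min_adjacency * len(members):
        return None
    size = len(members) + 1
    density = 2.0 * (internal_edges + adj_count) / (size * (size - 1))
    if size > 2 and density < params.min_density:
        return None
    mean_w = sum(weights[m] for m in members) / len(members)
    if weights[candidate] < params.weight_ratio * mean_w:
        return None
    return adj_count


def expand_module(
    net, state: NodeWeightState, seed: int, params: ModuleParams | None = None
) -> Module | None:
    """Grow one module greedily from a seed; None if it stays below min_size.

    At each step the outside neighbours of the module are screened by the
    admission rule (adjacency fraction strictly above min_adjacency,
    post-admission density >= min_density, weight >= weight_ratio * member
    mean) and the
    best candidate is added: highest weight, ties to the candidate touching
    more members, remaining ties to the smallest index.  With over-pruning
    enabled, weakly attached non-seed members (within-module degree below
    prune_gamma * (|M| - 1)) are removed afterwards and the seed's connected
    component is kept.
    """
    if params is None:
        params = ModuleParams()
    g = _graph(net)
    if seed not in g:
        raise ValueError(f"seed {seed} not in network")
    w = state.weights
    members: set[int] = {seed}
    internal_edges = 0
    while True:
        candidates: set[int] = set()
        for m in members:
            candidates.update(g.neighbors(m))
        candidates -= members
        best = None  # (weight, adj_count, -index) maximised
        for c in sorted(candidates):
            adj_count = _admissible(g, members, internal_edges, w, params, c)
            if adj_count is None:
                continue
            key = (w[c], adj_count, -c)
            if best is None or key > best[0]:
                best = (key, c, adj_count)
        if best is None:
            break
        members.add(best[1])
        internal_edges += best[2]

    if params.over_prune and len(members) > 1:
        changed = True
        while changed:
            changed = False
            for v in sorted(members - {seed}):
                indeg = sum(1 for m in members if m != v and g.has_edge(v, m))
                if indeg < params.prune_gamma * (len(members) - 1):
                    members.discard(v)
                    changed = True
                    break
        sub = g.subgraph(members)
        members = set(nx.node_connected_component(sub, seed))

    if len(members) < params.min_size:
        return None
    sub = g.subgraph(members)
    return Module(
        members=frozenset(members),
        seed=seed,
        density=nx.density(sub),
        mean_weight=sum(w[m] for m in members) / len(members),
    )


def _jaccard(a: frozenset[int], b: frozenset[int]) -> float:
    return len(a & b) / len(a | b)


def detect_modules(net, params: ModuleParams | None = None) -> list[Module]:
    """Detect overlapping modules over the whole network.

    Weights are computed once.  Seeds are drawn in descending weight while
    the seed floor (mean + seed_floor_sigma * std of final weights) holds and
    fewer than n_max modules are accepted; used seeds are excluded from
    seeding but stay available as members, so modules may share nodes.
    Modules with Jaccard overlap >= dedup_jaccard are merged keeping the one
    with the higher mean weight.  Sub-min_size expansions do not count
    against n_max.  The whole procedure is deterministic.
    """
    if params is None:
        params = ModuleParams()
    g = _graph(net)
    if g.number_of_nodes() == 0:
        return []
    state = iterate_weights(g, t_max=params.t_max, dn=params.dn)
    wv = np.fromiter(state.weights.values(), dtype=float)
    floor = float(wv.mean() + params.seed_floor_sigma * wv.std())
    excluded: set[int] = set()
    accepted: list[Module] = []
    while len(accepted) < params.n_max:
        seed = select_seed(state, excluded, floor=floor)
        if seed is None:
            break
        excluded.add(seed)
        mod = expand_module(g, state, seed, params)
        if mod is not None:
            accepted.append(mod)
    # near-duplicate merging, better (higher mean weight) modules first
    accepted.sort(key=lambda m: (-m.mean_weight, -m.density, m.seed))
    kept: list[Module] = []
    for mod in accepted:
        if all(_jaccard(mod.members, k.members) < params.dedup_jaccard for k in kept):
            kept.append(mod)
    return kept
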