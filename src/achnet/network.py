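"""Directed scale-free network construction with controlled hub in-degree bias.

The undirected substrate is grown with the Barabási–Albert linearized
chord diagram (LCD) process: starting from an empty graph on a fixed node
set, each node in turn attaches to an existing node chosen proportionally
to degree.  The growth pass is executed ``z_passes`` times over the same
node set (degrees accumulate across passes, edges form a union), giving an
average degree of ~``z_passes`` incoming plus ~``z_passes`` outgoing per
neuron after orientation.

Each undirected edge then becomes exactly one directed synapse: with
probability ``p_in`` it points into its higher-degree endpoint, otherwise
out of it.  Low ``p_in`` gives "strong hub outgoing" networks, high
``p_in`` "strong hub incoming".  The hub is the top 10% of excitatory
neurons by total degree.

Weight-matrix convention: ``weights[i][j]`` is the conductance of the
synapse from presynaptic neuron ``j`` onto postsynaptic neuron ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "NetworkConfig",
    "NetworkTopology",
    "build_scale_free",
    "orient_edges",
    "identify_hub",
    "build_ei_network",
    "build_network",
    "remove_hub",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class NetworkConfig:
    n: int = 250                      # neuron count
    z_passes: int = 15                # LCD growth-pass executions
    p_in: float = 0.5                 # hub in-degree orientation probability
    inhibitory_fraction: float = 0.0  # fraction of inhibitory cells
    w0_exc: float = 0.04              # initial excitatory conductance, mS/cm^2
    w_inh: float = 0.01               # inhibitory conductance, mS/cm^2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not 0.0 <= self.p_in <= 1.0:
            raise ValueError("p_in must lie in [0, 1]")
        if not 0.0 <= self.inhibitory_fraction < 1.0:
            raise ValueError("inhibitory_fraction must lie in [0, 1)")
        if self.w0_exc <= 0:
            raise ValueError("w0_exc must be positive")
        if self.w_inh < 0:
            raise ValueError("w_inh must be non-negative")
        if self.z_passes < 1:
            raise ValueError("z_passes must be at least 1")


@dataclass
class NetworkTopology:
    """Directed weighted connectivity plus neuron class and hub labels."""

    weights: np.ndarray               # (n, n), [post, pre], mS/cm^2
    is_inhibitory: np.ndarray         # (n,) bool
    hub: np.ndarray                   # sorted hub indices
    degree_rank: np.ndarray           # permutation: neurons by descending degree
    w0_exc: float = 0.04

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def excitatory(self) -> np.ndarray:
        return np.flatnonzero(~self.is_inhibitory)

    @property
    def hub_mask(self) -> np.ndarray:
        m = np.zeros(self.n, dtype=bool)
        m[self.hub] = True
        return m

    def in_degrees(self) -> np.ndarray:
        return np.count_nonzero(self.weights, axis=1)

    def out_degrees(self) -> np.ndarray:
        return np.count_nonzero(self.weights, axis=0)

    def n_synapses(self) -> int:
        return int(np.count_nonzero(self.weights))

    def copy(self) -> "NetworkTopology":
        return NetworkTopology(self.weights.copy(), self.is_inhibitory.copy(),
                               self.hub.copy(), self.degree_rank.copy(),
                               self.w0_exc)


def build_scale_free(config: NetworkConfig,
                     rng: np.random.Generator | None = None) -> nx.Graph:
    """Grow the undirected scale-free substrate on ``config.n`` nodes.

    Runs the LCD growth process ``z_passes`` times over the same node set.
    Within a pass, node ``u`` attaches to one earlier node chosen
    proportionally to accumulated degree; self-loops and already-present
    edges are excluded (redrawing until a legal partner is found is
    equivalent to sampling the degree-weighted conditional over legal
    partners, which is what is drawn directly); when every legal partner
    still has zero degree the choice is uniform.  In later passes a
    low-index node can be adjacent to all of its predecessors already; the
    draw then falls back to the whole node set so that each pass keeps its
    budget of n - 1 attachments, and is skipped only when the node is
    adjacent to every other node.  Edge count is ``z_passes * (n - 1)``
    up to near-complete-graph saturation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    degree = np.zeros(n, dtype=np.int64)
    adj: list[set[int]] = [set() for _ in range(n)]

    for _ in range(config.z_passes):
        for u in range(n):
            if u == 0:
                continue  # no attachment partner other than itself
            free = np.array([v for v in range(u) if v not in adj[u]],
                            dtype=np.int64)
            if free.size == 0:
                # later passes can exhaust a low-index node's predecessor
                # pool; fall back to the whole node set to preserve the
                # per-pass edge budget of n - 1 attachments
                free = np.array([v for v in range(n)
                                 if v != u and v not in adj[u]],
                                dtype=np.int64)
            if free.size == 0:
                continue  # adjacent to every other node
            weights = degree[free].astype(np.float64)
            total = weights.sum()
            if total == 0.0:
                target = int(free[rng.integers(free.size)])
            else:
                x = rng.random() * total
                target = int(free[np.searchsorted(np.cumsum(weights), x,
                                                  side="right")])
            adj[u].add(target)
            adj[target].add(u)
            degree[u] += 1
            degree[target] += 1

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((u, v) for u in range(n) for v in adj[u] if v > u)
    return g


def _degree_order(degrees: np.ndarray) -> np.ndarray:
    """Neuron indices sorted by descending degree, ties broken by lower
    index (stable)."""
    return np.argsort(-degrees, kind="stable")


def orient_edges(graph: nx.Graph, p_in: float,
                 seed: int | np.random.Generator = 0,
                 w0_exc: float = 0.04,
                 hub_fraction: float = 0.1) -> NetworkTopology:
    """Assign a direction to every undirected edge.

    Neurons are ranked by descending total degree.  For each edge, with
    probability ``p_in`` it is directed *into* its higher-ranked (more
    connected) endpoint, otherwise out of it, and carries conductance
    ``w0_exc``.  Each undirected edge becomes exactly one directed synapse.
    """
    if not 0.0 <= p_in <= 1.0:
        raise ValueError("p_in must lie in [0, 1]")
    if any(u == v for u, v in graph.edges):
        raise ValueError("graph must be simple (no self-loops)")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n = graph.number_of_nodes()
    degrees = np.array([graph.degree(v) for v in range(n)], dtype=np.int64)
    order = _degree_order(degrees)
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)

    W = np.zeros((n, n))
    for u, v in sorted(graph.edges):
        hi, lo = (u, v) if rank[u] < rank[v] else (v, u)
        if rng.random() < p_in:
            W[hi, lo] = w0_exc     # into the higher-degree endpoint
        else:
            W[lo, hi] = w0_exc     # out of it
    topo = NetworkTopology(weights=W,
                           is_inhibitory=np.zeros(n, dtype=bool),
                           hub=np.empty(0, dtype=np.int64),
                           degree_rank=order, w0_exc=w0_exc)
    topo.hub = identify_hub(topo, hub_fraction)
    return topo


def identify_hub(topology: NetworkTopology, fraction: float = 0.1) -> np.ndarray:
    """Indices of the top ``fraction`` of excitatory neurons by total
    degree (in + out), ties broken by lower index."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    exc = topology.excitatory
    if exc.size == 0:
        raise ValueError("topology has no excitatory neurons")
    total = topology.in_degrees() + topology.out_degrees()
    n_hub = _round_half_up(fraction * exc.size)
    order = exc[_degree_order(total[exc])]
    return np.sort(order[:n_hub])


def build_ei_network(config: NetworkConfig,
                     rng: np.random.Generator | None = None) -> NetworkTopology:
    """Mixed excitatory-inhibitory topology.

    Excitatory cells (indices 0..n_exc-1) form the oriented scale-free
    network.  Inhibitory cells are wired uniformly at random: each receives
    K = ``z_passes`` inputs from distinct excitatory neurons (conductance
    ``w0_exc``) and sends K outputs to distinct neurons of any class
    (conductance ``w_inh``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    n_inh = _round_half_up(config.inhibitory_fraction * n)
    n_exc = n - n_inh
    sub = NetworkConfig(n=n_exc, z_passes=config.z_passes, p_in=config.p_in,
                        w0_exc=config.w0_exc, w_inh=config.w_inh)
    g = build_scale_free(sub, rng)
    exc_topo = orient_edges(g, config.p_in, rng, config.w0_exc)
    if n_inh == 0:
        return exc_topo

    W = np.zeros((n, n))
    W[:n_exc, :n_exc] = exc_topo.weights
    K = config.z_passes
    for i in range(n_exc, n):
        sources = rng.choice(n_exc, size=min(K, n_exc), replace=False)
        W[i, sources] = config.w0_exc
        candidates = np.array([v for v in range(n) if v != i])
        targets = rng.choice(candidates, size=min(K, n - 1), replace=False)
        W[targets, i] = config.w_inh
    is_inh = np.zeros(n, dtype=bool)
    is_inh[n_exc:] = True
    total = np.count_nonzero(W, axis=0) + np.count_nonzero(W, axis=1)
    topo = NetworkTopology(weights=W, is_inhibitory=is_inh,
                           hub=np.empty(0, dtype=np.int64),
                           degree_rank=_degree_order(total),
                           w0_exc=config.w0_exc)
    topo.hub = identify_hub(topo)
    return topo


def build_network(config: NetworkConfig,
                  rng: np.random.Generator | None = None) -> NetworkTopology:
    """Full pipeline: scale-free growth, orientation, hub labelling, and
    (if requested) the inhibitory population."""
    if config.inhibitory_fraction > 0:
        return build_ei_network(config, rng)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = build_scale_free(config, rng)
    return orient_edges(g, config.p_in, rng, config.w0_exc)


def remove_hub(topology: NetworkTopology) -> NetworkTopology:
    """Disconnect the hub: zero all synapses into and out of hub neurons.

    Hub neurons stay in the state vector (they keep receiving drive and
    noise) but are synaptically isolated.
    """
    out = topology.copy()
    if topology.hub.size:
        out.weights[topology.hub, :] = 0.0
        out.weights[:, topology.hub] = 0.0
    return out
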