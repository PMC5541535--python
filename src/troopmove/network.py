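"""Influence-network construction, centrality and core/periphery structure.

Edges run from influencer to influenced: an arrow j -> i with weight
beta[i, j] means i's direction of travel responds to j's position.  Only
coefficients whose 99% HPDI excludes zero are retained; positive weights
form the attraction subgraph, negative ones the repulsion subgraph (stored
with their magnitude, the sign kept as an attribute).

Under this orientation, graph-theoretic *out*-strength of a node is the
total influence it exerts (the field convention often calls this
"in-strength": how much others are sensitive to the animal), while graph
in-strength is its total responsiveness to others.

Core/periphery structure is measured on the attraction subgraph, made
undirected by summing reciprocal weights, with a weighted k-shell whose node
score is sqrt(degree x strength).  The D_core statistic (sum over all
ordered node pairs of absolute shell differences) is compared against
random graphs that keep the node set and the exact multiset of edge weights
but place them on uniformly drawn directed pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass
class InfluenceNetwork:
    """Directed weighted influence graph (edge j -> i: j influences i)."""

    graph: nx.DiGraph  # edge attrs: weight (signed), sign (+1/-1)

    @classmethod
    def from_edges(cls, nodes, edges) -> "InfluenceNetwork":
        """``edges`` is an iterable of (source, target, signed_weight)."""
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for u, v, w in edges:
            g.add_edge(u, v, weight=float(w), sign=1 if w > 0 else -1)
        return cls(g)

    def subgraph(self, which: str) -> nx.DiGraph:
        """Attraction (weight>0) or repulsion (weight<0, stored as |w|)."""
        if which not in ("attraction", "repulsion"):
            raise ValueError("which must be 'attraction' or 'repulsion'")
        out = nx.DiGraph()
        out.add_nodes_from(self.graph.nodes)
        for u, v, d in self.graph.edges(data=True):
            w = d["weight"]
            if which == "attraction" and w > 0:
                out.add_edge(u, v, weight=w, sign=1)
            elif which == "repulsion" and w < 0:
                out.add_edge(u, v, weight=abs(w), sign=-1)
        return out

    @property
    def attraction(self) -> nx.DiGraph:
        return self.subgraph("attraction")

    @property
    def repulsion(self) -> nx.DiGraph:
        return self.subgraph("repulsion")


def build_influence_network(fits) -> InfluenceNetwork:
    """Screened network from per-focal fits.

    Keeps an edge j -> i for every dyadic coefficient beta[i, j] whose 99%
    HPDI excludes zero; the signed posterior mean is the edge weight.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need fits for at least two focal animals")
    nodes = sorted({f.focal for f in fits} | {a for f in fits for a in f.beta})
    edges = []
    for f in fits:
        for j, summ in f.beta.items():
            if summ.excludes_zero():
                edges.append((j, f.focal, summ.mean))
    return InfluenceNetwork.from_edges(nodes, edges)


def node_strengths(net: InfluenceNetwork, which: str = "attraction") -> dict[str, tuple[float, float]]:
    """Graph-theoretic (in_strength, out_strength) per node on a subgraph.

    in_strength sums weights of arriving edges (how much the node responds
    to others); out_strength sums departing edges (influence it exerts).
    """
    g = net.subgraph(which)
    return {
        v: (float(g.in_degree(v, weight="weight")), float(g.out_degree(v, weight="weight")))
        for v in g.nodes
    }


def alpha_centrality(
    net: InfluenceNetwork,
    alpha: float | str = "auto",
    exo: np.ndarray | None = None,
    which: str = "attraction",
) -> dict[str, float]:
    """Alpha centrality x = (I - alpha * A^T)^-1 exo on a subgraph.

    A[source, target] is the weighted adjacency; the exogenous vector
    defaults to ones, which keeps the measure defined for nodes with no
    incoming edges.  ``alpha="auto"`` uses 0.9 / lambda_max(A) when the
    spectral radius is positive, else 1.
    """
    g = net.subgraph(which)
    nodes = list(g.nodes)
    A = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    n = len(nodes)
    if alpha == "auto":
        lam = np.max(np.abs(np.linalg.eigvals(A))) if n else 0.0
        alpha = 0.9 / lam if lam > 1e-12 else 1.0
    e = np.ones(n) if exo is None else np.asarray(exo, float)
    M = np.eye(n) - float(alpha) * A.T
    try:
        x = np.linalg.solve(M, e)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"(I - alpha A^T) is singular for alpha={alpha}; try a smaller alpha"
        ) from err
    return dict(zip(nodes, x.astype(float)))


@dataclass
class CoreDecomposition:
    """Weighted k-shell values per node and the D_core scalar."""

    shell: dict[str, float]
    d_core: float = field(init=False)

    def __post_init__(self) -> None:
        self.d_core = d_core(np.array(list(self.shell.values())))

    def top_shell(self) -> set[str]:
        """Nodes in the innermost (maximal, non-zero) shell; the detected core."""
        if not self.shell:
            return set()
        m = max(self.shell.values())
        if m <= 0:
            return set()
        return {v for v, s in self.shell.items() if abs(s - m) < 1e-9}


def _undirected_arrays(g: nx.DiGraph) -> tuple[list, np.ndarray, np.ndarray, np.ndarray]:
    """Symmetrise: reciprocal directed weights are summed on one undirected edge."""
    nodes = list(g.nodes)
    index = {v: k for k, v in enumerate(nodes)}
    acc: dict[tuple[int, int], float] = {}
    for u, v, d in g.edges(data=True):
        a, b = index[u], index[v]
        key = (a, b) if a < b else (b, a)
        acc[key] = acc.get(key, 0.0) + d["weight"]
    if acc:
        uu, vv = np.array(list(acc.keys()), int).T
        ww = np.array(list(acc.values()), float)
    else:
        uu = vv = np.empty(0, int)
        ww = np.empty(0, float)
    return nodes, uu, vv, ww


def _kshell_values(n: int, eu: np.ndarray, ev: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted k-shell on an undirected weighted edge list.

    Node score k' = sqrt(k * s) with k the current degree and s the current
    strength.  Pruning: repeatedly remove (simultaneously) every node whose
    k' is at or below the running threshold, assigning it the threshold as
    its shell value and recomputing k'; when no node qualifies the threshold
    rises to the minimum remaining k'.  Isolated nodes get shell 0.
    """
    shell = np.zeros(n)
    alive = np.ones(n, bool)
    edge_alive = np.ones(len(w), bool)
    threshold = 0.0
    tol = 1e-9
    while alive.any():
        k = np.bincount(eu[edge_alive], minlength=n) + np.bincount(ev[edge_alive], minlength=n)
        s = np.bincount(eu[edge_alive], weights=w[edge_alive], minlength=n) + np.bincount(
            ev[edge_alive], weights=w[edge_alive], minlength=n
        )
        kprime = np.sqrt(k * s)
        kprime[~alive] = np.inf
        low = np.min(kprime)
        if low > threshold + tol:
            threshold = low
        removable = alive & (kprime <= threshold + tol)
        shell[removable] = threshold
        alive &= ~removable
        edge_alive &= alive[eu] & alive[ev]
    return shell


def weighted_kshell(net: InfluenceNetwork | nx.DiGraph, which: str = "attraction") -> CoreDecomposition:
    """Core/periphery decomposition of the (symmetrised) attraction subgraph."""
    g = net.subgraph(which) if isinstance(net, InfluenceNetwork) else net
    nodes, eu, ev, w = _undirected_arrays(g)
    shell = _kshell_values(len(nodes), eu, ev, w)
    return CoreDecomposition(shell=dict(zip(nodes, shell.astype(float))))


def d_core(shell_values: np.ndarray) -> float:
    """Sum over all ordered node pairs (including i=j) of |x_i - x_j|."""
    x = np.asarray(shell_values, float)
    if x.size < 1:
        raise ValueError("need at least one shell value")
    return float(np.abs(x[:, None] - x[None, :]).sum())


@dataclass
class PermutationTestResult:
    observed_d: float
    null_d: np.ndarray
    q95: float
    exceeds: bool
    n_perm: int
    seed: int


def permutation_null(
    net: InfluenceNetwork,
    n_perm: int = 10_000,
    seed: int = 0,
    which: str = "attraction",
) -> PermutationTestResult:
    """Permutation test of core/periphery magnitude against a random-graph null.

    Each null draw keeps the node set and the exact multiset of observed
    edge weights, placing them on uniformly sampled distinct directed
    non-self pairs (edge count fixed), then recomputes the weighted k-shell
    and D_core.  ``exceeds`` is True when the observed D_core is strictly
    above the null's 95% quantile.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    g = net.subgraph(which)
    nodes, eu, ev, w_und = _undirected_arrays(g)
    n = len(nodes)
    observed = d_core(_kshell_values(n, eu, ev, w_und))
    weights = np.array([d["weight"] for _, _, d in g.edges(data=True)], float)
    m = len(weights)
    n_pairs = n * (n - 1)
    if m > n_pairs:
        raise ValueError("more edges than available ordered pairs")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        codes = rng.choice(n_pairs, size=m, replace=False)
        src = codes // (n - 1)
        tgt = codes % (n - 1)
        tgt = np.where(tgt >= src, tgt + 1, tgt)  # skip the diagonal
        # symmetrise the random directed placement exactly as observed graphs are
        a = np.minimum(src, tgt)
        b = np.maximum(src, tgt)
        key = a * n + b
        uniq, inv = np.unique(key, return_inverse=True)
        w_sum = np.bincount(inv, weights=weights, minlength=len(uniq))
        null[p] = d_core(_kshell_values(n, uniq // n, uniq % n, w_sum))
    q95 = float(np.quantile(null, 0.95))
    return PermutationTestResult(
        observed_d=float(observed),
        null_d=null,
        q95=q95,
        exceeds=bool(observed > q95),
        n_perm=n_perm,
        seed=seed,
    )
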