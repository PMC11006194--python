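"""Weighted population structures for evolutionary dynamics on graphs.

A population of ``N`` sites is represented as a connected, undirected,
weighted graph: nodes are sites occupied by one individual each, and edge
weights are dimensionless interaction strengths that bias where offspring
migrate.  This module provides the :class:`WeightedGraph` container with
validation, the classic graph families used in the study of amplifiers of
selection (complete graph, star, fan), the composite two-chunk graph
:func:`make_amplifier_AN` designed to amplify under *both* Birth-death and
death-Birth updating, structural quantities (weighted degree, temperature),
and a plain-text edge-list format.

Conventions
-----------
* Edge weights are strictly positive; ``w(u, v) == w(v, u)``.
* No self-loops; every node has at least one incident edge.
* Node identifiers are opaque strings.  Constructors emit descriptive
  labels such as ``hub-3`` or ``fan-blade-2-a``.
* Connectivity is checked at construction and recorded in
  :attr:`WeightedGraph.is_connected`; fixation computations require it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GraphValidationError",
    "GraphConnectivityError",
    "NodeLookupError",
    "SymmetrySpec",
    "WeightedGraph",
    "ANParams",
    "make_complete",
    "make_star",
    "make_fan",
    "make_bd_chunk",
    "make_amplifier_AN",
    "weighted_degree",
    "temperature",
    "temperature_vector",
    "read_edge_list",
    "write_edge_list",
]


class GraphValidationError(ValueError):
    """Raised when a graph (or graph parameter) violates the data model."""


class GraphConnectivityError(GraphValidationError):
    """Raised when an operation requiring a connected graph gets one that is not."""


class NodeLookupError(KeyError):
    """Raised when a node identifier is not present in the graph."""


@dataclass(frozen=True)
class SymmetrySpec:
    """Orbit description of a graph's node symmetries, used for exact lumping.

    The node set is partitioned into

    * ``tracked`` -- nodes whose mutant/resident state is tracked
      individually (e.g. the star center, or the two endpoints of the
      connecting edge in the composite amplifier);
    * ``single_groups`` -- groups of mutually exchangeable nodes, of which
      only the mutant *count* matters (e.g. star leaves, hub nodes);
    * ``pair_groups`` -- groups of exchangeable two-node blades, of which
      only the multiset of per-blade mutant counts (0, 1 or 2) matters.

    A configuration's lumping key is the tuple of tracked states, group
    counts, and per-pair-group ``(#blades with 1 mutant, #blades with 2)``.
    Exactness of the lumping is a property of the graph's automorphisms and
    is verified by test on small instances rather than assumed.
    """

    tracked: tuple[str, ...] = ()
    single_groups: tuple[tuple[str, ...], ...] = ()
    pair_groups: tuple[tuple[tuple[str, str], ...], ...] = ()


class WeightedGraph:
    """Undirected, weighted population structure.

    Parameters
    ----------
    nodes
        Ordered sequence of unique node labels (``N >= 2``).
    edges
        Iterable of ``(u, v, weight)`` triples, one per undirected edge.
        Weights must be strictly positive and finite; duplicate edges
        (in either order) and self-loops are rejected, and every node must
        appear in at least one edge.
    family, symmetry, designated
        Optional constructor metadata: a family tag (``"complete"``,
        ``"star"``, ``"fan"``, ``"an"``, ...), the :class:`SymmetrySpec`
        enabling the lumped solver, and a mapping of designated roles
        (e.g. ``{"u": "hub-0", "v": "fan-center"}``).
    """

    __slots__ = ("nodes", "_index", "W", "_deg", "family", "symmetry",
                 "designated", "is_connected")

    def __init__(
        self,
        nodes: Sequence[str],
        edges: Iterable[tuple[str, str, float]],
        *,
        family: str | None = None,
        symmetry: SymmetrySpec | None = None,
        designated: Mapping[str, str] | None = None,
    ) -> None:
        nodes = tuple(str(v) for v in nodes)
        if len(nodes) < 2:
            raise GraphValidationError(f"population needs at least 2 nodes, got {len(nodes)}")
        if len(set(nodes)) != len(nodes):
            raise GraphValidationError("duplicate node labels")
        self.nodes = nodes
        self._index = {v: i for i, v in enumerate(nodes)}
        N = len(nodes)
        W = np.zeros((N, N), dtype=float)
        seen: set[tuple[int, int]] = set()
        for u, v, w in edges:
            try:
                iu, iv = self._index[str(u)], self._index[str(v)]
            except KeyError as exc:
                raise GraphValidationError(f"edge references unknown node {exc.args[0]!r}") from exc
            if iu == iv:
                raise GraphValidationError(f"self-loop at node {u!r}")
            key = (iu, iv) if iu < iv else (iv, iu)
            if key in seen:
                raise GraphValidationError(f"duplicate edge {u!r}--{v!r}")
            seen.add(key)
            w = float(w)
            if not math.isfinite(w) or w <= 0:
                raise GraphValidationError(f"edge {u!r}--{v!r} has non-positive weight {w}")
            W[iu, iv] = W[iv, iu] = w
        self.W = W
        self._deg = W.sum(axis=1)
        if np.any(self._deg == 0):
            lonely = [nodes[i] for i in np.flatnonzero(self._deg == 0)]
            raise GraphValidationError(f"isolated node(s) {lonely}: every site must interact")
        self.family = family
        self.symmetry = symmetry
        self.designated = dict(designated or {})
        n_comp, _ = connected_components(csr_matrix(W), directed=False)
        self.is_connected = bool(n_comp == 1)

    # -- basic queries ----------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.nodes)

    @property
    def num_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.W)))

    @property
    def degree_vector(self) -> np.ndarray:
        """Weighted degrees in node order (read-only copy)."""
        return self._deg.copy()

    def index(self, v: str) -> int:
        try:
            return self._index[v]
        except KeyError:
            raise NodeLookupError(f"node {v!r} not in graph") from None

    def weight(self, u: str, v: str) -> float:
        return float(self.W[self.index(u), self.index(v)])

    def neighbors(self, v: str) -> tuple[str, ...]:
        i = self.index(v)
        return tuple(self.nodes[j] for j in np.flatnonzero(self.W[i]))

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate undirected edges ``(u, v, w)`` with u before v in node order."""
        iu, iv = np.nonzero(np.triu(self.W))
        for i, j in zip(iu.tolist(), iv.tolist()):
            yield self.nodes[i], self.nodes[j], float(self.W[i, j])

    def weighted_degree(self, v: str) -> float:
        return float(self._deg[self.index(v)])

    def require_connected(self) -> None:
        if not self.is_connected:
            raise GraphConnectivityError("operation requires a connected graph")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges())
        return g

    @classmethod
    def from_networkx(cls, g, default_weight: float = 1.0) -> "WeightedGraph":
        """Build from a networkx graph; missing ``weight`` attributes default to 1."""
        nodes = [str(v) for v in g.nodes()]
        edges = [(str(u), str(v), float(d.get("weight", default_weight)))
                 for u, v, d in g.edges(data=True)]
        return cls(nodes, edges)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = f" family={self.family!r}" if self.family else ""
        return f"<WeightedGraph N={self.N} edges={self.num_edges}{tag} connected={self.is_connected}>"


# -- structural quantities ------------------------------------------------


def weighted_degree(G: WeightedGraph, v: str) -> float:
    """Sum of edge weights incident to ``v``: ``deg(v) = sum_u w(v, u)``."""
    return G.weighted_degree(v)


def temperature(G: WeightedGraph, u: str) -> float:
    """Temperature ``T(u) = sum_{v ~ u} w(v, u) / deg(v)``.

    Under neutral Birth-death updating this is the rate (relative to the
    population average of 1) at which node ``u`` is replaced by its
    neighbours.  Temperatures sum to ``N`` over any connected graph.
    """
    G.require_connected()
    i = G.index(u)
    return float(np.sum(G.W[:, i] / G._deg))


def temperature_vector(G: WeightedGraph) -> np.ndarray:
    """All node temperatures in node order."""
    G.require_connected()
    return (G.W / G._deg[:, None]).sum(axis=0)


# -- graph family constructors --------------------------------------------


def make_complete(N: int) -> WeightedGraph:
    """Unweighted complete graph ``K_N`` (the well-mixed population)."""
    if N < 2:
        raise GraphValidationError(f"complete graph needs N >= 2, got {N}")
    nodes = [f"v{i}" for i in range(N)]
    edges = [(nodes[i], nodes[j], 1.0) for i in range(N) for j in range(i + 1, N)]
    sym = SymmetrySpec(single_groups=(tuple(nodes),))
    return WeightedGraph(nodes, edges, family="complete", symmetry=sym)


def make_star(N: int) -> WeightedGraph:
    """Unweighted star ``S_N``: one center joined to ``N - 1`` leaves."""
    if N < 2:
        raise GraphValidationError(f"star graph needs N >= 2, got {N}")
    leaves = [f"leaf-{i}" for i in range(N - 1)]
    nodes = ["center"] + leaves
    edges = [("center", leaf, 1.0) for leaf in leaves]
    sym = SymmetrySpec(tracked=("center",), single_groups=(tuple(leaves),))
    return WeightedGraph(nodes, edges, family="star",
                         symmetry=sym, designated={"center": "center"})


def make_fan(m: int, hub_coupling: float = 0.01) -> WeightedGraph:
    """Fan graph on ``2m + 1`` nodes: a center and ``m`` two-node blades.

    Within-blade edges have weight 1; each blade node is joined to the
    center with weight ``hub_coupling``.  Small coupling makes the blades
    interact only rarely with the hub, which is what gives the fan its
    amplification under death-Birth updating.
    """
    if m < 1:
        raise GraphValidationError(f"fan needs at least 1 blade, got {m}")
    if not (hub_coupling > 0):
        raise GraphValidationError(f"hub_coupling must be positive, got {hub_coupling}")
    nodes = ["fan-center"]
    edges: list[tuple[str, str, float]] = []
    blades: list[tuple[str, str]] = []
    for i in range(m):
        a, b = f"fan-blade-{i}-a", f"fan-blade-{i}-b"
        nodes += [a, b]
        blades.append((a, b))
        edges.append((a, b, 1.0))
        edges.append(("fan-center", a, hub_coupling))
        edges.append(("fan-center", b, hub_coupling))
    sym = SymmetrySpec(tracked=("fan-center",), pair_groups=(tuple(blades),))
    return WeightedGraph(nodes, edges, family="fan",
                         symmetry=sym, designated={"center": "fan-center"})


def make_bd_chunk(a: int, b: int, coupling: float = 0.01) -> WeightedGraph:
    """Fan-like Birth-death amplifier chunk: a hub clique of ``a`` nodes and
    ``b`` two-node blades.

    Hub-hub edges have weight 1, within-blade edges weight 1, and each
    blade node is joined to every hub node with the small ``coupling``
    weight so that distinct blades interact only rarely (through the hub).
    With ``a = 1`` this degenerates to a fan.
    """
    if a < 1 or b < 1:
        raise GraphValidationError(f"chunk needs a >= 1 hub nodes and b >= 1 blades, got a={a}, b={b}")
    if not (coupling > 0):
        raise GraphValidationError(f"coupling must be positive, got {coupling}")
    hubs = [f"hub-{i}" for i in range(a)]
    nodes = list(hubs)
    edges = [(hubs[i], hubs[j], 1.0) for i in range(a) for j in range(i + 1, a)]
    blades: list[tuple[str, str]] = []
    for i in range(b):
        x, y = f"blade-{i}-a", f"blade-{i}-b"
        nodes += [x, y]
        blades.append((x, y))
        edges.append((x, y, 1.0))
        for h in hubs:
            edges.append((h, x, coupling))
            edges.append((h, y, coupling))
    sym = SymmetrySpec(single_groups=(tuple(hubs),), pair_groups=(tuple(blades),))
    return WeightedGraph(nodes, edges, family="bd-chunk", symmetry=sym)


@dataclass(frozen=True)
class ANParams:
    """Parameters of the composite simultaneous Bd/dB amplifier.

    Attributes
    ----------
    a : int
        Hub size of the Birth-death chunk (``a >= 1``).
    b : int
        Number of two-node blades in the Birth-death chunk (``b >= 1``).
    f : int
        Node count of the fan (death-Birth) chunk; must be odd and >= 3,
        i.e. ``f = 2m + 1`` for ``m`` blades.
    t : float
        Separation parameter, ``t > 1`` (intended ``t >> 1``).  The single
        connecting edge has weight ``t**-3``, and the Birth-death chunk is
        uniformly rescaled so the total weight of the other edges at its
        designated endpoint ``u`` is ``t**-1``; the fan is built so the
        total weight of the other edges at its center ``v`` is exactly 1.
    """

    a: int
    b: int
    f: int
    t: float = 100.0

    def __post_init__(self) -> None:
        if self.a < 1:
            raise GraphValidationError(f"a must be >= 1, got {self.a}")
        if self.b < 1:
            raise GraphValidationError(f"b must be >= 1, got {self.b}")
        if self.f < 3 or self.f % 2 == 0:
            raise GraphValidationError(f"f must be odd and >= 3, got {self.f}")
        if not (self.t > 1):
            raise GraphValidationError(f"t must exceed 1, got {self.t}")

    @property
    def m(self) -> int:
        """Number of fan blades, ``(f - 1) / 2``."""
        return (self.f - 1) // 2

    @property
    def N(self) -> int:
        """Total population size ``a + 2b + f``."""
        return self.a + 2 * self.b + self.f


def make_amplifier_AN(params: ANParams, *, bd_coupling: float | None = None) -> WeightedGraph:
    """Composite amplifier: a Birth-death chunk and a fan chunk joined by
    one very weak edge.

    The Birth-death chunk is :func:`make_bd_chunk` (hub clique plus
    blades); the death-Birth chunk is a fan whose hub coupling is set to
    ``1 / (2m)`` so the total weight at its center ``v`` is exactly 1.
    The designated hub node ``u = hub-0`` and the fan center
    ``v = fan-center`` are joined by an edge of weight ``t**-3``, and
    every Birth-death-chunk edge is scaled by a common factor so that the
    total weight of ``u``'s other incident edges is ``t**-1`` (uniform
    scaling leaves the chunk's internal dynamics unchanged).  The weight
    asymmetry at the two endpoints makes offspring flow across the
    connecting edge mostly ``u -> v`` under Birth-death updating and
    mostly ``v -> u`` under death-Birth updating.

    ``bd_coupling`` is the pre-scaling blade-hub weight inside the
    Birth-death chunk; it defaults to ``1 / t`` (rare within-chunk
    interactions, the same motif as the fan).

    Designated endpoints are retrievable as ``G.designated["u"]`` and
    ``G.designated["v"]``.
    """
    a, b, f, t = params.a, params.b, params.f, params.t
    m = params.m
    if bd_coupling is None:
        bd_coupling = 1.0 / t
    if not (bd_coupling > 0):
        raise GraphValidationError(f"bd_coupling must be positive, got {bd_coupling}")

    # Birth-death chunk, uniformly scaled so u's within-chunk weight totals 1/t.
    pre_total_u = (a - 1) * 1.0 + 2 * b * bd_coupling
    scale = (1.0 / t) / pre_total_u
    chunk = make_bd_chunk(a, b, bd_coupling)
    edges = [(u, v, w * scale) for u, v, w in chunk.edges()]
    nodes = list(chunk.nodes)

    # Fan chunk with center weight total exactly 1.
    fan = make_fan(m, hub_coupling=1.0 / (2 * m))
    nodes += list(fan.nodes)
    edges += list(fan.edges())

    # The single connecting edge.
    edges.append(("hub-0", "fan-center", t ** -3))

    hubs = tuple(f"hub-{i}" for i in range(1, a))
    bd_blades = tuple((f"blade-{i}-a", f"blade-{i}-b") for i in range(b))
    fan_blades = tuple((f"fan-blade-{i}-a", f"fan-blade-{i}-b") for i in range(m))
    sym = SymmetrySpec(
        tracked=("hub-0", "fan-center"),
        single_groups=(hubs,) if hubs else (),
        pair_groups=(bd_blades, fan_blades),
    )
    return WeightedGraph(
        nodes, edges, family="an", symmetry=sym,
        designated={"u": "hub-0", "v": "fan-center"},
    )


# -- edge-list text format -------------------------------------------------


def write_edge_list(G: WeightedGraph, path: str | Path) -> None:
    """Write a graph as tab-separated ``node_a  node_b  weight`` lines.

    Weights are written with ``repr`` so a round trip through
    :func:`read_edge_list` reproduces them bit-for-bit.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# moranamp weighted edge list\n")
        for u, v, w in G.edges():
            fh.write(f"{u}\t{v}\t{w!r}\n")


def read_edge_list(path: str | Path) -> WeightedGraph:
    """Read a weighted edge list written by :func:`write_edge_list` (or by hand).

    Three tab-separated columns per line; ``#``-prefixed lines and blank
    lines are ignored.  Node order is order of first appearance.  Rejects
    duplicate edges, self-loops and non-positive weights.
    """
    path = Path(path)
    nodes: list[str] = []
    seen: set[str] = set()
    edges: list[tuple[str, str, float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise GraphValidationError(
                f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}")
        u, v, ws = parts
        try:
            w = float(ws)
        except ValueError:
            raise GraphValidationError(f"{path}:{lineno}: bad weight {ws!r}") from None
        for x in (u, v):
            if x not in seen:
                seen.add(x)
                nodes.append(x)
        edges.append((u, v, w))
    return WeightedGraph(nodes, edges)
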