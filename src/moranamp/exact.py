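"""Exact fixation probabilities by linear solve of the absorbing Markov chain.

Two backends:

* **full-state** -- enumerates all ``2**N`` mutant configurations as
  N-bit integers and solves the absorption system on the transient
  subspace with a sparse direct solver.  Capped at ``N <= 20``.
* **lumped** -- exploits node symmetries declared by a graph's
  :class:`~moranamp.graphs.SymmetrySpec` (attached by the family
  constructors) to aggregate configurations into orbit classes: mutant
  counts for exchangeable nodes, per-blade count multisets for
  exchangeable two-node blades, and individually tracked special nodes.
  Classes are discovered by breadth-first search from the initial
  configurations, with transition probabilities computed on one
  representative per class.  Exactness of the lumping is a property of
  the graph's automorphism group; :func:`verify_lumpability` checks it
  exhaustively on small instances.

Both backends solve ``(D - Q) x = b`` where ``Q`` holds the
configuration-changing transition probabilities among transient states,
``D`` its row sums, and ``b`` the one-step probabilities of jumping to
the all-mutant state (self-loops cancel out of the absorption system).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix, identity
from scipy.sparse.linalg import spsolve

from .dynamics import FixationResult, ProcessSpec, _event_matrix, flip_probabilities
from .graphs import SymmetrySpec, WeightedGraph

__all__ = [
    "FULL_STATE_CAP",
    "CapacityError",
    "UnsupportedFamilyError",
    "LumpabilityError",
    "AbsorbingChain",
    "build_absorbing_chain",
    "fixation_by_state",
    "solve_fixation_exact",
    "solve_fixation_lumped",
    "verify_lumpability",
]

FULL_STATE_CAP = 20
_SOLVER_TOL = 1e-12  # documented tolerance of the sparse direct solve


class CapacityError(RuntimeError):
    """State space too large for the requested backend."""


class UnsupportedFamilyError(RuntimeError):
    """The graph carries no symmetry description usable by the lumped solver."""


class LumpabilityError(RuntimeError):
    """A declared symmetry is not an exact lumping of the chain."""


@dataclass
class AbsorbingChain:
    """A (possibly lumped) absorbing chain: row-stochastic transition matrix
    ``P`` over ``states``, with extinction and fixation state indices."""

    states: list
    P: csr_matrix
    extinction: int
    fixation: int


def _bits_table(N: int) -> np.ndarray:
    states = np.arange(1 << N, dtype=np.int64)
    return ((states[:, None] >> np.arange(N)) & 1).astype(np.uint8)


def _flip_transitions(G: WeightedGraph, spec: ProcessSpec):
    """COO triples of configuration-changing transitions over all 2**N states."""
    N = G.N
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    data: list[np.ndarray] = []
    full = (1 << N) - 1
    for s in range(1, full):
        bits = np.array([(s >> i) & 1 for i in range(N)], dtype=np.uint8)
        p = flip_probabilities(G, bits, spec)
        (idx,) = np.nonzero(p)
        if idx.size == 0:
            continue
        rows.append(np.full(idx.size, s, dtype=np.int64))
        cols.append(s ^ (np.int64(1) << idx.astype(np.int64)))
        data.append(p[idx])
    if rows:
        return (np.concatenate(rows), np.concatenate(cols), np.concatenate(data))
    return (np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0, float))


def _check_cap(N: int) -> None:
    if N > FULL_STATE_CAP:
        raise CapacityError(
            f"full-state backend enumerates 2^{N} configurations (cap N <= "
            f"{FULL_STATE_CAP}); use the lumped or Monte Carlo backends")


def build_absorbing_chain(G: WeightedGraph, spec: ProcessSpec) -> AbsorbingChain:
    """Full 2**N-state chain with explicit self-loops (row-stochastic)."""
    G.require_connected()
    _check_cap(G.N)
    n = 1 << G.N
    rows, cols, data = _flip_transitions(G, spec)
    T = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    diag = 1.0 - np.asarray(T.sum(axis=1)).ravel()
    P = T + csr_matrix((diag, (np.arange(n), np.arange(n))), shape=(n, n))
    return AbsorbingChain(states=list(range(n)), P=P.tocsr(),
                          extinction=0, fixation=n - 1)


def fixation_by_state(G: WeightedGraph, spec: ProcessSpec) -> np.ndarray:
    """Fixation probability from every configuration (indexed by bitmask)."""
    G.require_connected()
    _check_cap(G.N)
    N = G.N
    n = 1 << N
    full = n - 1
    rows, cols, data = _flip_transitions(G, spec)
    T = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    transient = np.arange(1, full)
    Ttt = T[transient][:, transient]
    rowsum = np.asarray(T[transient].sum(axis=1)).ravel()
    A = csr_matrix((rowsum, (np.arange(len(transient)),) * 2)) - Ttt
    b = T[:, [full]].toarray().ravel()[transient]
    x = spsolve(A.tocsc(), b)
    out = np.empty(n, dtype=float)
    out[0] = 0.0
    out[full] = 1.0
    out[transient] = x
    return out


def _init_mask(G: WeightedGraph, init) -> int | None:
    """Bitmask for a set/node init, or None for 'uniform'."""
    if isinstance(init, str):
        if init == "uniform":
            return None
        return 1 << G.index(init)
    mask = 0
    for v in init:
        mask |= 1 << G.index(v)
    return mask


def solve_fixation_exact(G: WeightedGraph, spec: ProcessSpec,
                         init="uniform") -> FixationResult:
    """Exact fixation probability via the full-state linear solve.

    ``init`` is ``"uniform"`` (average of the ``N`` single-mutant
    solutions), a node label, or an iterable of node labels.  The empty
    and full sets return 0 and 1 exactly.
    """
    G.require_connected()
    mask = _init_mask(G, init)
    if mask == 0:
        return FixationResult(0.0, "exact", extra={"tol": 0.0})
    if mask == (1 << G.N) - 1:
        return FixationResult(1.0, "exact", extra={"tol": 0.0})
    x = fixation_by_state(G, spec)
    if mask is None:
        p = float(np.mean([x[1 << i] for i in range(G.N)]))
    else:
        p = float(x[mask])
    return FixationResult(p, "exact", extra={"tol": _SOLVER_TOL})


# -- symmetry-lumped backend ------------------------------------------------


class _Lumper:
    """Index machinery turning occupancy vectors into orbit keys."""

    def __init__(self, G: WeightedGraph, sym: SymmetrySpec):
        idx = G.index
        self.tracked = np.array([idx(v) for v in sym.tracked], dtype=np.int64)
        self.singles = [np.array([idx(v) for v in grp], dtype=np.int64)
                        for grp in sym.single_groups]
        self.pairs = [
            (np.array([idx(a) for a, _ in grp], dtype=np.int64),
             np.array([idx(b) for _, b in grp], dtype=np.int64))
            for grp in sym.pair_groups
        ]
        covered = set(self.tracked.tolist())
        for g in self.singles:
            covered.update(g.tolist())
        for a, b in self.pairs:
            covered.update(a.tolist())
            covered.update(b.tolist())
        if covered != set(range(G.N)) or len(covered) != G.N:
            raise UnsupportedFamilyError(
                "symmetry groups must partition the node set exactly")

    def key(self, bits: np.ndarray) -> tuple:
        t = tuple(int(bits[i]) for i in self.tracked)
        s = tuple(int(bits[g].sum()) for g in self.singles)
        p = []
        for a, b in self.pairs:
            per = bits[a].astype(np.int64) + bits[b].astype(np.int64)
            p.append((int(np.sum(per == 1)), int(np.sum(per == 2))))
        return (t, s, tuple(p))


def solve_fixation_lumped(G: WeightedGraph, spec: ProcessSpec,
                          init="uniform") -> FixationResult:
    """Fixation probability via the symmetry-lumped chain.

    Requires a graph built by one of the family constructors (or any graph
    with a valid :class:`~moranamp.graphs.SymmetrySpec` attached); raises
    :class:`UnsupportedFamilyError` otherwise.  Agrees with
    :func:`solve_fixation_exact` to solver tolerance whenever the declared
    symmetry is an exact lumping (verified by test on small instances).
    """
    G.require_connected()
    if G.symmetry is None:
        raise UnsupportedFamilyError(
            f"graph (family={G.family!r}) has no symmetry description; "
            "use the exact or Monte Carlo backends")
    lmp = _Lumper(G, G.symmetry)
    N = G.N

    # Seed configurations: every single-mutant start, plus the requested set.
    seeds: list[np.ndarray] = []
    for i in range(N):
        bits = np.zeros(N, dtype=np.uint8)
        bits[i] = 1
        seeds.append(bits)
    if not isinstance(init, str):  # explicit mutant set
        bits = np.zeros(N, dtype=np.uint8)
        for v in init:
            bits[G.index(v)] = 1
        seeds.append(bits)

    class_of: dict[tuple, int] = {}
    reps: list[np.ndarray] = []

    def intern(bits: np.ndarray) -> int:
        k = lmp.key(bits)
        cid = class_of.get(k)
        if cid is None:
            cid = len(reps)
            class_of[k] = cid
            reps.append(bits.copy())
        return cid

    frontier = [intern(b) for b in seeds]
    transitions: dict[int, list[tuple[int, float]]] = {}
    pos = 0
    order = list(dict.fromkeys(frontier))
    seen = set(order)
    while pos < len(order):
        cid = order[pos]
        pos += 1
        bits = reps[cid]
        k = int(bits.sum())
        if k == 0 or k == N:
            continue
        p = flip_probabilities(G, bits, spec)
        agg: dict[int, float] = {}
        for v in np.flatnonzero(p):
            nb = bits.copy()
            nb[v] ^= 1
            tid = intern(nb)
            agg[tid] = agg.get(tid, 0.0) + float(p[v])
            if tid not in seen:
                seen.add(tid)
                order.append(tid)
        transitions[cid] = list(agg.items())

    n_cls = len(reps)
    counts = np.array([int(b.sum()) for b in reps])
    ext_ids = np.flatnonzero(counts == 0)
    fix_ids = np.flatnonzero(counts == N)
    x = np.zeros(n_cls)
    if fix_ids.size:
        fix = int(fix_ids[0])
        x[fix] = 1.0
        transient = np.flatnonzero((counts > 0) & (counts < N))
        tpos = {int(c): i for i, c in enumerate(transient)}
        rows, cols, data = [], [], []
        b = np.zeros(len(transient))
        rowsum = np.zeros(len(transient))
        for cid in transient:
            i = tpos[int(cid)]
            for tid, pr in transitions[int(cid)]:
                rowsum[i] += pr
                if tid == fix:
                    b[i] += pr
                elif tid in tpos:
                    rows.append(i)
                    cols.append(tpos[tid])
                    data.append(pr)
        nt = len(transient)
        A = (csr_matrix((rowsum, (np.arange(nt), np.arange(nt))), shape=(nt, nt))
             - coo_matrix((data, (rows, cols)), shape=(nt, nt)).tocsr())
        x[transient] = spsolve(A.tocsc(), b)

    extra = {"n_classes": n_cls, "tol": _SOLVER_TOL}
    if isinstance(init, str) and init == "uniform":
        vals = [x[frontier[i]] for i in range(N)]
        return FixationResult(float(np.mean(vals)), "lumped", extra=extra)
    if isinstance(init, str):
        return FixationResult(float(x[frontier[G.index(init)]]), "lumped", extra=extra)
    return FixationResult(float(x[class_of[lmp.key(seeds[-1])]]), "lumped", extra=extra)


def verify_lumpability(G: WeightedGraph, spec: ProcessSpec, atol: float = 1e-12,
                       max_n: int = 14) -> None:
    """Exhaustively check that the graph's declared symmetry is an exact lumping.

    For every configuration, the distribution over *target classes* must
    depend only on the configuration's own class.  Raises
    :class:`LumpabilityError` on the first mismatch.  Limited to small
    graphs (``N <= max_n``).
    """
    G.require_connected()
    if G.symmetry is None:
        raise UnsupportedFamilyError("graph has no symmetry description")
    if G.N > max_n:
        raise CapacityError(f"exhaustive lumpability check limited to N <= {max_n}")
    lmp = _Lumper(G, G.symmetry)
    N = G.N
    seen: dict[tuple, dict[tuple, float]] = {}
    for s in range(1, (1 << N) - 1):
        bits = np.array([(s >> i) & 1 for i in range(N)], dtype=np.uint8)
        key = lmp.key(bits)
        p = flip_probabilities(G, bits, spec)
        dist: dict[tuple, float] = {}
        for v in np.flatnonzero(p):
            nb = bits.copy()
            nb[v] ^= 1
            nk = lmp.key(nb)
            dist[nk] = dist.get(nk, 0.0) + float(p[v])
        if key not in seen:
            seen[key] = dist
            continue
        ref = seen[key]
        if set(ref) != set(dist) or any(abs(ref[k] - dist[k]) > atol for k in ref):
            raise LumpabilityError(
                f"configurations in class {key} have differing class-transition "
                "distributions; the declared symmetry is not an exact lumping")
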