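"""Closed forms, first-step bias, amplifier classification, and the
coarse-grained coupling model of the composite amplifier.

The complete-graph baseline is

    rho_Bd(K_N) = (1 - 1/r) / (1 - r**-N)
    rho_dB(K_N) = ((N - 1) / N) * (1 - 1/r) / (1 - r**-(N-1))

with the analytic limit ``1/N`` at ``r = 1``.  A graph is an *amplifier*
(resp. *suppressor*) under a given update rule if its uniform-initialization
fixation probability exceeds (falls below) this baseline at the same N and r.

The module also provides numerical verifications of two impossibility
statements for single-mutant quantities:

* at ``r = 1``, no starting node beats the ``1/N`` baseline under both
  update rules at once (checked through the neutral closed forms);
* for the first-step survival probability ``gamma`` (the chance that the
  first configuration-changing event preserves the lone mutant), no node
  beats the complete-graph value under both rules at once.  Under Bd the
  closed form is ``gamma = r / (r + T(u))`` with ``T(u)`` the node
  temperature.

Neither statement is proved here; they are exercised as invariants over
random-fixture sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import (FixationResult, ProcessSpec, _event_matrix,
                       estimate_fixation_probability, replacement_distribution,
                       state_to_bits)
from .exact import solve_fixation_exact, solve_fixation_lumped
from .graphs import ANParams, WeightedGraph, make_bd_chunk, make_complete, \
    make_fan, make_amplifier_AN, temperature

__all__ = [
    "InvariantViolationError",
    "rho_complete",
    "GammaResult",
    "gamma_first_step",
    "gamma_bd_closed_form",
    "gamma_db_closed_form",
    "gamma_first_step_mc",
    "neutral_fixation_closed_form",
    "neutral_start_trichotomy",
    "first_step_trichotomy",
    "AmplifierVerdict",
    "classify",
    "scan_fitness_grid",
    "ChunkCouplingInputs",
    "CoarseChainResult",
    "chunk_coupling_approximation",
    "approximate_an_fixation",
]

EXACT_VERDICT_TOL = 1e-9


class InvariantViolationError(AssertionError):
    """A numerically checked impossibility statement was violated."""


def rho_complete(N: int, r: float, kind: str) -> float:
    """Fixation probability of a single mutant on the complete graph ``K_N``.

    ``kind`` is ``"Bd"`` or ``"dB"``; both reduce to ``1/N`` at ``r = 1``
    (handled analytically, not by perturbation).  Evaluated through
    ``expm1`` for stability near ``r = 1``.
    """
    kind = ProcessSpec(kind, 1.0).kind
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    r = float(r)
    if not (r > 0) or not math.isfinite(r):
        raise ValueError(f"r must be positive and finite, got {r}")
    if r == 1.0:
        return 1.0 / N
    x = math.log(r)
    if kind == "Bd":
        return math.expm1(-x) / math.expm1(-N * x)
    return (N - 1) / N * math.expm1(-x) / math.expm1(-(N - 1) * x)


# -- first-step survival (gamma) --------------------------------------------


@dataclass
class GammaResult:
    """First-step survival probability of a lone mutant at ``node``.

    ``gamma = p_plus / (p_plus + p_minus)`` where ``p_plus`` (``p_minus``)
    is the one-step probability that the mutant count increases
    (decreases); the complete-graph baseline at the same N and r is
    included for comparison.
    """

    kind: str
    r: float
    node: str
    gamma: float
    p_plus: float
    p_minus: float
    baseline_complete: float


def _first_step_masses(G: WeightedGraph, u: str, spec: ProcessSpec) -> tuple[float, float]:
    bits = state_to_bits(G, [u])
    P = _event_matrix(G.W, G._deg, bits, spec.r, spec.is_bd)
    i = G.index(u)
    p_plus = float(P[i].sum() - P[i, i])   # mutant reproduces onto a resident
    p_minus = float(P[:, i].sum() - P[i, i])  # a resident replaces the mutant
    return p_plus, p_minus


@lru_cache(maxsize=256)
def _gamma_complete(N: int, r: float, kind: str) -> float:
    K = make_complete(N)
    p_plus, p_minus = _first_step_masses(K, K.nodes[0], ProcessSpec(kind, r))
    return p_plus / (p_plus + p_minus)


def gamma_first_step(G: WeightedGraph, u: str, spec: ProcessSpec) -> GammaResult:
    """Probability that the first configuration-changing event preserves the
    single initial mutant at ``u``.

    Computed generically by conditioning the one-step event distribution on
    configuration-changing events; the Bd closed form ``r / (r + T(u))``
    and the dB sum formula are available as cross-checked fast paths
    (:func:`gamma_bd_closed_form`, :func:`gamma_db_closed_form`).
    """
    G.require_connected()
    p_plus, p_minus = _first_step_masses(G, u, spec)
    return GammaResult(
        kind=spec.kind, r=spec.r, node=u,
        gamma=p_plus / (p_plus + p_minus),
        p_plus=p_plus, p_minus=p_minus,
        baseline_complete=_gamma_complete(G.N, spec.r, spec.kind),
    )


def gamma_bd_closed_form(G: WeightedGraph, u: str, r: float) -> float:
    """Bd fast path: ``gamma = r / (r + T(u))``."""
    return r / (r + temperature(G, u))


def gamma_db_closed_form(G: WeightedGraph, u: str, r: float) -> float:
    """dB fast path: ``gamma = S / (1 + S)`` with
    ``S = sum_{v ~ u} r w(u,v) / (deg(v) + (r - 1) w(u,v))``."""
    G.require_connected()
    i = G.index(u)
    w = G.W[i]
    (nbr,) = np.nonzero(w)
    S = float(np.sum(r * w[nbr] / (G._deg[nbr] + (r - 1.0) * w[nbr])))
    return S / (1.0 + S)


def gamma_first_step_mc(G: WeightedGraph, u: str, spec: ProcessSpec,
                        replicates: int, seed: int) -> tuple[float, float]:
    """Monte Carlo estimate of gamma with its binomial standard error.

    Until the first configuration change the state is frozen, so the first
    changing event is an exact categorical draw from the conditional
    one-step distribution; replicates are sampled directly from it.
    """
    dist = replacement_distribution(G, [u], spec)
    probs = np.array([p for _, _, p in dist.events])
    probs = probs / probs.sum()
    survives = np.array([src == u for src, _, _ in dist.events])
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(probs), size=replicates, p=probs)
    hits = int(survives[draws].sum())
    p = hits / replicates
    return p, float(np.sqrt(p * (1 - p) / replicates))


# -- neutral closed forms ----------------------------------------------------


def neutral_fixation_closed_form(G: WeightedGraph, v: str, kind: str) -> float:
    """Neutral (r = 1) fixation probability of a single mutant at ``v``.

    Bd: ``(1/deg(v)) / sum_u (1/deg(u))`` -- cold (low-degree) nodes are
    replaced rarely and make good starting points.
    dB: ``deg(v) / sum_u deg(u)`` -- high-degree nodes win the competition
    for vacancies more often.

    Both follow from a martingale argument on reproductive values; the test
    suite verifies them against the exact solver on random weighted graphs
    before they are relied upon.
    """
    G.require_connected()
    kind = ProcessSpec(kind, 1.0).kind
    deg = G._deg
    i = G.index(v)
    if kind == "Bd":
        inv = 1.0 / deg
        return float(inv[i] / inv.sum())
    return float(deg[i] / deg.sum())


# -- trichotomy checks -------------------------------------------------------


def _trichotomy(below_bd: bool, below_db: bool, equal_bd: bool, equal_db: bool) -> str:
    if equal_bd and equal_db:
        return "both-equal"
    if below_bd and below_db:
        return "both-below"
    if below_bd:
        return "Bd-below"
    if below_db:
        return "dB-below"
    raise InvariantViolationError(
        "trichotomy violated: neither quantity is below its complete-graph "
        "value and they are not both equal")


def neutral_start_trichotomy(G: WeightedGraph, v: str, tol: float = 1e-12) -> str:
    """Neutral-start trichotomy for node ``v``.

    Compares the neutral fixation probabilities from ``v`` under both
    update rules against the complete-graph value ``1/N``.  Returns one of
    ``{"Bd-below", "dB-below", "both-below", "both-equal"}``; a state in
    which both strictly exceed ``1/N`` raises
    :class:`InvariantViolationError`.
    """
    base = 1.0 / G.N
    bd = neutral_fixation_closed_form(G, v, "Bd")
    db = neutral_fixation_closed_form(G, v, "dB")
    return _trichotomy(bd < base - tol, db < base - tol,
                       abs(bd - base) <= tol, abs(db - base) <= tol)


def first_step_trichotomy(G: WeightedGraph, u: str, r: float, tol: float = 1e-12) -> str:
    """First-step-survival trichotomy for node ``u`` at fitness ``r >= 1``.

    Compares ``gamma_Bd(G, u)`` against ``r / (r + 1)`` and
    ``gamma_dB(G, u)`` against the complete-graph value at the same N and
    r.  A node with above-average temperature (``T(u) > 1``) necessarily
    lands in the Bd-below branch.
    """
    if r < 1:
        raise ValueError(f"the first-step trichotomy is stated for r >= 1, got {r}")
    g_bd = gamma_first_step(G, u, ProcessSpec("Bd", r))
    g_db = gamma_first_step(G, u, ProcessSpec("dB", r))
    return _trichotomy(
        g_bd.gamma < g_bd.baseline_complete - tol,
        g_db.gamma < g_db.baseline_complete - tol,
        abs(g_bd.gamma - g_bd.baseline_complete) <= tol,
        abs(g_db.gamma - g_db.baseline_complete) <= tol,
    )


# -- amplifier classification ------------------------------------------------


@dataclass
class AmplifierVerdict:
    """Comparison of a graph's uniform-init fixation probability with the
    complete-graph baseline at the same N and r."""

    kind: str
    r: float
    rho_graph: float
    rho_baseline: float
    verdict: str  # "amplifier" | "suppressor" | "equivalent" | "inconclusive"
    tolerance: float
    method: str
    std_error: float | None = None

    @property
    def ratio(self) -> float:
        return self.rho_graph / self.rho_baseline


def _fixation_backend(G: WeightedGraph, spec: ProcessSpec, method: str,
                      replicates: int, seed: int) -> FixationResult:
    if method == "exact":
        return solve_fixation_exact(G, spec)
    if method == "lumped":
        return solve_fixation_lumped(G, spec)
    if method in ("mc", "monte-carlo"):
        return estimate_fixation_probability(G, "uniform", spec, replicates, seed)
    raise ValueError(f"unknown backend {method!r}")


def classify(G: WeightedGraph, spec: ProcessSpec, method: str = "exact",
             tol: float = EXACT_VERDICT_TOL, replicates: int = 20000,
             seed: int = 0, z: float = 2.576) -> AmplifierVerdict:
    """Classify ``G`` as amplifier / suppressor / equivalent under ``spec``.

    Exact and lumped backends use the absolute tolerance ``tol`` (default
    1e-9, wide enough to absorb solver noise but far below any real
    amplification effect).  The Monte Carlo backend instead applies a 99%
    confidence rule: when the interval straddles the baseline the verdict
    is ``"inconclusive"``.
    """
    G.require_connected()
    res = _fixation_backend(G, spec, method, replicates, seed)
    base = rho_complete(G.N, spec.r, spec.kind)
    if res.method == "monte-carlo":
        half = z * (res.std_error or 0.0)
        if res.probability > base + half:
            verdict = "amplifier"
        elif res.probability < base - half:
            verdict = "suppressor"
        else:
            verdict = "inconclusive"
        return AmplifierVerdict(spec.kind, spec.r, res.probability, base,
                                verdict, half, res.method, res.std_error)
    if res.probability > base + tol:
        verdict = "amplifier"
    elif res.probability < base - tol:
        verdict = "suppressor"
    else:
        verdict = "equivalent"
    return AmplifierVerdict(spec.kind, spec.r, res.probability, base,
                            verdict, tol, res.method)


def scan_fitness_grid(G: WeightedGraph, kind: str, r_grid: Sequence[float],
                      backend: str = "exact", replicates: int = 20000,
                      seed: int = 0) -> pd.DataFrame:
    """Fixation probability versus the complete-graph baseline over a fitness grid.

    Returns a DataFrame with columns
    ``r, rho_graph, rho_complete, ratio, method, std_error``; a backend
    failure at a grid point is recorded as a NaN row, never dropped.
    """
    if len(r_grid) == 0:
        raise ValueError("r_grid must be nonempty")
    if list(r_grid) != sorted(r_grid):
        raise ValueError("r_grid must be sorted")
    rows = []
    for j, r in enumerate(r_grid):
        base = rho_complete(G.N, r, kind)
        try:
            res = _fixation_backend(G, ProcessSpec(kind, r), backend,
                                    replicates, seed + j)
            rows.append((r, res.probability, base, res.probability / base,
                         res.method, res.std_error))
        except Exception as exc:  # noqa: BLE001 - recorded, not dropped
            rows.append((float(r), float("nan"), base, float("nan"),
                         f"{backend}-failed: {exc}", None))
    return pd.DataFrame(rows, columns=["r", "rho_graph", "rho_complete",
                                       "ratio", "method", "std_error"])


# -- coarse-grained coupling model of the composite amplifier ----------------


@dataclass(frozen=True)
class ChunkCouplingInputs:
    """Inputs of the coarse four-state model of the composite amplifier.

    The two chunks interact only through one very weak edge, so the
    process is approximated by the absorbing chain over
    ``{all-resident, Bd-chunk fixed ("half done"), dB-chunk fixed,
    all-mutant}``.  ``p_half_*`` are the probabilities that a uniformly
    placed initial mutant fixes on its own chunk; ``mig_*`` are per-step
    migration rates across the connecting edge evaluated at the half-done
    configurations; ``inv_*`` are the corresponding single-invader success
    probabilities in the opposite chunk.
    """

    p_half_bd: float
    p_half_db: float
    # at the Bd-chunk-fixed configuration:
    mig_mut_from_bd: float   # mutant offspring crosses into the fan chunk
    mig_res_into_bd: float   # resident offspring crosses back
    inv_mut_into_db: float   # a lone mutant at the fan entry point fixes there
    inv_res_into_bd: float   # a lone resident at the Bd-chunk entry point fixes there
    # at the dB-chunk-fixed configuration:
    mig_mut_from_db: float
    mig_res_into_db: float
    inv_mut_into_bd: float
    inv_res_into_db: float

    def __post_init__(self) -> None:
        for name in ("mig_mut_from_bd", "mig_res_into_bd",
                     "mig_mut_from_db", "mig_res_into_db"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"migration rate {name} must be positive")
        for name in ("p_half_bd", "p_half_db", "inv_mut_into_db",
                     "inv_res_into_bd", "inv_mut_into_bd", "inv_res_into_db"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")


@dataclass
class CoarseChainResult:
    """Absorption analysis of the coarse chain."""

    fixation_probability: float
    p_fix_given_half_bd: float
    p_fix_given_half_db: float
    transition_matrix: np.ndarray  # rows: extinct, half-Bd, half-dB, fixed


def chunk_coupling_approximation(inputs: ChunkCouplingInputs) -> CoarseChainResult:
    """Solve the coarse absorbing chain over the four chunk-level states.

    From a half-done state the next decisive event is a race between a
    successful mutant invasion of the other chunk (rate
    ``migration x invasion success``) and a successful resident
    re-invasion; unsuccessful invasions return to the same half-done
    state, so the chain's jump probabilities are the normalized success
    rates.  With symmetric rates and invasion probabilities the chain
    reduces to a fair gambler's ruin (fixation probability 1/2 from either
    half-done state).
    """
    s_fix_bd = inputs.mig_mut_from_bd * inputs.inv_mut_into_db
    s_ext_bd = inputs.mig_res_into_bd * inputs.inv_res_into_bd
    s_fix_db = inputs.mig_mut_from_db * inputs.inv_mut_into_bd
    s_ext_db = inputs.mig_res_into_db * inputs.inv_res_into_db

    # states: 0 extinct, 1 half-Bd, 2 half-dB, 3 fixed
    P = np.zeros((4, 4))
    P[0, 0] = P[3, 3] = 1.0
    P[1, 3] = s_fix_bd / (s_fix_bd + s_ext_bd)
    P[1, 0] = 1.0 - P[1, 3]
    P[2, 3] = s_fix_db / (s_fix_db + s_ext_db)
    P[2, 0] = 1.0 - P[2, 3]

    # absorption into "fixed" from the transient states (direct here, but
    # solved as a linear system for transparency)
    Q = P[1:3, 1:3]
    b = P[1:3, 3]
    h = np.linalg.solve(np.eye(2) - Q, b)
    rho = inputs.p_half_bd * h[0] + inputs.p_half_db * h[1]
    return CoarseChainResult(float(rho), float(h[0]), float(h[1]), P)


def approximate_an_fixation(
    params: ANParams, spec: ProcessSpec, *, bd_coupling: float | None = None,
) -> tuple[CoarseChainResult, ChunkCouplingInputs]:
    """Chunk-coupling approximation of the composite amplifier's fixation
    probability, with all inputs computed from the chunk solvers.

    Chunk fixation and invasion probabilities are solved exactly (lumped)
    on the isolated chunks -- a good approximation because the connecting
    edge perturbs within-chunk dynamics only at order ``t**-2``.
    Migration rates are evaluated exactly on the full graph at the two
    half-done configurations.
    """
    G = make_amplifier_AN(params, bd_coupling=bd_coupling)
    u, v = G.designated["u"], G.designated["v"]
    iu, iv = G.index(u), G.index(v)
    n_bd = params.a + 2 * params.b
    N = params.N

    chunk_bd = make_bd_chunk(params.a, params.b,
                             bd_coupling if bd_coupling is not None else 1.0 / params.t)
    chunk_db = make_fan(params.m, hub_coupling=1.0 / (2 * params.m))

    rho_chunk_bd = solve_fixation_lumped(chunk_bd, spec).probability
    rho_chunk_db = solve_fixation_lumped(chunk_db, spec).probability
    p_half_bd = (n_bd / N) * rho_chunk_bd
    p_half_db = (params.f / N) * rho_chunk_db

    # Invasion success: a lone mutant at the entry node of a resident chunk,
    # and a lone resident (fitness ratio 1/r seen from its own side) in a
    # mutant-fixed chunk, i.e. one minus mutant re-fixation from the
    # complement of the entry node.
    inv_mut_into_bd = solve_fixation_lumped(chunk_bd, spec, init="hub-0").probability
    inv_mut_into_db = solve_fixation_lumped(chunk_db, spec, init="fan-center").probability
    rest_bd = [w for w in chunk_bd.nodes if w != "hub-0"]
    rest_db = [w for w in chunk_db.nodes if w != "fan-center"]
    inv_res_into_bd = 1.0 - solve_fixation_lumped(chunk_bd, spec, init=rest_bd).probability
    inv_res_into_db = 1.0 - solve_fixation_lumped(chunk_db, spec, init=rest_db).probability

    # Migration rates across the connecting edge at the half-done states,
    # read off the exact one-step event matrix of the full graph.
    bits_half_bd = np.zeros(N, dtype=np.uint8)
    for w in chunk_bd.nodes:
        bits_half_bd[G.index(w)] = 1
    bits_half_db = np.zeros(N, dtype=np.uint8)
    for w in chunk_db.nodes:
        bits_half_db[G.index(w)] = 1
    P1 = _event_matrix(G.W, G._deg, bits_half_bd, spec.r, spec.is_bd)
    P2 = _event_matrix(G.W, G._deg, bits_half_db, spec.r, spec.is_bd)

    inputs = ChunkCouplingInputs(
        p_half_bd=p_half_bd,
        p_half_db=p_half_db,
        mig_mut_from_bd=float(P1[iu, iv]),
        mig_res_into_bd=float(P1[iv, iu]),
        inv_mut_into_db=inv_mut_into_db,
        inv_res_into_bd=inv_res_into_bd,
        mig_mut_from_db=float(P2[iv, iu]),
        mig_res_into_db=float(P2[iu, iv]),
        inv_mut_into_bd=inv_mut_into_bd,
        inv_res_into_db=inv_res_into_db,
    )
    return chunk_coupling_approximation(inputs), inputs
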