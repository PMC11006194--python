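"""Single-step kernels and Monte Carlo estimation for the Moran process.

Two update rules are supported on a weighted graph with mutant fitness
``r`` (residents have fitness 1):

* **Bd (Birth-death)** -- an individual ``u`` reproduces with probability
  ``f(u) / F`` (fitness-proportional, ``F`` the total fitness), and the
  offspring replaces a neighbour ``v`` chosen with probability
  ``w(u, v) / deg(u)``.
* **dB (death-Birth)** -- an individual ``v`` dies with probability
  ``1 / N``, and the vacancy is filled by a neighbour ``u`` chosen with
  probability ``f(u) w(u, v) / sum_u' f(u') w(u', v)``.

Fitness enters the *birth* step only.  A replacement that copies a type
onto the same type changes nothing but still counts as a time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .graphs import WeightedGraph

__all__ = [
    "KINDS",
    "ProcessSpec",
    "AbsorbingStateError",
    "ReplacementDistribution",
    "replacement_distribution",
    "step",
    "simulate_to_absorption",
    "FixationResult",
    "estimate_fixation_probability",
]

KINDS = ("Bd", "dB")
_KIND_ALIASES = {"bd": "Bd", "db": "dB", "moran-bd": "Bd", "moran-db": "dB"}


@dataclass(frozen=True)
class ProcessSpec:
    """Which update rule to run and the relative mutant fitness ``r > 0``."""

    kind: str
    r: float = 1.0

    def __post_init__(self) -> None:
        kind = _KIND_ALIASES.get(str(self.kind).lower(), self.kind)
        if kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        object.__setattr__(self, "kind", kind)
        r = float(self.r)
        if not np.isfinite(r) or r <= 0:
            raise ValueError(f"mutant fitness r must be positive and finite, got {self.r}")
        object.__setattr__(self, "r", r)

    @property
    def is_bd(self) -> bool:
        return self.kind == "Bd"


class AbsorbingStateError(RuntimeError):
    """Raised when a one-step operation is asked to act on a homogeneous state."""


def state_to_bits(G: WeightedGraph, state: Iterable[str]) -> np.ndarray:
    """Convert a mutant node set into a 0/1 occupancy vector in node order."""
    bits = np.zeros(G.N, dtype=np.uint8)
    for v in state:
        bits[G.index(v)] = 1
    return bits


def _event_matrix(W: np.ndarray, deg: np.ndarray, bits: np.ndarray, r: float,
                  is_bd: bool) -> np.ndarray:
    """Probability ``P[u, v]`` that the next event is ``u`` replacing ``v``.

    Entries cover *all* ordered adjacent pairs (including same-type pairs,
    which leave the configuration unchanged); they sum to 1.
    """
    f = np.where(bits == 1, r, 1.0)
    if is_bd:
        return (f / f.sum())[:, None] * (W / deg[:, None])
    denom = f @ W  # competition mass at each dying node
    return (f[:, None] * W) / (len(f) * denom[None, :])


@dataclass(frozen=True)
class ReplacementDistribution:
    """One-step event distribution: configuration-changing events plus the
    aggregated probability that the step changes nothing."""

    events: tuple[tuple[str, str, float], ...]  # (source, target, probability)
    no_change: float

    def total(self) -> float:
        return self.no_change + sum(p for _, _, p in self.events)


def replacement_distribution(G: WeightedGraph, state: Iterable[str],
                             spec: ProcessSpec) -> ReplacementDistribution:
    """Distribution of the next replacement event from ``state``.

    Only configuration-changing events (source and target of different
    types) are listed individually; same-type replacements are aggregated
    into :attr:`ReplacementDistribution.no_change`.  Raises
    :class:`AbsorbingStateError` on a homogeneous state.
    """
    G.require_connected()
    bits = state_to_bits(G, state)
    k = int(bits.sum())
    if k == 0 or k == G.N:
        raise AbsorbingStateError("state is homogeneous; the process is absorbed")
    P = _event_matrix(G.W, G._deg, bits, spec.r, spec.is_bd)
    diff = bits[:, None] != bits[None, :]
    iu, iv = np.nonzero((P > 0) & diff)
    events = tuple(
        (G.nodes[i], G.nodes[j], float(P[i, j])) for i, j in zip(iu.tolist(), iv.tolist())
    )
    return ReplacementDistribution(events=events,
                                   no_change=float(1.0 - P[diff].sum()))


def flip_probabilities(G: WeightedGraph, bits: np.ndarray, spec: ProcessSpec) -> np.ndarray:
    """Per-node probability that the next step flips node ``v``'s type.

    Low-level kernel shared by the exact and lumped solvers;
    ``bits`` is a 0/1 occupancy vector.
    """
    P = _event_matrix(G.W, G._deg, bits, spec.r, spec.is_bd)
    diff = bits[:, None] != bits[None, :]
    return (P * diff).sum(axis=0)


def step(G: WeightedGraph, state: frozenset[str] | set[str], spec: ProcessSpec,
         rng: np.random.Generator) -> frozenset[str]:
    """Sample one Moran step and return the (possibly unchanged) mutant set.

    Sampling is by inverse CDF over the explicit event list in fixed node
    order, so identical generator states give identical trajectories.
    """
    dist = replacement_distribution(G, state, spec)
    x = rng.random()
    acc = 0.0
    state = frozenset(state)
    for source, target, p in dist.events:
        acc += p
        if x < acc:
            if source in state:  # mutant spreads onto a resident site
                return state | {target}
            return state - {target}
    return state


def simulate_to_absorption(
    G: WeightedGraph,
    state: Iterable[str],
    spec: ProcessSpec,
    rng: np.random.Generator,
    max_steps: int | None = None,
) -> tuple[frozenset[str], int, bool]:
    """Run :func:`step` until a homogeneous state (or ``max_steps``).

    Returns ``(final_state, steps_taken, absorbed)``.  Intended for small
    graphs and tests; :func:`estimate_fixation_probability` uses a faster
    kernel for replicated estimation.
    """
    current = frozenset(state)
    steps = 0
    while 0 < len(current) < G.N:
        if max_steps is not None and steps >= max_steps:
            return current, steps, False
        current = step(G, current, spec, rng)
        steps += 1
    return current, steps, True


@dataclass
class FixationResult:
    """A fixation probability together with how it was obtained.

    ``std_error`` and ``replicates`` are set for Monte Carlo estimates
    only; ``truncated`` counts replicates that hit ``max_steps`` without
    absorbing (these are excluded from the estimate, never silently
    counted).  ``extra`` carries backend metadata such as solver tolerance
    or lumped class counts.
    """

    probability: float
    method: str  # "exact" | "lumped" | "monte-carlo"
    std_error: float | None = None
    replicates: int | None = None
    seed: int | None = None
    truncated: int = 0
    extra: dict = field(default_factory=dict)


def _resolve_init(G: WeightedGraph, init, rng: np.random.Generator,
                  replicates: int) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Return ``(per-replicate start nodes, fixed start bits)``.

    Exactly one of the two is non-None: single-node starts (uniform or a
    named node) come back as an index array, an explicit mutant set as a
    bit vector reused by every replicate.
    """
    if isinstance(init, str):
        if init == "uniform":
            return rng.integers(0, G.N, size=replicates), None
        return np.full(replicates, G.index(init), dtype=np.int64), None
    bits = state_to_bits(G, init)
    return None, bits


def estimate_fixation_probability(
    G: WeightedGraph,
    init,
    spec: ProcessSpec,
    replicates: int,
    seed: int,
    max_steps: int | None = None,
    ci_method: str = "normal",
) -> FixationResult:
    """Monte Carlo fixation probability from independent seeded trajectories.

    Parameters
    ----------
    init
        ``"uniform"`` (a single initial mutant at a uniformly random node,
        drawn independently per replicate), a node label, or an iterable
        of node labels (a fixed initial mutant set).
    replicates, seed
        Number of trajectories and the master seed; per-replicate seeds
        are derived deterministically.
    max_steps
        Optional cap per trajectory.  Truncated replicates are reported in
        :attr:`FixationResult.truncated` and excluded from the estimate.
    ci_method
        ``"normal"`` for the binomial normal-approximation standard error,
        ``"clopper-pearson"`` to additionally store an exact 95% interval
        in ``extra["ci95"]``.

    Notes
    -----
    A numba-compiled kernel is used when numba is importable; otherwise a
    pure NumPy path runs the same process (statistically identical,
    slower).  Trajectories are reproducible for a fixed seed within a
    given backend.
    """
    G.require_connected()
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    start_nodes, start_bits = _resolve_init(G, init, rng, replicates)

    if start_bits is not None:
        k = int(start_bits.sum())
        if k == 0:
            return FixationResult(0.0, "monte-carlo", 0.0, replicates, seed)
        if k == G.N:
            return FixationResult(1.0, "monte-carlo", 0.0, replicates, seed)

    cap = max_steps if max_steps is not None else 2 ** 62
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=replicates, dtype=np.int64)

    from . import _fast

    if _fast.HAVE_NUMBA:
        outcomes = _fast.run_batch(
            G.W, G._deg, spec.r, spec.is_bd,
            start_nodes if start_nodes is not None else np.full(replicates, -1, np.int64),
            start_bits if start_bits is not None else np.zeros(0, np.uint8),
            rep_seeds, cap,
        )
    else:
        outcomes = _run_batch_python(G.W, G._deg, spec.r, spec.is_bd,
                                     start_nodes, start_bits, rep_seeds, cap)

    fixed = int(np.sum(outcomes == 1))
    lost = int(np.sum(outcomes == 0))
    truncated = int(np.sum(outcomes == -1))
    done = fixed + lost
    if done == 0:
        raise RuntimeError("all replicates hit max_steps before absorbing; "
                           "raise max_steps or reduce the graph's time scales")
    p = fixed / done
    se = float(np.sqrt(p * (1 - p) / done))
    extra: dict = {"fixed": fixed, "extinct": lost}
    if ci_method == "clopper-pearson":
        from scipy.stats import beta

        lo = 0.0 if fixed == 0 else float(beta.ppf(0.025, fixed, done - fixed + 1))
        hi = 1.0 if fixed == done else float(beta.ppf(0.975, fixed + 1, done - fixed))
        extra["ci95"] = (lo, hi)
    return FixationResult(p, "monte-carlo", se, replicates, seed,
                          truncated=truncated, extra=extra)


def _run_batch_python(W, deg, r, is_bd, start_nodes, start_bits, rep_seeds, cap):
    """NumPy reference kernel: one O(N) categorical draw per step."""
    N = W.shape[0]
    outcomes = np.empty(len(rep_seeds), dtype=np.int8)
    for i, s in enumerate(rep_seeds):
        rng = np.random.default_rng(int(s))
        bits = np.zeros(N, dtype=np.uint8) if start_nodes is not None else start_bits.copy()
        if start_nodes is not None:
            bits[start_nodes[i]] = 1
        k = int(bits.sum())
        steps = 0
        while 0 < k < N and steps < cap:
            f = np.where(bits == 1, r, 1.0)
            if is_bd:
                u = rng.choice(N, p=f / f.sum())
                v = rng.choice(N, p=W[u] / deg[u])
            else:
                v = rng.integers(N)
                wv = f * W[:, v]
                u = rng.choice(N, p=wv / wv.sum())
            if bits[v] != bits[u]:
                k += 1 if bits[u] else -1
                bits[v] = bits[u]
            steps += 1
        outcomes[i] = 1 if k == N else (0 if k == 0 else -1)
    return outcomes
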