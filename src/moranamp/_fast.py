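"""Optional numba-compiled Monte Carlo kernel.

The package runs without numba (a NumPy kernel in :mod:`moranamp.dynamics`
implements the same process); when numba is importable the batch simulator
below makes long trajectories -- e.g. on the weakly coupled composite
amplifier -- practical.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=False)
def _run_one(W, deg, r, is_bd, bits, cap):  # pragma: no cover - jitted
    N = W.shape[0]
    k = 0
    for i in range(N):
        k += bits[i]
    steps = 0
    while 0 < k < N and steps < cap:
        if is_bd:
            # birth: fitness-proportional reproducer
            F = r * k + (N - k)
            x = np.random.random() * F
            u = N - 1
            acc = 0.0
            for i in range(N):
                acc += r if bits[i] == 1 else 1.0
                if x < acc:
                    u = i
                    break
            # death: weighted neighbour of u
            y = np.random.random() * deg[u]
            v = N - 1
            acc = 0.0
            for j in range(N):
                acc += W[u, j]
                if y < acc:
                    v = j
                    break
        else:
            # death: uniform
            v = int(np.random.random() * N)
            if v == N:
                v = N - 1
            # birth: fitness- and weight-proportional neighbour of v
            total = 0.0
            for i in range(N):
                total += (r if bits[i] == 1 else 1.0) * W[i, v]
            y = np.random.random() * total
            u = N - 1
            acc = 0.0
            for i in range(N):
                acc += (r if bits[i] == 1 else 1.0) * W[i, v]
                if y < acc:
                    u = i
                    break
        if bits[v] != bits[u]:
            if bits[u] == 1:
                k += 1
            else:
                k -= 1
            bits[v] = bits[u]
        steps += 1
    if k == N:
        return 1
    if k == 0:
        return 0
    return -1


@njit(cache=False)
def run_batch(W, deg, r, is_bd, start_nodes, start_bits, rep_seeds, cap):  # pragma: no cover
    """Run one trajectory per seed; returns 1 (fixed), 0 (extinct), -1 (truncated)."""
    n = len(rep_seeds)
    N = W.shape[0]
    out = np.empty(n, dtype=np.int8)
    use_bits = len(start_bits) == N
    for i in range(n):
        np.random.seed(rep_seeds[i])
        bits = np.zeros(N, dtype=np.uint8)
        if use_bits:
            for j in range(N):
                bits[j] = start_bits[j]
        else:
            bits[start_nodes[i]] = 1
        out[i] = _run_one(W, deg, r, is_bd, bits, cap)
    return out
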