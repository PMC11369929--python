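"""Compiled inner loops for the asynchronous bilayer dynamics.

The kernel operates on a single ``(2, L, L)`` int8 array holding both
layers (slot 0 = layer -1, slot 1 = layer +1; cell value 1 = cooperator,
0 = defector).  Cooperator counts per layer are tracked incrementally in a
length-2 int64 array so absorbing-state checks are O(1).

Payoffs use the rescaled donation-game matrix ``[[1-r, -r], [1, 0]]``:
with ``m`` cooperating partners among the 5 cross-layer partners, a
cooperator earns ``m - 5r`` and a defector earns ``m``.
"""

import numpy as np
from numba import njit

# exp argument beyond which the Fermi probability saturates in float64
_EXP_CLIP = 700.0


@njit(cache=True)
def payoff(lat, slot, i, j, L, r):
    """Accumulated payoff of cell (i, j) in layer slot against its 5
    cross-layer partners (opposite cell plus its von Neumann neighbours)."""
    o = 1 - slot
    m = (
        lat[o, i, j]
        + lat[o, (i + 1) % L, j]
        + lat[o, (i - 1) % L, j]
        + lat[o, i, (j + 1) % L]
        + lat[o, i, (j - 1) % L]
    )
    if lat[slot, i, j] == 1:
        return m - 5.0 * r
    return float(m)


@njit(cache=True)
def fermi(du, K):
    """Pairwise-comparison adoption probability 1/(1+exp(-du/K))."""
    x = du / K
    if x > _EXP_CLIP:
        return 1.0
    if x < -_EXP_CLIP:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def sweep(lat, L, r, K, counts, seed):
    """One Monte Carlo step: 2N elementary updates, focal cell uniform
    over both layers, competitor uniform over its 4 same-layer neighbours.

    Reseeds the kernel RNG from ``seed``; counts is updated in place.
    """
    np.random.seed(seed)
    N = L * L
    for _ in range(2 * N):
        idx = np.random.randint(0, 2 * N)
        slot = idx // N
        rem = idx - slot * N
        i = rem // L
        j = rem - i * L
        d = np.random.randint(0, 4)
        if d == 0:
            ni, nj = (i - 1) % L, j
        elif d == 1:
            ni, nj = (i + 1) % L, j
        elif d == 2:
            ni, nj = i, (j - 1) % L
        else:
            ni, nj = i, (j + 1) % L
        sf = lat[slot, i, j]
        sn = lat[slot, ni, nj]
        if sf == sn:
            continue  # adoption would be a no-op
        uf = payoff(lat, slot, i, j, L, r)
        un = payoff(lat, slot, ni, nj, L, r)
        if np.random.random() < fermi(un - uf, K):
            lat[slot, i, j] = sn
            counts[slot] += 2 * sn - 1  # +1 if C adopted, -1 if D
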