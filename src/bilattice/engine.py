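"""Two-layer lattice engine for the inter-species donation game.

Two species occupy parallel L x L square lattices with periodic boundaries.
Each individual plays the rescaled donation game

    A = [[1 - r, -r],
         [1,      0]]      (rows/columns ordered C, D; r = cost/benefit)

with its k + 1 = 5 partners on the *other* layer (the directly opposite
cell and that cell's four von Neumann neighbours) and accumulates the
payoffs.  Competition stays *within* a layer: a randomly chosen focal
individual compares payoffs with one of its 4 same-layer neighbours and
adopts the neighbour's strategy with the Fermi probability

    w = 1 / (1 + exp(-(U_neighbour - U_focal) / K)),

where K > 0 is the selection noise.  One Monte Carlo step comprises 2N
elementary updates (N = L^2), so each layer averages N update attempts.

Conventions: cells store 1 for C and 0 for D; layer labels -1/+1 map to
array slots 0/1; sites are (row, col), 0-based, wrapped by modular
arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .errors import InvalidParameterError

__all__ = [
    "C",
    "D",
    "GameParams",
    "LatticeConfig",
    "BilayerState",
    "RunSchedule",
    "UpdateResult",
    "build_payoff_matrix",
    "site_payoff",
    "fermi_accept_prob",
    "elementary_update",
    "mc_step",
    "initialize",
    "run",
]

C: int = 1
D: int = 0

#: layer label (-1 or +1) -> slot in the strategies array
LAYER_SLOTS = {-1: 0, +1: 1}

#: competition neighbourhood, fixed von Neumann order (up, down, left, right)
NEIGHBOUR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def build_payoff_matrix(r: float) -> np.ndarray:
    """Return the rescaled donation-game payoff matrix [[1-r, -r], [1, 0]].

    Row = focal strategy (C first), column = partner strategy.
    """
    if not np.isfinite(r):
        raise InvalidParameterError(f"cost-to-benefit ratio must be finite, got {r}")
    return np.array([[1.0 - r, -r], [1.0, 0.0]])


@dataclass(frozen=True)
class GameParams:
    """Model physics: cost-to-benefit ratio r and selection noise K."""

    r: float
    K: float

    def __post_init__(self):
        if not np.isfinite(self.r):
            raise InvalidParameterError(f"r must be finite, got {self.r}")
        if not (np.isfinite(self.K) and self.K > 0):
            raise InvalidParameterError(f"noise K must be positive, got {self.K}")

    @property
    def A(self) -> np.ndarray:
        """Derived 2x2 payoff matrix."""
        return build_payoff_matrix(self.r)


@dataclass(frozen=True)
class LatticeConfig:
    """Square-lattice geometry; k = 4 neighbours, periodic boundaries."""

    L: int
    k: int = 4
    boundary: str = "periodic"

    def __post_init__(self):
        if self.L < 2:
            raise InvalidParameterError(f"L must be >= 2, got {self.L}")
        if self.k != 4 or self.boundary != "periodic":
            raise InvalidParameterError("only k=4 with periodic boundaries is supported")

    @property
    def N(self) -> int:
        return self.L * self.L


@dataclass
class BilayerState:
    """Two L x L binary strategy grids plus the elapsed MC-step counter.

    ``strategies[0]`` is layer -1, ``strategies[1]`` is layer +1; cells
    hold 1 (C) or 0 (D).
    """

    strategies: np.ndarray
    t: int = 0

    def __post_init__(self):
        s = np.asarray(self.strategies, dtype=np.int8)
        if s.ndim != 3 or s.shape[0] != 2 or s.shape[1] != s.shape[2]:
            raise InvalidParameterError(f"strategies must have shape (2, L, L), got {s.shape}")
        if not np.isin(s, (C, D)).all():
            raise InvalidParameterError("cells must be C (1) or D (0)")
        self.strategies = s

    @property
    def L(self) -> int:
        return self.strategies.shape[1]

    @property
    def N(self) -> int:
        return self.L * self.L

    def layer(self, a: int) -> np.ndarray:
        """Grid of layer a (label -1 or +1)."""
        try:
            return self.strategies[LAYER_SLOTS[a]]
        except KeyError:
            raise InvalidParameterError(f"layer label must be -1 or +1, got {a}") from None

    def cooperator_counts(self) -> tuple[int, int]:
        """(layer +1 count, layer -1 count) of cooperators."""
        return int(self.strategies[1].sum()), int(self.strategies[0].sum())

    def is_absorbing(self) -> bool:
        """True when both layers are homogeneous (C or D)."""
        n = self.N
        cp, cm = self.cooperator_counts()
        return cp in (0, n) and cm in (0, n)

    def absorbing_label(self) -> str | None:
        """'CC'/'CD'/'DC'/'DD' (layer +1 letter first) or None."""
        if not self.is_absorbing():
            return None
        cp, cm = self.cooperator_counts()
        return ("C" if cp else "D") + ("C" if cm else "D")

    def copy(self) -> "BilayerState":
        return BilayerState(self.strategies.copy(), self.t)


@dataclass(frozen=True)
class RunSchedule:
    """Relaxation/sampling protocol for one simulation run.

    tau_r unrecorded MC steps, then tau_s recorded ones sampled every
    ``sample_interval`` steps.  ``seed`` fixes the whole trajectory.
    """

    tau_r: int
    tau_s: int
    sample_interval: int = 1
    seed: int = 0
    early_stop_on_absorbing: bool = True

    def __post_init__(self):
        if self.tau_r < 0:
            raise InvalidParameterError(f"tau_r must be >= 0, got {self.tau_r}")
        if self.tau_s < 1:
            raise InvalidParameterError(f"tau_s must be >= 1, got {self.tau_s}")
        if not (1 <= self.sample_interval <= self.tau_s):
            raise InvalidParameterError(
                f"sample_interval must lie in [1, tau_s], got {self.sample_interval}"
            )


def site_payoff(state: BilayerState, a: int, site: tuple[int, int], params: GameParams) -> float:
    """Accumulated payoff of ``site`` in layer ``a`` from its 5 cross-layer
    partners: the directly opposite cell plus its 4 von Neumann neighbours.
    """
    L = state.L
    i, j = site
    if not (0 <= i < L and 0 <= j < L):
        raise IndexError(f"site {site} out of range for L={L}")
    slot = LAYER_SLOTS.get(a)
    if slot is None:
        raise InvalidParameterError(f"layer label must be -1 or +1, got {a}")
    A = params.A
    opp = state.strategies[1 - slot]
    row = 1 - state.strategies[slot, i, j]  # matrix row index: C -> 0, D -> 1
    total = A[row, 1 - opp[i, j]]
    for di, dj in NEIGHBOUR_OFFSETS:
        total += A[row, 1 - opp[(i + di) % L, (j + dj) % L]]
    return float(total)


def fermi_accept_prob(U_focal: float, U_neighbor: float, K: float) -> float:
    """Probability that the focal individual adopts the neighbour's strategy,
    1 / (1 + exp(-(U_neighbor - U_focal)/K)).

    Saturates smoothly to 0 or 1 when |dU|/K exceeds the float64 exponent
    range.
    """
    if not (np.isfinite(K) and K > 0):
        raise InvalidParameterError(f"noise K must be positive, got {K}")
    if not (np.isfinite(U_focal) and np.isfinite(U_neighbor)):
        raise InvalidParameterError("payoffs must be finite")
    return float(_kernel.fermi(U_neighbor - U_focal, K))


@dataclass(frozen=True)
class UpdateResult:
    """Record of one elementary update (useful for instrumented tests)."""

    layer: int
    site: tuple[int, int]
    neighbor_site: tuple[int, int]
    accepted: bool
    changed: bool


def elementary_update(state: BilayerState, params: GameParams, rng: np.random.Generator) -> UpdateResult:
    """One asynchronous update: uniform focal cell over both layers, uniform
    same-layer neighbour, fresh payoffs, Fermi adoption.  Mutates ``state``;
    at most one cell changes.
    """
    L, N = state.L, state.N
    idx = int(rng.integers(2 * N))
    slot, rem = divmod(idx, N)
    i, j = divmod(rem, L)
    a = +1 if slot == 1 else -1
    di, dj = NEIGHBOUR_OFFSETS[int(rng.integers(4))]
    ni, nj = (i + di) % L, (j + dj) % L
    uf = site_payoff(state, a, (i, j), params)
    un = site_payoff(state, a, (ni, nj), params)
    w = fermi_accept_prob(uf, un, params.K)
    accepted = bool(rng.random() < w)
    changed = False
    if accepted and state.strategies[slot, i, j] != state.strategies[slot, ni, nj]:
        state.strategies[slot, i, j] = state.strategies[slot, ni, nj]
        changed = True
    return UpdateResult(a, (i, j), (ni, nj), accepted, changed)


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1 << 32))


def mc_step(state: BilayerState, params: GameParams, rng: np.random.Generator) -> BilayerState:
    """One Monte Carlo step = 2N elementary updates; increments t."""
    counts = np.array([state.strategies[0].sum(), state.strategies[1].sum()], dtype=np.int64)
    _kernel.sweep(state.strategies, state.L, params.r, params.K, counts, _kernel_seed(rng))
    state.t += 1
    return state


def initialize(
    config: LatticeConfig, freqC_plus: float, freqC_minus: float, seed: int
) -> BilayerState:
    """Independent Bernoulli initial condition: each cell of layer a is C
    with probability freqC_a.  Layer +1 is drawn first.
    """
    for f in (freqC_plus, freqC_minus):
        if not (0.0 <= f <= 1.0):
            raise InvalidParameterError(f"initial C frequency must lie in [0, 1], got {f}")
    rng = np.random.default_rng(seed)
    shape = (config.L, config.L)
    plus = (rng.random(shape) < freqC_plus).astype(np.int8)
    minus = (rng.random(shape) < freqC_minus).astype(np.int8)
    return BilayerState(np.stack([minus, plus]), t=0)


def run(state: BilayerState, params: GameParams, schedule: RunSchedule):
    """Evolve ``state`` (in place) through tau_r relaxation steps and tau_s
    sampling steps, recording layer cooperator frequencies and cross-layer
    pair frequencies every ``sample_interval`` steps.

    With early stopping, an absorbed run pads the remaining samples with
    the constant absorbing values.  Returns a :class:`~bilattice.observables.Trajectory`.
    """
    from .observables import Trajectory, pair_frequencies

    rng = np.random.default_rng(schedule.seed)
    L, N = state.L, state.N
    lat = state.strategies
    counts = np.array([lat[0].sum(), lat[1].sum()], dtype=np.int64)

    n_samples = schedule.tau_s // schedule.sample_interval
    times = np.empty(n_samples, dtype=np.int64)
    rho_plus = np.empty(n_samples)
    rho_minus = np.empty(n_samples)
    pair_freqs = np.empty((n_samples, 4))

    absorbed_at: int | None = None
    total = schedule.tau_r + schedule.tau_s
    si = 0
    for step in range(total):
        absorbing = counts[0] in (0, N) and counts[1] in (0, N)
        if absorbing and schedule.early_stop_on_absorbing:
            absorbed_at = state.t
            break
        _kernel.sweep(lat, L, params.r, params.K, counts, _kernel_seed(rng))
        state.t += 1
        done = step + 1
        if done > schedule.tau_r and (done - schedule.tau_r) % schedule.sample_interval == 0:
            times[si] = state.t
            rho_plus[si] = counts[1] / N
            rho_minus[si] = counts[0] / N
            pair_freqs[si] = pair_frequencies(state)
            si += 1

    if si < n_samples:  # pad with the current (constant) values
        rp, rm = counts[1] / N, counts[0] / N
        pf = pair_frequencies(state)
        for k in range(si, n_samples):
            times[k] = state.t
            rho_plus[k] = rp
            rho_minus[k] = rm
            pair_freqs[k] = pf

    absorbed = state.absorbing_label()
    return Trajectory(
        times=times,
        rho_plus=rho_plus,
        rho_minus=rho_minus,
        pair_freqs=pair_freqs,
        N=N,
        absorbed=absorbed,
        absorbed_at=absorbed_at,
    )
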