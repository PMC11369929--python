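"""Well-mixed two-species replicator dynamics — the analytic baseline.

Cooperators in species X pay cost c_x to donate benefit b_x to partners in
species Y, and vice versa.  With cooperator frequencies x and y the
replicator equations are

    dx/dt = x (xi_C - xi_bar),   xi_C = y b_x - c_x,  xi_bar = y b_x - x c_x
    dy/dt = y (zeta_C - zeta_bar),

which reduce algebraically to dx/dt = -c_x x (1 - x) and
dy/dt = -c_y y (1 - y): cooperation always declines, at a rate set by the
cost alone — the foregone benefits never enter.  The closed-form solution
is logistic decay, used as the accuracy oracle for the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "ReplicatorParams",
    "ReplicatorState",
    "MeanFieldTrajectory",
    "replicator_rhs",
    "integrate_replicator",
]


@dataclass(frozen=True)
class ReplicatorParams:
    """Donation-game benefits and costs per species (b > c > 0)."""

    b_x: float
    b_y: float
    c_x: float
    c_y: float

    def __post_init__(self):
        for b, c, sp in ((self.b_x, self.c_x, "X"), (self.b_y, self.c_y, "Y")):
            if not (b > c > 0):
                raise InvalidParameterError(f"species {sp} requires b > c > 0, got b={b}, c={c}")


@dataclass(frozen=True)
class ReplicatorState:
    """Cooperator frequencies in the two species."""

    x: float
    y: float

    def __post_init__(self):
        if not (0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0):
            raise InvalidParameterError(f"frequencies must lie in [0, 1], got ({self.x}, {self.y})")


@dataclass(frozen=True)
class MeanFieldTrajectory:
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray


def replicator_rhs(state: ReplicatorState, params: ReplicatorParams) -> tuple[float, float]:
    """(dx/dt, dy/dt) from the full payoff bookkeeping (not the reduced
    form), so the benefit-independence of the flow is a checkable property
    rather than an assumption."""
    x, y = state.x, state.y
    xi_C = y * params.b_x - params.c_x
    xi_bar = y * params.b_x - x * params.c_x
    zeta_C = x * params.b_y - params.c_y
    zeta_bar = x * params.b_y - y * params.c_y
    return x * (xi_C - xi_bar), y * (zeta_C - zeta_bar)


def integrate_replicator(
    state0: ReplicatorState,
    params: ReplicatorParams,
    t_end: float,
    dt: float = 0.01,
) -> MeanFieldTrajectory:
    """Fixed-step 4th-order Runge-Kutta integration of the replicator flow.

    Frequencies are clamped to [0, 1] after every step (the flow preserves
    the interval exactly; clamping only guards round-off).
    """
    if not (np.isfinite(dt) and dt > 0):
        raise InvalidParameterError(f"dt must be positive, got {dt}")
    if not (np.isfinite(t_end) and t_end > 0):
        raise InvalidParameterError(f"t_end must be positive, got {t_end}")
    n = int(round(t_end / dt))
    ts = np.linspace(0.0, n * dt, n + 1)
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    xs[0], ys[0] = state0.x, state0.y

    def f(x, y):
        return replicator_rhs(ReplicatorState(min(max(x, 0.0), 1.0), min(max(y, 0.0), 1.0)), params)

    x, y = state0.x, state0.y
    for k in range(n):
        k1x, k1y = f(x, y)
        k2x, k2y = f(x + 0.5 * dt * k1x, y + 0.5 * dt * k1y)
        k3x, k3y = f(x + 0.5 * dt * k2x, y + 0.5 * dt * k2y)
        k4x, k4y = f(x + dt * k3x, y + dt * k3y)
        x += dt * (k1x + 2 * k2x + 2 * k3x + k4x) / 6.0
        y += dt * (k1y + 2 * k2y + 2 * k3y + k4y) / 6.0
        x = min(max(x, 0.0), 1.0)
        y = min(max(y, 0.0), 1.0)
        xs[k + 1], ys[k + 1] = x, y
    return MeanFieldTrajectory(t=ts, x=xs, y=ys)
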