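"""Parameter scans over r, power-law fits and critical-point location.

The model shows four dynamical regimes separated by three critical points
(r1 > r2 > r3): extinction of cooperation (directed-percolation-like),
spontaneous symmetry breaking between the layers (Ising-like) and a
burst-driven transition at small r.  This module drives scans over the
cost-to-benefit ratio, optionally chaining the equilibrated configuration
from one r value into the next, and provides the log-log regression and
peak-location machinery used to characterize the transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .engine import GameParams, LatticeConfig, RunSchedule, initialize, run
from .errors import EstimationError, InsufficientDataError, InvalidInputError, InvalidParameterError
from .observables import ObservableSummary, summarize

__all__ = [
    "ScanPlan",
    "ScalingFit",
    "CriticalPointEstimate",
    "scan_r",
    "fit_power_law",
    "estimate_critical_point",
]


@dataclass(frozen=True)
class ScanPlan:
    """A chained (or independent) sweep over cost-to-benefit ratios."""

    r_values: tuple
    K: float
    L: int
    schedule: RunSchedule
    chain_states: bool = True
    initial_freqs: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self):
        rv = np.asarray(self.r_values, dtype=float)
        if rv.size == 0:
            raise InvalidParameterError("r_values must be non-empty")
        d = np.diff(rv)
        if rv.size > 1 and not ((d > 0).all() or (d < 0).all()):
            raise InvalidParameterError("r_values must be strictly monotone")
        object.__setattr__(self, "r_values", tuple(float(r) for r in rv))


@dataclass(frozen=True)
class ScalingFit:
    """Power law y = amplitude * x**exponent fitted on log-log axes."""

    exponent: float
    amplitude: float
    window: tuple[float, float]
    stderr: float
    n_points: int


@dataclass(frozen=True)
class CriticalPointEstimate:
    r_c: float
    uncertainty: float
    method: str


def _seed_for(base_seed: int, r: float) -> int:
    """Per-r seed tied to the r *value* (not its position), so scans with
    chaining disabled are order-invariant."""
    bits = int(np.float64(r).view(np.uint64))
    ss = np.random.SeedSequence([int(base_seed), bits & 0xFFFFFFFF, bits >> 32])
    return int(ss.generate_state(1)[0] >> 1)  # keep below 2**31


def scan_r(plan: ScanPlan) -> list[ObservableSummary]:
    """Run the simulator at each r of the plan and summarize each run.

    With ``chain_states`` the final configuration at one r seeds the run at
    the next (re-initialized if the chained state is absorbing, since an
    absorbing configuration cannot leave).  Summaries carry provenance
    (r, K, L, per-r seed, absorbing label).
    """
    config = LatticeConfig(plan.L)
    state = None
    results: list[ObservableSummary] = []
    for r in plan.r_values:
        seed_r = _seed_for(plan.schedule.seed, r)
        if state is None or not plan.chain_states or state.is_absorbing():
            state = initialize(config, *plan.initial_freqs, seed=seed_r)
        params = GameParams(r=r, K=plan.K)
        schedule = replace(plan.schedule, seed=seed_r)
        traj = run(state, params, schedule)
        summary = summarize(traj)
        summary.r = r
        summary.K = plan.K
        summary.L = plan.L
        summary.seed = seed_r
        results.append(summary)
        if not plan.chain_states:
            state = None
    return results


def fit_power_law(x, y, window: tuple[float, float] | None = None) -> ScalingFit:
    """Least-squares line on (log x, log y); the slope is the exponent.

    ``window`` restricts the fit to x in [x_min, x_max]; by default the
    largest 20% of x values are dropped, keeping the asymptotic regime.
    Exponent standard error comes from the residual variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D arrays of equal length")
    if window is None:
        cut = np.quantile(x, 0.8) if x.size > 3 else x.max()
        window = (float(x.min()), float(cut))
    lo, hi = window
    mask = (x >= lo) & (x <= hi)
    xs, ys = x[mask], y[mask]
    if np.any(xs <= 0) or np.any(ys <= 0):
        raise InvalidInputError("power-law fits require positive x and y inside the window")
    if xs.size < 3:
        raise InsufficientDataError(f"need >= 3 points inside the window, got {xs.size}")
    lx, ly = np.log(xs), np.log(ys)
    (slope, intercept), cov = np.polyfit(lx, ly, 1, cov=True)
    stderr = float(np.sqrt(cov[0, 0]))
    return ScalingFit(
        exponent=float(slope),
        amplitude=float(np.exp(intercept)),
        window=(float(lo), float(hi)),
        stderr=stderr,
        n_points=int(xs.size),
    )


def _peak_estimate(r: np.ndarray, obs: np.ndarray) -> CriticalPointEstimate:
    i = int(np.argmax(obs))
    if i == 0 or i == len(r) - 1:
        raise EstimationError("observable has no interior peak")
    # parabolic refinement through the three points around the maximum,
    # clamped to the bracketing interval
    x0, x1, x2 = r[i - 1], r[i], r[i + 1]
    y0, y1, y2 = obs[i - 1], obs[i], obs[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    rc = x1 if a == 0 else float(np.clip(-b / (2 * a), min(x0, x2), max(x0, x2)))
    unc = max(abs(x1 - x0), abs(x2 - x1))
    return CriticalPointEstimate(r_c=rc, uncertainty=float(unc), method="fluctuation peak")


def _fit_quality_estimate(r: np.ndarray, obs: np.ndarray) -> CriticalPointEstimate:
    """Scan candidate r_c values; keep the one maximizing R^2 of the
    power-law fit of the observable versus |r - r_c|."""
    spacing = np.diff(r).min()
    candidates = np.linspace(r[0], r[-1], max(50, 10 * len(r)))
    best_rc, best_score = None, -np.inf
    for rc in candidates:
        x = np.abs(r - rc)
        mask = (x > 0) & (obs > 0)
        if mask.sum() < 3:
            continue
        lx, ly = np.log(x[mask]), np.log(obs[mask])
        slope, intercept = np.polyfit(lx, ly, 1)
        resid = ly - (slope * lx + intercept)
        ss_tot = float(((ly - ly.mean()) ** 2).sum())
        if ss_tot == 0:
            continue
        score = 1.0 - float((resid**2).sum()) / ss_tot
        if score > best_score:
            best_rc, best_score = float(rc), score
    if best_rc is None or best_score < 0.9:
        raise EstimationError("no candidate r_c yields an acceptable power-law fit")
    return CriticalPointEstimate(r_c=best_rc, uncertainty=float(spacing), method="fit-quality scan")


def estimate_critical_point(r_values, observable, mode: str = "fluctuation peak") -> CriticalPointEstimate:
    """Locate a critical point from a scan of a diverging (peak mode) or
    vanishing (fit-quality mode) observable.

    Modes: ``"fluctuation peak"`` — interior maximum with parabolic
    refinement; ``"fit-quality scan"`` — r_c maximizing the goodness of the
    power-law fit of the observable versus |r - r_c|.
    """
    r = np.asarray(r_values, dtype=float)
    obs = np.asarray(observable, dtype=float)
    if r.shape != obs.shape or r.ndim != 1:
        raise InvalidInputError("r_values and observable must be 1-D arrays of equal length")
    if r.size < 5:
        raise InsufficientDataError(f"need >= 5 scan points, got {r.size}")
    order = np.argsort(r)
    r, obs = r[order], obs[order]
    if mode == "fluctuation peak":
        return _peak_estimate(r, obs)
    if mode == "fit-quality scan":
        return _fit_quality_estimate(r, obs)
    raise InvalidParameterError(f"unknown mode {mode!r}")
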