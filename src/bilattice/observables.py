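"""Summary statistics of bilayer states and trajectories.

Notation: rho_a(t) is the cooperator frequency in layer a at MC step t,
rho_bar_a its time average, chi_a = N<(rho_a - rho_bar_a)^2> the scaled
fluctuations, Phi = |rho_bar_+1 - rho_bar_-1| the symmetry-breaking order
parameter, and kappa the per-site cross-layer covariance of cooperation
indicators.  Pair types classify each lattice position by the (layer +1,
layer -1) strategies: CC (mutualistic), CD / DC (exploitative), DD (no
exchange).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import LAYER_SLOTS, BilayerState
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "Trajectory",
    "ObservableSummary",
    "BurstEvent",
    "cooperator_frequency",
    "pair_frequencies",
    "chi",
    "asymmetry",
    "asymmetry_fluctuations",
    "covariance_kappa",
    "summarize",
    "detect_bursts",
]

#: column order of pair frequencies everywhere in the package
PAIR_LABELS = ("CC", "CD", "DC", "DD")


@dataclass
class Trajectory:
    """Sampled time series of one run.

    pair_freqs columns are ordered (f_CC, f_CD, f_DC, f_DD) with the layer
    +1 strategy named first, so f_CC + f_CD = rho_plus and
    f_CC + f_DC = rho_minus at every sample.
    """

    times: np.ndarray
    rho_plus: np.ndarray
    rho_minus: np.ndarray
    pair_freqs: np.ndarray  # shape (n_samples, 4)
    N: int
    absorbed: str | None = None
    absorbed_at: int | None = None

    def __len__(self) -> int:
        return len(self.times)

    def validate(self, tol: float = 1e-12) -> None:
        """Raise InvalidInputError if the pair-frequency invariants fail."""
        if len(self.times) == 0:
            raise InvalidInputError("trajectory has no samples")
        pf = self.pair_freqs
        if np.abs(pf.sum(axis=1) - 1.0).max() > tol:
            raise InvalidInputError("pair frequencies do not sum to 1")
        if np.abs(pf[:, 0] + pf[:, 1] - self.rho_plus).max() > tol:
            raise InvalidInputError("f_CC + f_CD does not match rho_plus")
        if np.abs(pf[:, 0] + pf[:, 2] - self.rho_minus).max() > tol:
            raise InvalidInputError("f_CC + f_DC does not match rho_minus")


@dataclass
class ObservableSummary:
    """Equilibrium averages for one (r, K, L) point."""

    rho_bar_plus: float
    rho_bar_minus: float
    chi_plus: float
    chi_minus: float
    Phi: float
    chi_Phi: float
    kappa: float
    pair_means: tuple[float, float, float, float]
    n_samples: int = 0
    # provenance, filled by parameter scans
    r: float | None = None
    K: float | None = None
    L: int | None = None
    seed: int | None = None
    absorbed: str | None = None


@dataclass(frozen=True)
class BurstEvent:
    """One excursion of the DD pair frequency above a detection threshold."""

    start: int
    peak: int
    end: int
    peak_DD: float
    area: float


def cooperator_frequency(state: BilayerState, a: int) -> float:
    """Fraction of C cells in layer a (label -1 or +1)."""
    if a not in LAYER_SLOTS:
        raise InvalidParameterError(f"layer label must be -1 or +1, got {a}")
    return float(state.layer(a).mean())


def pair_frequencies(state: BilayerState) -> np.ndarray:
    """Frequencies (f_CC, f_CD, f_DC, f_DD) of cross-layer strategy pairs,
    layer +1 strategy first.  Sums to 1."""
    plus = state.strategies[1]
    minus = state.strategies[0]
    n = state.N
    f_cc = int(np.count_nonzero(plus & minus))
    cp = int(plus.sum())
    cm = int(minus.sum())
    f_cd = cp - f_cc  # +1 C, -1 D
    f_dc = cm - f_cc  # +1 D, -1 C
    f_dd = n - f_cc - f_cd - f_dc
    return np.array([f_cc, f_cd, f_dc, f_dd], dtype=float) / n


def chi(series, N: int) -> float:
    """Scaled fluctuations N<(rho(t) - rho_bar)^2> of a frequency series
    (population variance over the samples, times N)."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise InvalidInputError("empty series")
    if np.all(series == series[0]):
        return 0.0  # exactly zero for homogeneous/constant series
    return float(N * series.var())


def asymmetry(rho_bar_plus: float, rho_bar_minus: float) -> float:
    """Order parameter Phi = |rho_bar_+1 - rho_bar_-1|."""
    return abs(rho_bar_plus - rho_bar_minus)


def asymmetry_fluctuations(trajectory: Trajectory, signed: bool = True) -> float:
    """chi-style fluctuations of the layer difference.

    Uses the signed instantaneous difference m(t) = rho_+1(t) - rho_-1(t)
    by default (the magnetization analogue); ``signed=False`` uses |m(t)|.
    """
    if len(trajectory) == 0:
        raise InvalidInputError("empty trajectory")
    m = trajectory.rho_plus - trajectory.rho_minus
    if not signed:
        m = np.abs(m)
    return chi(m, trajectory.N)


def covariance_kappa(state: BilayerState, rho_bar_plus: float, rho_bar_minus: float) -> float:
    """Per-site cross-layer covariance of cooperation indicators,
    (1/N) sum_i (x_-1(i) - rho_bar_-1)(x_+1(i) - rho_bar_+1),
    evaluated with the supplied (typically time-averaged) means."""
    plus = state.strategies[1].astype(float)
    minus = state.strategies[0].astype(float)
    return float(((minus - rho_bar_minus) * (plus - rho_bar_plus)).mean())


def summarize(trajectory: Trajectory, signed_phi: bool = True) -> ObservableSummary:
    """All equilibrium observables of one trajectory.

    Phi is computed from the time-averaged means.  The run-level kappa is
    the time average of per-snapshot covariances with run-level means,
    which reduces identically to <f_CC> - rho_bar_+1 * rho_bar_-1.
    """
    if len(trajectory) == 0:
        raise InvalidInputError("empty trajectory")
    rp = float(trajectory.rho_plus.mean())
    rm = float(trajectory.rho_minus.mean())
    pair_means = trajectory.pair_freqs.mean(axis=0)
    kappa = float(pair_means[0] - rp * rm)
    return ObservableSummary(
        rho_bar_plus=rp,
        rho_bar_minus=rm,
        chi_plus=chi(trajectory.rho_plus, trajectory.N),
        chi_minus=chi(trajectory.rho_minus, trajectory.N),
        Phi=asymmetry(rp, rm),
        chi_Phi=asymmetry_fluctuations(trajectory, signed=signed_phi),
        kappa=kappa,
        pair_means=tuple(float(x) for x in pair_means),
        n_samples=len(trajectory),
        absorbed=trajectory.absorbed,
    )


def detect_bursts(dd_series, threshold: float, min_separation: int = 1) -> list[BurstEvent]:
    """Segment excursions of the DD pair frequency above ``threshold``.

    Contiguous above-threshold runs separated by gaps shorter than
    ``min_separation`` samples are merged.  ``area`` is the summed excess
    of f_DD over the threshold across the event's samples; indices refer
    to positions in the series.
    """
    if not (0.0 < threshold < 1.0):
        raise InvalidParameterError(f"threshold must lie in (0, 1), got {threshold}")
    if min_separation < 1:
        raise InvalidParameterError(f"min_separation must be >= 1, got {min_separation}")
    s = np.asarray(dd_series, dtype=float)
    above = s > threshold
    if not above.any():
        return []
    # raw [start, end] index ranges of above-threshold runs
    padded = np.concatenate([[False], above, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    runs = list(zip(starts, ends))
    merged = [list(runs[0])]
    for st, en in runs[1:]:
        if st - merged[-1][1] - 1 < min_separation:
            merged[-1][1] = en
        else:
            merged.append([st, en])
    events = []
    for st, en in merged:
        seg = s[st : en + 1]
        peak = st + int(np.argmax(seg))
        area = float(np.clip(seg - threshold, 0.0, None).sum())
        events.append(BurstEvent(start=int(st), peak=peak, end=int(en), peak_DD=float(s[peak]), area=area))
    return events
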