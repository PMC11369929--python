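# Methods

## Model

Two species occupy two parallel `L x L` square lattices (layers, labelled
`a = +1` and `a = -1`) with periodic boundaries; every site holds one
individual playing either cooperate (C) or defect (D). The interaction is
the donation game: a cooperator pays cost `c` to give benefit `b` (with
`b > c > 0`) to its partner. Rescaling by `b` leaves the single control
parameter `r = c/b`, the cost-to-benefit ratio, and the payoff matrix

    A = | 1-r  -r |      (rows/columns ordered C, D)
        |  1    0 |

For `0 < r < 1` this is a prisoner's dilemma (D dominates); for `r < 0` it
is a harmony game (C dominates); at `r = 0` the payoff is independent of
the focal individual's own strategy.

The defining structural feature is that **interactions cross layers while
competition stays within a layer**. An individual at site `i` accumulates
payoffs from `k + 1 = 5` partners on the *other* layer: the directly
opposite site and that site's four von Neumann neighbours. With `m`
cooperating partners a cooperator therefore earns `m - 5r` (it pays the
cost `r` towards each of its 5 partners) and a defector earns `m`.

### Update rule

Evolution is asynchronous imitation. An elementary update draws one focal
cell uniformly from all `2N` cells (`N = L^2`) and one of its four
same-layer neighbours uniformly; both payoffs are computed fresh (never
cached — the asynchronous rule makes cached payoffs stale after any
neighbouring flip), and the focal cell adopts the neighbour's strategy
with the Fermi (pairwise-comparison) probability

    w = 1 / (1 + exp(-(U_neighbour - U_focal) / K)).

`K > 0` is the selection noise: `K << 1` means strong selection (better
neighbours are almost surely imitated), `K -> infinity` reduces every
comparison to a fair coin. One **Monte Carlo (MC) step** is `2N`
elementary updates, so each layer averages `N` update attempts per step.
Four absorbing states exist — each layer homogeneous C or D (CC, CD, DC,
DD, naming the layer `+1` strategy first).

When `|dU|/K` exceeds the float64 exponent range, `w` saturates exactly to
0 or 1 (the mathematically correct limit). Comparisons between two cells
that already share a strategy are no-ops and the compiled kernel skips
their acceptance draw; this does not change the law of the process.

### Dynamical regimes

Scanning `r` at low noise (`K = 0.1` is the package-wide default, the
standard strong-selection choice for Fermi-rule lattice games) reveals
four regimes separated by three critical points `r1 > r2 > r3`:

1. `r > r1` — defection dominates; absorption at DD.
2. `r2 < r < r1` — symmetric coexistence; both layers hold the same
   cooperator frequency, increasing as `r` falls. The extinction
   transition at `r1` belongs to the two-dimensional directed-percolation
   universality class.
3. `r3 < r < r2` — spontaneous symmetry breaking: the layers settle at
   essentially complementary frequencies (mostly CD and DC pairs); the
   transition at `r2` is Ising-like (order parameter `Phi`, below).
4. `0 < r < r3` — bursts of mutual defection (transient DD domains) grow
   with decreasing `r` and eventually drive the system into an absorbing
   state, typically CD or DC.

## Observables

For layer `a`, `rho_a(t)` is the cooperator frequency at MC step `t`;
averages run over the sampling window.

- `rho_bar_a = <rho_a(t)>` — equilibrium cooperation per layer.
- `chi_a = N <(rho_a(t) - rho_bar_a)^2>` — scaled fluctuations
  (population variance over samples, times `N`; exactly 0 for constant
  series by an explicit short-circuit, honouring the homogeneous-state
  invariant despite float round-off). Diverges at the critical points.
- `Phi = |rho_bar_+1 - rho_bar_-1|` — the symmetry-breaking order
  parameter, the analogue of the Ising magnetization.
- Fluctuations of `Phi`: the chi-style estimator applied to the *signed*
  instantaneous difference `m(t) = rho_+1(t) - rho_-1(t)` (the
  magnetization analogy; the absolute-value variant is available via
  `signed=False`).
- Pair frequencies `(f_CC, f_CD, f_DC, f_DD)`: the cross-layer strategy
  pair at each site position, layer `+1` named first; they satisfy
  `f_CC + f_CD = rho_+1` and `f_CC + f_DC = rho_-1` at every sample.
- Cross-layer covariance
  `kappa = (1/N) sum_i (x_-1(i) - rho_bar_-1)(x_+1(i) - rho_bar_+1)`
  with `x_a(i)` the cooperation indicator. The run-level value is the
  time average of per-snapshot covariances using run-level means, which
  reduces identically to `<f_CC> - rho_bar_+1 * rho_bar_-1` — so it can
  be computed from the sampled series without storing snapshots.
  Positive `kappa` means aligned layers, negative complementary ones;
  it is bounded by ±0.25.
- Burst detection: excursions of `f_DD` above a user-chosen threshold,
  with above-threshold runs merged when separated by gaps shorter than
  `min_separation` samples (threshold-with-hysteresis segmentation; no
  canonical quantitative burst definition exists, so both knobs are
  exposed). Each event reports start/peak/end, peak `f_DD` and the summed
  excess area.

## Runs, scans and fits

A run is `tau_r` unrecorded relaxation steps followed by `tau_s` sampling
steps recorded every `sample_interval` steps. Early stopping (default on)
halts when both layers are homogeneous and pads the remaining samples
with the constant absorbing values — the physically exact continuation.

Scans over `r` can chain states: the equilibrated configuration at one
`r` seeds the next, so only small adjustments are needed near the new
equilibrium. If a chained state is absorbing, the next point
re-initializes from the plan's initial frequencies (an absorbing state
cannot leave, so inheriting it would pin the rest of the scan).
Per-`r` seeds derive from the base seed and the bit pattern of `r`
itself, making unchained scans independent of scan order.
Symmetry-breaking scans should start from asymmetric initial frequencies
(0.7/0.3 by default in the examples): symmetric starts can wander through
long-lived strip-like metastable domains before breaking symmetry.

Power laws are fitted by least squares on `(log x, log y)`; the slope is
the exponent, the intercept the log-amplitude, and the exponent standard
error comes from the residual covariance. The default fit window drops
the largest 20% of reduced-parameter values, keeping the asymptotic
regime; windows are user-overridable. The fit is exact to machine
precision on noiseless power laws.

Critical points are located two ways, and every estimate records its
method: (a) *fluctuation peak* — the interior maximum of `chi(r)` with
parabolic refinement clamped to the bracketing grid interval,
uncertainty = the local grid spacing; (b) *fit-quality scan* — the
candidate `r_c` maximizing the R^2 of the power-law fit of the order
parameter versus `|r - r_c|`. Both recover planted synthetic critical
points to within one grid spacing; a monotone featureless observable
raises an estimation error rather than returning a boundary value.

## Mean-field baseline

In well-mixed populations the two-species replicator dynamics with
cooperator frequencies `x`, `y` reduces to `dx/dt = -c_x x (1 - x)` (and
symmetrically for `y`): cooperation decays logistically at a rate set by
the cost alone, regardless of the foregone benefits — the additive-game
property. The integrator is fixed-step classical RK4 with default
`dt = 0.01` (dimensionless replicator time); adaptive stepping is
unnecessary because accuracy is verified directly against the logistic
closed form (agreement to 1e-6 at `t = 10`). The right-hand side is
implemented from the full payoff bookkeeping, so benefit-independence is
a checkable property rather than a baked-in simplification.

## Synthetic initial conditions

`initialize` draws each cell i.i.d. Bernoulli per layer — a product
measure with chosen per-layer cooperator frequencies. That is the
canonical disordered start for this class of models and what all shipped
defaults use (0.5/0.5 symmetric, 0.7/0.3 for the symmetry-broken phase).
It deliberately has no spatial correlations; structured starts (domains,
islands, stripes) are available as named deterministic fixtures. Passing
tests on these inputs validates the dynamics and estimators, not any
claim about empirical ecological data.

## Problem sizes and scale

Desk-scale defaults used by the tests, the examples and the acceptance
script: `L = 100` (`N = 10^4`), `tau_r = tau_s = 2x10^3` MC steps,
sampling every step, `K = 0.1`. These sizes resolve the regime structure
(absorption at DD for `r = 0.05`, symmetric coexistence at `r = 0.01`,
symmetry breaking at `r = 0.0015` with the cross-layer mean near 1/2,
absorption at CC for `r < 0`) in seconds per run with the compiled
kernel.

Quantitative critical behaviour needs far more: apparent thresholds at
`L <~ 200` are finite-size-shifted, and fluctuations diverge at the
transitions, so accidental absorption becomes likely on small lattices.
The full-scale protocol for reproducing thresholds and exponents —
`L = 800` with `tau_r = 10^5`, `tau_s = 10^5` for baseline scans, up to
`L = 1,800` with `tau_r = 2x10^6`, `tau_s = 10^7` near the critical
points, chaining equilibrated states between adjacent `r` values — is
fully expressible with `ScanPlan`/`RunSchedule`, and targets the known
characterization: extinction at `r1 ~ 0.0228` with directed-percolation
exponents (`rho_bar ~ (r1-r)^beta`, `beta = 0.580`; `chi ~ (r1-r)^-0.35`),
Ising-class symmetry breaking at `r2 ~ 0.00217` (`Phi` slope 1/8,
`chi_Phi` exponent -7/4), and the burst-driven divergence
`chi ~ (r-r3)^-1.33` at `r3 ~ 0.0004`. Those runs are cluster-scale and
not exercised by the shipped tests.

## Known limitations

- Only the two-layer square lattice with k = 4 and periodic boundaries;
  no other topologies, no variable population density, no
  finite-size-scaling collapse machinery.
- No spatial correlation functions; `kappa` is the only cross-layer
  spatial statistic.
- The burst definition is an operationalization (threshold + merge); the
  event list depends on its two parameters.
- `chi_a` estimates from a single run understate the true fluctuations
  very close to a critical point, where sampling times beyond any desk
  budget are required.
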