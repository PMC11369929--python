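# bilattice

Monte Carlo simulator for cooperation **between** species: a donation game
played across two coupled square-lattice layers, with imitation-driven
selection inside each layer.

## The problem

Mutualistic associations — pollinators and plants, microbial symbionts and
their hosts — hinge on costly cooperation whose benefits flow to *another*
species. In a well-mixed world this is hopeless: the two-species
replicator dynamics reduces to `dx/dt = -c x (1 - x)`, so cooperators
dwindle at a rate set by the cost alone, no matter how large the benefit.
`bilattice` simulates the spatial version of this system, where structure
changes the outcome qualitatively, and provides the observables and
scaling tools needed to map its phase diagram.

## The model

Each of two species occupies one `L x L` lattice layer (periodic
boundaries). Every individual plays the rescaled donation game

    A = [[1-r, -r], [1, 0]]        r = cost/benefit ratio

with its 5 partners on the *other* layer (the opposite site plus its four
von Neumann neighbours) and accumulates the payoffs. Competition stays
*within* a layer: a random focal individual adopts a random same-layer
neighbour's strategy with the Fermi probability
`w = 1/(1 + exp(-(U_j - U_i)/K))`, where `K` is the selection noise. One
MC step is `2N` such updates (`N = L^2`).

Varying `r` at `K = 0.1` produces four regimes separated by critical
points `r1 > r2 > r3`: extinction of cooperation for `r > r1`
(directed-percolation class), symmetric coexistence for `r2 < r < r1`,
**spontaneous symmetry breaking** for `r3 < r < r2` — the two identically
modelled species settle at complementary cooperation levels, one
exploiting the other — and burst-driven relaxation into asymmetric
absorbing states for `r < r3`. Key observables: per-layer cooperation
`rho_bar_a`, scaled fluctuations `chi_a = N var(rho_a)`, the order
parameter `Phi = |rho_bar_+1 - rho_bar_-1|`, cross-layer pair frequencies
`(f_CC, f_CD, f_DC, f_DD)` and the covariance `kappa`. See
`docs/methods.md` for the full account.

## Worked example

`examples/symmetry_breaking.py` runs the symmetry-broken phase
(`r = 0.0015`, `K = 0.1`, `L = 100`, asymmetric 0.7/0.3 start, 2000 MC
steps of relaxation + 2000 of sampling):

```
rho_bar_+1 = 0.850   rho_bar_-1 = 0.131
Phi = 0.719   kappa = -0.0026   mean cooperation = 0.490
pair means (CC, CD, DC, DD) = (0.109, 0.741, 0.022, 0.128)
```

Although the two layers obey identical rules, layer +1 cooperates at 85%
and layer -1 at 13% (`Phi = 0.72`): selection has spontaneously separated
the species into a producer and a consumer, with mostly CD pairs — yet
the cooperation level *averaged over both layers* stays near 1/2.

`examples/scan_and_fit.py` chains a scan down through the extinction
transition and locates it from the order parameter:

```
r = 0.0260  rho_bar = (0.000, 0.000)  chi_+1 =     0.00  absorbed = DD
r = 0.0240  rho_bar = (0.037, 0.036)  chi_+1 =     1.26  absorbed = -
...
fit-quality scan -> r_c = 0.0234 +/- 0.0020
rho_bar ~ (r_c - r)^beta with beta = 0.75 +/- 0.03  (9 points; desk-scale, finite-size shifted)
```

Even at `L = 100` the estimated threshold lands near the known
`r1 ~ 0.023`; the exponent is finite-size shifted, as expected at this
scale. The other examples cover symmetric coexistence, the well-mixed
baseline against its logistic closed form, and DD-burst detection.

A thin CLI mirrors the library (`bilattice run|scan|summarize|fit|
meanfield|fixture|render`; `bilattice --help`), with a YAML config file
for defaults and plain-text outputs throughout.

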