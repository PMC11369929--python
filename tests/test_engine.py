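"""Unit and property tests for the bilayer lattice engine."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bilattice import (
    BilayerState,
    GameParams,
    InvalidParameterError,
    LatticeConfig,
    RunSchedule,
    build_payoff_matrix,
    elementary_update,
    fermi_accept_prob,
    initialize,
    mc_step,
    run,
    site_payoff,
)
from bilattice import _kernel
from bilattice.engine import NEIGHBOUR_OFFSETS

from conftest import bilayer


# ------------------------------------------------------------ payoff matrix

@pytest.mark.parametrize(
    "r, expected",
    [
        (0.0, [[1, 0], [1, 0]]),
        (0.5, [[0.5, -0.5], [1, 0]]),
        (1.0, [[0, -1], [1, 0]]),
    ],
)
def test_payoff_matrix_values(r, expected):
    np.testing.assert_allclose(build_payoff_matrix(r), expected)


@pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
def test_payoff_matrix_rejects_nonfinite(bad):
    with pytest.raises(InvalidParameterError):
        build_payoff_matrix(bad)


# --------------------------------------------------------------- site payoff

def brute_force_payoff(state, a, site, params):
    """Independent oracle: enumerate the 5 cross-layer partners and sum the
    unit-vector bilinear forms s_f . A s_p."""
    A = params.A
    i, j = site
    L = state.L
    focal = state.layer(a)[i, j]
    opp = state.layer(-a)
    partners = [opp[i, j]] + [opp[(i + di) % L, (j + dj) % L] for di, dj in NEIGHBOUR_OFFSETS]
    def unit(s):  # C -> e1, D -> e2
        return np.array([1, 0]) if s == 1 else np.array([0, 1])
    return sum(float(unit(focal) @ A @ unit(p)) for p in partners)


def test_site_payoff_all_cooperators():
    state = bilayer(np.ones((4, 4)), np.ones((4, 4)))
    params = GameParams(r=0.1, K=0.1)
    for i, j in itertools.product(range(4), repeat=2):
        assert site_payoff(state, +1, (i, j), params) == pytest.approx(4.5)


def test_site_payoff_all_defectors_any_r():
    state = bilayer(np.zeros((4, 4)), np.zeros((4, 4)))
    for r in (-0.3, 0.0, 0.7):
        params = GameParams(r=r, K=0.1)
        assert site_payoff(state, -1, (2, 1), params) == 0.0


def test_defector_with_five_cooperating_partners_earns_five():
    state = bilayer(np.zeros((4, 4)), np.ones((4, 4)))  # +1 all D, -1 all C
    params = GameParams(r=0.3, K=0.1)
    assert site_payoff(state, +1, (0, 0), params) == pytest.approx(5.0)


def test_site_payoff_out_of_range():
    state = bilayer(np.ones((3, 3)), np.ones((3, 3)))
    with pytest.raises(IndexError):
        site_payoff(state, +1, (3, 0), GameParams(r=0.1, K=0.1))


def test_site_payoff_oracle_all_3x3_configurations():
    """Exhaustive check on a 3x3 bilayer.

    The payoff depends only on the focal strategy and the opposite-layer
    configuration, so enumerating all 2^9 opposite layers x 9 sites x both
    focal strategies covers every payoff situation arising in any 3x3
    bilayer configuration.
    """
    L = 3
    params = GameParams(r=0.37, K=0.1)
    for code in range(2**9):
        opp = np.array([(code >> k) & 1 for k in range(9)], dtype=np.int8).reshape(L, L)
        for focal_strategy in (0, 1):
            focal_grid = np.full((L, L), focal_strategy, dtype=np.int8)
            state = bilayer(focal_grid, opp)  # focal layer is +1
            for i, j in itertools.product(range(L), repeat=2):
                expected = brute_force_payoff(state, +1, (i, j), params)
                assert site_payoff(state, +1, (i, j), params) == pytest.approx(expected, abs=1e-12)
                # the compiled kernel must agree exactly with the public op
                got = _kernel.payoff(state.strategies, 1, i, j, L, params.r)
                assert got == pytest.approx(expected, abs=1e-12)


def test_r_zero_strategy_neutrality(rng):
    """At r=0 the payoff is identical whether the focal cell holds C or D."""
    params = GameParams(r=0.0, K=0.1)
    for _ in range(20):
        state = BilayerState((rng.random((2, 5, 5)) < 0.5).astype(np.int8))
        flipped = state.copy()
        flipped.strategies[1, 2, 3] ^= 1
        assert site_payoff(state, +1, (2, 3), params) == site_payoff(flipped, +1, (2, 3), params)


def test_harmony_dominance_for_negative_r(rng):
    """For r<0 a cooperator strictly outearns a defector with the same
    partner set; the gap is exactly -5r."""
    r = -0.2
    params = GameParams(r=r, K=0.1)
    opp = (rng.random((5, 5)) < 0.5).astype(np.int8)
    coop = bilayer(np.ones((5, 5)), opp)
    defe = bilayer(np.zeros((5, 5)), opp)
    for i, j in itertools.product(range(5), repeat=2):
        gap = site_payoff(coop, +1, (i, j), params) - site_payoff(defe, +1, (i, j), params)
        assert gap == pytest.approx(-5 * r)
        assert gap > 0


# -------------------------------------------------------------- Fermi rule

def test_fermi_equal_payoffs():
    assert fermi_accept_prob(1.7, 1.7, 0.1) == 0.5


def test_fermi_large_noise_limit():
    assert fermi_accept_prob(-3.0, 4.0, 1e9) == pytest.approx(0.5, abs=1e-6)


def test_fermi_unit_advantage():
    assert fermi_accept_prob(0.0, 0.1, 0.1) == pytest.approx(1 / (1 + np.exp(-1)))


@pytest.mark.parametrize("K", [0.0, -0.5])
def test_fermi_rejects_nonpositive_noise(K):
    with pytest.raises(InvalidParameterError):
        fermi_accept_prob(0.0, 1.0, K)


def test_fermi_rejects_nonfinite_payoffs():
    with pytest.raises(InvalidParameterError):
        fermi_accept_prob(np.nan, 1.0, 0.1)


def test_fermi_overflow_saturates():
    assert fermi_accept_prob(0.0, 1e6, 1e-3) == 1.0
    assert fermi_accept_prob(1e6, 0.0, 1e-3) == 0.0


@given(du=st.floats(-50, 50), K=st.floats(1e-3, 1e3))
@settings(max_examples=200, deadline=None)
def test_fermi_symmetry_and_monotonicity(du, K):
    w = fermi_accept_prob(0.0, du, K)
    w_neg = fermi_accept_prob(du, 0.0, K)
    assert w + w_neg == pytest.approx(1.0, abs=1e-12)
    w_up = fermi_accept_prob(0.0, du + 1e-3, K)
    if 1e-12 < w < 1 - 1e-12:  # strict growth is resolvable away from saturation
        assert w_up > w
    else:
        assert w_up >= w


# ------------------------------------------------------- elementary update

def test_homogeneous_state_never_changes(rng):
    state = bilayer(np.ones((4, 4)), np.ones((4, 4)))
    params = GameParams(r=0.3, K=0.1)
    before = state.strategies.copy()
    for _ in range(200):
        elementary_update(state, params, rng)
    np.testing.assert_array_equal(state.strategies, before)


def test_update_changes_at_most_one_cell(rng):
    params = GameParams(r=0.4, K=0.5)
    state = BilayerState((rng.random((2, 4, 4)) < 0.5).astype(np.int8))
    for _ in range(500):
        before = state.strategies.copy()
        elementary_update(state, params, rng)
        assert np.count_nonzero(state.strategies != before) <= 1


def enumerate_flip_probabilities(state, params):
    """Brute-force oracle: probability that each cell flips in one
    elementary update, from the (focal, neighbour, accept) decomposition."""
    L, N = state.L, state.N
    probs = np.zeros((2, L, L))
    for slot in (0, 1):
        a = +1 if slot == 1 else -1
        for i, j in itertools.product(range(L), repeat=2):
            for di, dj in NEIGHBOUR_OFFSETS:
                ni, nj = (i + di) % L, (j + dj) % L
                if state.strategies[slot, i, j] == state.strategies[slot, ni, nj]:
                    continue
                uf = site_payoff(state, a, (i, j), params)
                un = site_payoff(state, a, (ni, nj), params)
                w = fermi_accept_prob(uf, un, params.K)
                probs[slot, i, j] += w / (2 * N * 4)
    return probs


def test_one_step_transition_frequencies_match_enumeration():
    """Empirical per-cell flip frequencies over 1e5 single updates from a
    fixed 2x2 bilayer agree with exhaustive enumeration within 3 sigma."""
    start = bilayer([[1, 0], [0, 1]], [[1, 1], [0, 0]])
    params = GameParams(r=0.5, K=0.1)
    expected = enumerate_flip_probabilities(start, params)
    n = 100_000
    rng = np.random.default_rng(777)
    flips = np.zeros_like(expected)
    for _ in range(n):
        state = start.copy()
        res = elementary_update(state, params, rng)
        if res.changed:
            slot = 1 if res.layer == 1 else 0
            flips[slot][res.site] += 1
    freq = flips / n
    sigma = np.sqrt(expected * (1 - expected) / n)
    assert np.all(np.abs(freq - expected) <= 3 * sigma + 1e-12)


def test_kernel_marginals_match_python_updates():
    """One full MC step via the compiled kernel and via composed Python
    elementary updates yield the same per-cell cooperator marginals."""
    start = bilayer([[1, 0], [0, 1]], [[1, 1], [0, 0]])
    params = GameParams(r=0.3, K=0.2)
    n_py, n_k = 8000, 20000
    rng = np.random.default_rng(99)
    acc_py = np.zeros((2, 2, 2))
    for _ in range(n_py):
        state = start.copy()
        for _ in range(2 * state.N):
            elementary_update(state, params, rng)
        acc_py += state.strategies
    acc_k = np.zeros((2, 2, 2))
    rng_k = np.random.default_rng(98)
    for _ in range(n_k):
        state = start.copy()
        mc_step(state, params, rng_k)
        acc_k += state.strategies
    p_py, p_k = acc_py / n_py, acc_k / n_k
    sigma = np.sqrt(p_py * (1 - p_py) / n_py + p_k * (1 - p_k) / n_k)
    assert np.all(np.abs(p_py - p_k) <= 4 * sigma + 1e-12)


def test_mc_step_absorbing_states_stable(rng):
    params = GameParams(r=0.1, K=0.1)
    for plus, minus in itertools.product((0, 1), repeat=2):
        state = bilayer(np.full((4, 4), plus), np.full((4, 4), minus))
        before = state.strategies.copy()
        for _ in range(50):
            mc_step(state, params, rng)
        np.testing.assert_array_equal(state.strategies, before)
        assert state.t == 50


def test_voter_limit_acceptance_rate():
    """r=0 with one layer homogeneous C: every comparison in the other
    layer is a fair coin (all payoffs equal), so the measured acceptance
    frequency is 1/2."""
    rng = np.random.default_rng(4242)
    plus = np.ones((10, 10), dtype=np.int8)
    minus = (np.random.default_rng(7).random((10, 10)) < 0.5).astype(np.int8)
    state = bilayer(plus, minus)
    params = GameParams(r=0.0, K=0.1)
    accepted = total = 0
    while total < 10_000:
        res = elementary_update(state, params, rng)
        if res.layer == -1:
            total += 1
            accepted += res.accepted
    rate = accepted / total
    assert abs(rate - 0.5) <= 3 * np.sqrt(0.25 / total)


# ------------------------------------------------------------- initialize

def test_initialize_degenerate_frequencies():
    cfg = LatticeConfig(4)
    assert initialize(cfg, 1.0, 1.0, seed=0).absorbing_label() == "CC"
    assert initialize(cfg, 0.0, 0.0, seed=0).absorbing_label() == "DD"


def test_initialize_bernoulli_frequencies():
    state = initialize(LatticeConfig(100), 0.5, 0.5, seed=3)
    cp, cm = state.cooperator_counts()
    assert abs(cp / state.N - 0.5) < 0.02
    assert abs(cm / state.N - 0.5) < 0.02


def test_initialize_deterministic():
    a = initialize(LatticeConfig(16), 0.3, 0.8, seed=11)
    b = initialize(LatticeConfig(16), 0.3, 0.8, seed=11)
    np.testing.assert_array_equal(a.strategies, b.strategies)


@pytest.mark.parametrize("fp, fm", [(-0.1, 0.5), (0.5, 1.5)])
def test_initialize_rejects_bad_frequencies(fp, fm):
    with pytest.raises(InvalidParameterError):
        initialize(LatticeConfig(4), fp, fm, seed=0)


# -------------------------------------------------------------------- run

def test_run_from_absorbing_start():
    state = bilayer(np.ones((8, 8)), np.ones((8, 8)))
    traj = run(state, GameParams(r=0.1, K=0.1), RunSchedule(tau_r=5, tau_s=10, seed=0))
    assert traj.absorbed == "CC"
    assert traj.absorbed_at == 0
    assert np.all(traj.rho_plus == 1.0)
    assert np.all(traj.rho_minus == 1.0)


def test_run_harmony_absorbs_at_cc():
    state = initialize(LatticeConfig(100), 0.5, 0.5, seed=5)
    traj = run(state, GameParams(r=-0.1, K=0.1), RunSchedule(tau_r=0, tau_s=500, seed=6))
    assert traj.absorbed == "CC"


def test_run_reproducible():
    def one():
        state = initialize(LatticeConfig(20), 0.5, 0.5, seed=21)
        return run(state, GameParams(r=0.01, K=0.1), RunSchedule(tau_r=20, tau_s=50, seed=22))

    t1, t2 = one(), one()
    np.testing.assert_array_equal(t1.rho_plus, t2.rho_plus)
    np.testing.assert_array_equal(t1.rho_minus, t2.rho_minus)
    np.testing.assert_array_equal(t1.pair_freqs, t2.pair_freqs)
    np.testing.assert_array_equal(t1.times, t2.times)


def test_run_schedule_validation():
    with pytest.raises(InvalidParameterError):
        RunSchedule(tau_r=-1, tau_s=10)
    with pytest.raises(InvalidParameterError):
        RunSchedule(tau_r=0, tau_s=0)
    with pytest.raises(InvalidParameterError):
        RunSchedule(tau_r=0, tau_s=10, sample_interval=11)


def test_run_sampling_invariants():
    state = initialize(LatticeConfig(20), 0.5, 0.5, seed=31)
    traj = run(state, GameParams(r=0.01, K=0.1), RunSchedule(tau_r=10, tau_s=40, seed=32))
    traj.validate()  # pair-frequency marginals hold at every sample
    assert len(traj) == 40
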