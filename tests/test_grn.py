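"""Hill right-hand sides and steady-state integration of the GRN systems."""

import numpy as np
import pytest
from scipy.optimize import root

import neuraltube as nt
from neuraltube.grn import (INVIVO_NODES, IntegrationError, integrate_invitro,
                            invitro_rhs, invivo_cell_rhs)
from neuraltube.params import ParameterSet


def hand_invitro_rhs(state, p):
    """Independent hand expansion of the printed consensus equations."""
    FB, MB, HB, G, CT = state
    c, n, d = p.c, p.n, p.delta
    dFB = c[1] * G ** n[1] / (1 + c[1] * G ** n[1] + c[2] * MB ** n[2]
                              + c[3] * HB ** n[3]) - d[1] * FB
    dMB = c[4] * MB ** n[4] / (1 + c[4] * MB ** n[4] + c[5] * FB ** n[5]
                               + c[6] * HB ** n[6] + c[7] * G ** n[7]) - d[2] * MB
    dHB = c[8] * HB ** n[8] / (1 + c[8] * HB ** n[8] + c[9] * FB ** n[9]
                               + c[10] * MB ** n[10] + c[11] * G ** n[11]) - d[3] * HB
    dG = c[12] * G ** n[12] / (1 + c[12] * G ** n[12]
                               + c[13] * CT ** n[13]) - d[4] * G
    return np.array([dFB, dMB, dHB, dG, 0.0])


def test_rhs_zero_state_gives_zero_derivatives(params, consensus):
    state = np.zeros(5)
    assert nt.hill_node_rhs(state, params, consensus, "FB") == 0.0
    assert np.allclose(invitro_rhs(state, params, consensus), 0.0)


def test_single_activator_half_max():
    """One activator at c = n = level = 1 and no decay gives rate 1/2."""
    c = np.ones(17)
    n = np.ones(17)
    delta = np.full(6, 1e-12)
    p = ParameterSet(c=c, n=n, delta=delta)
    topo = nt.Topology({("FB", "GSK3"): 1})
    state = np.array([0.0, 0.0, 0.0, 1.0, 0.0])
    assert nt.hill_node_rhs(state, p, topo, "FB") == pytest.approx(0.5, abs=1e-9)


def test_consensus_rhs_matches_hand_expansion(params, consensus):
    rng = np.random.default_rng(11)
    for _ in range(25):
        state = rng.uniform(0.0, 5.0, size=5)
        got = invitro_rhs(state, params, consensus)
        assert np.allclose(got, hand_invitro_rhs(state, params), rtol=0, atol=1e-13)


def test_rhs_rejects_bad_input(params, consensus):
    with pytest.raises(ValueError):
        nt.hill_node_rhs(np.array([-1.0, 0, 0, 0, 0]), params, consensus, "FB")
    with pytest.raises(ValueError):
        nt.hill_node_rhs(np.zeros(5), params, consensus, "CT")


def test_general_topology_rule_activators_in_numerator(params):
    """Two activators both contribute to numerator and denominator."""
    topo = nt.Topology({("MB", "MB"): 1, ("MB", "FB"): 1})
    c, n = params.c, params.n
    state = np.array([1.3, 0.7, 0.0, 0.0, 0.0])
    t_self = c[4] * 0.7 ** n[4]
    t_fb = c[5] * 1.3 ** n[5]
    expected = (t_self + t_fb) / (1 + t_self + t_fb) - params.delta[2] * 0.7
    assert nt.hill_node_rhs(state, params, topo, "MB") == pytest.approx(expected)


def test_integration_reaches_forebrain_state_at_zero_ct(params, consensus):
    init = np.array([1.0, 1.0, 1.0, 1.0, 0.0])
    state, conv = integrate_invitro(init, params, consensus)
    assert conv
    assert state[0] > state[1] and state[0] > state[2]  # FB dominates


def test_integration_reaches_hindbrain_state_at_high_ct(params, consensus):
    init = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
    state, conv = integrate_invitro(init, params, consensus)
    assert conv
    assert state[2] > state[0] and state[2] > state[1]  # HB dominates


def test_steady_state_agrees_with_root_finding_oracle(params, consensus):
    """Integrated fixed points solve rhs = 0 (checked with scipy.root)."""
    rng = np.random.default_rng(5)
    checked = 0
    for _ in range(40):
        ct = float(rng.uniform(0, 1))
        init = np.ones(5)
        init[4] = ct
        state, conv = integrate_invitro(init, params, consensus, tol=1e-10)
        if not conv:
            continue
        assert np.max(np.abs(invitro_rhs(state, params, consensus))) < 1e-10

        def f(x):
            s = np.concatenate([np.clip(x, 0, None), [ct]])
            return invitro_rhs(s, params, consensus)[:4]

        sol = root(f, state[:4], method="hybr", tol=1e-12)
        if sol.success:
            assert np.allclose(np.clip(sol.x, 0, None), state[:4], atol=1e-4)
            checked += 1
    assert checked >= 20


def test_random_parameter_sets_oracle_equivalence(consensus):
    """Integration and root-finding agree on random parameter draws."""
    rng = np.random.default_rng(17)
    agreements = 0
    for _ in range(30):
        c = np.ones(17)
        n = np.ones(17)
        c[1:14] = 10.0 ** rng.uniform(-2, 2, size=13)
        n[1:14] = rng.uniform(1, 4, size=13)
        delta = np.concatenate([[1.0], rng.uniform(0.05, 1.0, size=5)])
        p = ParameterSet(c=c, n=n, delta=delta)
        init = np.ones(5)
        init[4] = float(rng.uniform(0, 1))
        state, conv = integrate_invitro(init, p, consensus, tol=1e-10,
                                        max_time=20_000)
        if not conv:
            continue

        def f(x, ct=init[4]):
            s = np.concatenate([np.clip(x, 0, None), [ct]])
            return invitro_rhs(s, p, consensus)[:4]

        sol = root(f, state[:4], method="hybr", tol=1e-12)
        if sol.success and np.all(sol.x > -1e-9):
            assert np.allclose(np.clip(sol.x, 0, None), state[:4], atol=1e-4)
            agreements += 1
    assert agreements >= 20


def test_nonnegativity_and_boundedness_on_random_draws(consensus):
    """Hill production < 1 implies steady levels below 1/delta."""
    rng = np.random.default_rng(23)
    for _ in range(10):
        c = np.ones(17)
        n = np.ones(17)
        c[1:14] = 10.0 ** rng.uniform(-2, 3, size=13)
        n[1:14] = rng.uniform(1, 5, size=13)
        delta = np.concatenate([[1.0], rng.uniform(0.1, 1.0, size=5)])
        p = ParameterSet(c=c, n=n, delta=delta)
        init = rng.uniform(0, 3, size=5)
        state, _ = integrate_invitro(init, p, consensus, max_time=2000)
        assert np.all(state >= 0)
        bound = 1.0 / p.delta[1:5] + 1e-6
        assert np.all(state[:4] <= bound)


def test_gsk3_steady_state_monotone_in_ct(params, consensus):
    ct = np.linspace(0, 1, 41)
    init = np.ones((5, ct.size))
    init[4] = ct
    state, conv = integrate_invitro(init, params, consensus, max_time=20_000)
    # trajectories next to the GSK3 collapse point slow down critically;
    # the monotonicity claim holds for the profile as a whole
    assert conv.mean() > 0.9
    gsk3 = state[3]
    assert np.all(np.diff(gsk3) <= 1e-6)


def test_integration_error_on_nonfinite(params, consensus):
    with pytest.raises(ValueError):
        integrate_invitro(np.full(5, -1.0), params, consensus)
    with pytest.raises(ValueError):
        integrate_invitro(np.ones(5), params, consensus, step=0.0)


# -- in-vivo system ------------------------------------------------------

def hand_invivo_rhs(state, p, W, S):
    P, O, N, G, U, GSK3, FB, MB, HB = state
    c, n, d, dv = p.c, p.n, p.delta, p.dv
    out = np.empty(9)
    out[0] = dv["alpha"] / (1 + (N / dv["NcritP"]) ** dv["h1"]
                            + (O / dv["OcritP"]) ** dv["h2"]) - dv["k1"] * P
    out[1] = dv["beta"] * G / (1 + G) / (1 + (N / dv["NcritO"]) ** dv["h3"]) \
        - dv["k2"] * O
    out[2] = dv["gamma"] * G / (1 + G) / (1 + (O / dv["OcritN"]) ** dv["h4"]
                                          + (P / dv["PcritN"]) ** dv["h5"]) \
        - dv["k3"] * N
    out[3] = dv["deltaG"] * S / (1 + S) / (1 + (W / dv["WcritG"]) ** dv["h6"]) \
        - dv["k4"] * G
    ua = c[14] * W ** n[14] + c[15] * U ** n[15]
    out[4] = ua / (1 + ua + c[16] * U ** n[16]) - d[5] * U
    ga = c[12] * GSK3 ** n[12]
    out[5] = ga / (1 + ga + c[13] * U ** n[13]) - d[4] * GSK3
    fa = c[1] * GSK3 ** n[1]
    out[6] = fa / (1 + fa + c[2] * MB ** n[2] + c[3] * HB ** n[3]) - d[1] * FB
    ma = c[4] * MB ** n[4]
    out[7] = ma / (1 + ma + c[5] * FB ** n[5] + c[6] * HB ** n[6]
                   + c[7] * GSK3 ** n[7]) - d[2] * MB
    ha = c[8] * HB ** n[8]
    out[8] = ha / (1 + ha + c[9] * FB ** n[9] + c[10] * MB ** n[10]
                   + c[11] * GSK3 ** n[11]) - d[3] * HB
    return out


def test_invivo_rhs_matches_hand_expansion(params):
    rng = np.random.default_rng(29)
    for _ in range(20):
        state = rng.uniform(0, 4, size=9)
        W, S = rng.uniform(0, 2, size=2)
        got = invivo_cell_rhs(state, params, W, S)
        assert np.allclose(got, hand_invivo_rhs(state, params, W, S), atol=1e-13)


def test_invivo_trivial_states(params):
    # no morphogens, everything but GSK3 at zero: Gli derivative vanishes
    state = np.zeros(9)
    state[INVIVO_NODES.index("GSK3")] = 1.0
    d = invivo_cell_rhs(state, params, 0.0, 0.0)
    assert d[INVIVO_NODES.index("G")] == 0.0
    # without WNT, the buffer node's off state is absorbing
    assert d[INVIVO_NODES.index("U")] == 0.0
    with pytest.raises(ValueError):
        invivo_cell_rhs(state, params, -0.1, 0.0)
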