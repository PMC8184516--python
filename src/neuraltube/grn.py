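"""Hill-formalism ODE systems and their steady-state integration.

Two systems are defined.  The *in-vitro* system describes the response of
the three brain-region fate nodes (FB, MB, HB) and GSK3 activity to a
constant concentration of the GSK3 inhibitor CT, as in the cell-culture
dose-response experiments.  The *in-vivo* system couples the same
rostrocaudal circuit (driven through a WNT-responsive buffer node U instead
of CT) to the dorsoventral Gli/Pax6/Olig2/Nkx2.2 circuit; its morphogen
inputs WNT and SHH are supplied per cell by the 3D diffusion layer.

Production terms follow the Hill convention used throughout: every
activator contributes ``c * x**n`` to both numerator and denominator of the
production fraction, every repressor contributes to the denominator only,
so each production rate lies in [0, 1).

The in-vitro integrator is classic fixed-step fourth-order Runge-Kutta
(default step 2 time units), run until the largest time derivative falls
below tolerance.  States are clipped to zero after each step: Hill terms
have no meaning for negative levels and only discretisation overshoot can
produce them.
"""

from __future__ import annotations

import numpy as np

from .params import EDGE_PARAM_INDEX
from .topology import ACTIVATION, REPRESSION, Topology

INVITRO_NODES = ("FB", "MB", "HB", "GSK3", "CT")


def _pow(x, e):
    """x**e with a fast path for small integer exponents.

    Hill and gating exponents are almost always small integers; repeated
    multiplication is several times faster than the general power kernel
    on large arrays and bit-identical for integer e.
    """
    ei = int(e)
    if ei != e or not 1 <= ei <= 8:
        return x ** e
    result = None
    base = x
    while ei:
        if ei & 1:
            result = base if result is None else result * base
        ei >>= 1
        if ei:
            base = base * base
    return result


INVIVO_NODES = ("P", "O", "N", "G", "U", "GSK3", "FB", "MB", "HB")

_IDX = {name: i for i, name in enumerate(INVITRO_NODES)}


class IntegrationError(RuntimeError):
    """Raised when an integration step produces non-finite values."""


def _node_terms(topology: Topology, node: str):
    """(source index, parameter index, sign) for each edge into ``node``."""
    terms = []
    for src, sign in topology.incoming(node):
        pi = EDGE_PARAM_INDEX[(node, src)]
        terms.append((_IDX[src], pi, sign))
    terms.sort(key=lambda t: t[1])
    return terms


def _compile_invitro(topology: Topology, params):
    """Per-node term tables for fast repeated evaluation."""
    c, n = np.asarray(params.c, float), np.asarray(params.n, float)
    tables = []
    for node in ("FB", "MB", "HB", "GSK3"):
        acts, reps = [], []
        for src_i, pi, sign in _node_terms(topology, node):
            (acts if sign == ACTIVATION else reps).append((src_i, c[pi], n[pi]))
        tables.append((acts, reps))
    return tables


def _production(state, acts, reps):
    num = 0.0
    den = 1.0
    for src_i, ci, ni in acts:
        t = ci * _pow(state[src_i], ni)
        num = num + t
        den = den + t
    for src_i, ci, ni in reps:
        den = den + ci * _pow(state[src_i], ni)
    return num / den


def invitro_rhs(state, params, topology: Topology, _tables=None):
    """Time derivative of the in-vitro system.

    ``state`` has shape (5, ...) in INVITRO_NODES order; CT is a constant
    input (d[CT]/dt = 0).  Vectorised over trailing axes.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise ValueError("state components must be non-negative")
    tables = _tables if _tables is not None else _compile_invitro(topology, params)
    delta = np.asarray(params.delta, float)
    out = np.zeros_like(state)
    for k, (acts, reps) in enumerate(tables):
        out[k] = _production(state, acts, reps) - delta[k + 1] * state[k]
    # CT row stays zero
    return out


def hill_node_rhs(state, params, topology: Topology, node: str) -> float:
    """d[node]/dt at a single state, per the Hill construction rules."""
    if node not in ("FB", "MB", "HB", "GSK3"):
        raise ValueError(f"unknown in-vitro dynamical node {node!r}")
    s = np.asarray(state, dtype=float)
    if s.shape != (5,):
        raise ValueError("state must be length 5 (FB, MB, HB, GSK3, CT)")
    full = invitro_rhs(s, params, topology)
    return float(full[_IDX[node]])


def integrate_invitro(
    initial,
    params,
    topology: Topology,
    step: float = 2.0,
    max_time: float = 10_000.0,
    tol: float = 1e-8,
    clamp: tuple = (),
):
    """Integrate the in-vitro system to steady state with fixed-step RK4.

    Parameters
    ----------
    initial
        State of shape (5,) or (5, m) in INVITRO_NODES order; the trailing
        axis vectorises over independent conditions (e.g. a CT grid).
    clamp
        Names of fate nodes whose derivative is pinned at zero (knockdown /
        overexpression: the initial value then persists).

    Returns
    -------
    state : ndarray
        First state where ``max |d/dt| < tol``, or the state at
        ``max_time``.
    converged : bool or ndarray of bool
        Per-condition convergence flag.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    state = np.array(initial, dtype=float)
    scalar = state.ndim == 1
    if scalar:
        state = state[:, None]
    if np.any(state < 0):
        raise ValueError("initial state must be non-negative")
    tables = _compile_invitro(topology, params)
    clamp_idx = [_IDX[c] for c in clamp]

    def rhs(s):
        d = invitro_rhs(s, params, topology, _tables=tables)
        for i in clamp_idx:
            d[i] = 0.0
        return d

    n_steps = int(np.ceil(max_time / step))
    converged = np.zeros(state.shape[1], dtype=bool)
    for istep in range(n_steps):
        k1 = rhs(state)
        converged = np.max(np.abs(k1), axis=0) < tol
        if converged.all():
            break
        k2 = rhs(np.clip(state + 0.5 * step * k1, 0.0, None))
        k3 = rhs(np.clip(state + 0.5 * step * k2, 0.0, None))
        k4 = rhs(np.clip(state + step * k3, 0.0, None))
        state = state + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise IntegrationError(f"non-finite state at step {istep}")
        state = np.clip(state, 0.0, None)
    else:
        converged = np.max(np.abs(rhs(state)), axis=0) < tol
    if scalar:
        return state[:, 0], bool(converged[0])
    return state, converged


def invivo_cell_rhs(state, params, local_WNT, local_SHH):
    """Time derivative of the intracellular in-vivo system.

    ``state`` has shape (9, ...) in INVIVO_NODES order and is vectorised
    over trailing axes (one entry per cell).  ``local_WNT`` / ``local_SHH``
    are the morphogen concentrations currently seen by each cell; their
    reaction-diffusion dynamics live in the spatial layer, not here.

    The dorsoventral branch: Pax6 (P) is produced constitutively and
    repressed by Nkx2.2 (N) and Olig2 (O); O and N production is gated by
    Gli activity G/(1+G) with mutual/dorsal repression; Gli is driven by
    SHH/(1+SHH) and repressed by WNT.  The rostrocaudal branch: U is a
    WNT-driven bistable buffer (self-activation c15, self-repression c16)
    that represses GSK3, which feeds the FB/MB/HB tristable switch.
    """
    s = np.asarray(state, dtype=float)
    W = np.asarray(local_WNT, dtype=float)
    S = np.asarray(local_SHH, dtype=float)
    if np.any(W < 0) or np.any(S < 0):
        raise ValueError("morphogen inputs must be non-negative")
    P, O, N, G, U, GSK3, FB, MB, HB = s
    c, n, delta, dv = params.c, params.n, params.delta, params.dv

    dP = dv["alpha"] / (
        1 + _pow(N / dv["NcritP"], dv["h1"]) + _pow(O / dv["OcritP"], dv["h2"])
    ) - dv["k1"] * P
    gli_gate = G / (1 + G)
    dO = dv["beta"] * gli_gate / (
        1 + _pow(N / dv["NcritO"], dv["h3"])
    ) - dv["k2"] * O
    dN = dv["gamma"] * gli_gate / (
        1 + _pow(O / dv["OcritN"], dv["h4"]) + _pow(P / dv["PcritN"], dv["h5"])
    ) - dv["k3"] * N
    dG = dv["deltaG"] * S / (1 + S) / (
        1 + _pow(W / dv["WcritG"], dv["h6"])
    ) - dv["k4"] * G

    u_act = c[14] * _pow(W, n[14]) + c[15] * _pow(U, n[15])
    dU = u_act / (1 + u_act + c[16] * _pow(U, n[16])) - delta[5] * U

    g_act = c[12] * _pow(GSK3, n[12])
    dGSK3 = g_act / (1 + g_act + c[13] * _pow(U, n[13])) - delta[4] * GSK3

    fb_act = c[1] * _pow(GSK3, n[1])
    dFB = fb_act / (
        1 + fb_act + c[2] * _pow(MB, n[2]) + c[3] * _pow(HB, n[3])
    ) - delta[1] * FB
    mb_act = c[4] * _pow(MB, n[4])
    dMB = mb_act / (
        1 + mb_act + c[5] * _pow(FB, n[5]) + c[6] * _pow(HB, n[6])
        + c[7] * _pow(GSK3, n[7])
    ) - delta[2] * MB
    hb_act = c[8] * _pow(HB, n[8])
    dHB = hb_act / (
        1 + hb_act + c[9] * _pow(FB, n[9]) + c[10] * _pow(MB, n[10])
        + c[11] * _pow(GSK3, n[11])
    ) - delta[3] * HB

    return np.stack([dP, dO, dN, dG, dU, dGSK3, dFB, dMB, dHB])
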