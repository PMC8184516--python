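"""Dose-response simulation, in-silico knockdown/overexpression and
parameter sensitivity of the fitted in-vitro model.

A knockdown (kd) or overexpression (oex) pins a fate node's derivative at
zero so that its initial value persists for the whole trajectory: 0 for a
knockdown, 1 for an overexpression (on the max-scaled model axis).  The
steady-state expression pattern across a CT grid is the model output, each
channel scaled to [0, 1] by its maximum over the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grn import integrate_invitro
from .topology import Topology

FATE_NODES = ("FB", "MB", "HB")


@dataclass(frozen=True)
class PerturbationSpec:
    """Clamped fate nodes and their clamp levels.

    ``clamps`` maps node name to level; by default only the canonical
    levels 0 (kd) and 1 (oex) are admitted -- pass ``allow_any_level=True``
    for arbitrary clamping experiments.
    """

    clamps: tuple = ()
    allow_any_level: bool = False

    def __post_init__(self):
        for node, level in self.clamps:
            if node not in FATE_NODES:
                raise ValueError(f"only fate nodes can be clamped, not {node!r}")
            if not self.allow_any_level and level not in (0.0, 1.0):
                raise ValueError(
                    f"clamp level {level} for {node}: use 0 (kd) or 1 (oex), "
                    "or set allow_any_level"
                )

    @classmethod
    def kd(cls, *nodes) -> "PerturbationSpec":
        return cls(tuple((n, 0.0) for n in nodes))

    @classmethod
    def oex(cls, *nodes) -> "PerturbationSpec":
        return cls(tuple((n, 1.0) for n in nodes))

    @property
    def label(self) -> str:
        if not self.clamps:
            return "wildtype"
        return "+".join(
            f"{n}-{'kd' if lv == 0 else 'oex' if lv == 1 else lv}"
            for n, lv in self.clamps
        )


@dataclass
class DoseResponse:
    """Steady-state FB/MB/HB levels across a CT grid (0-1 scaled)."""

    ct_grid: np.ndarray
    steady: np.ndarray          # (3, n_ct), max-scaled per channel
    raw: np.ndarray             # (3, n_ct), unscaled steady states
    condition: str
    converged: np.ndarray       # (n_ct,) bool

    def channel(self, name: str) -> np.ndarray:
        return self.steady[FATE_NODES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"CT_uM": self.ct_grid})
        for i, ch in enumerate(FATE_NODES):
            df[ch] = self.steady[i]
        df["condition"] = self.condition
        return df


def dose_response(
    params,
    topology: Topology,
    ct_grid,
    perturbation: PerturbationSpec = PerturbationSpec(),
    step: float = 2.0,
    max_time: float = 10_000.0,
    tol: float = 1e-8,
) -> DoseResponse:
    """Steady state at each CT with clamped nodes held at their level.

    The network is initialised at FB = MB = HB = GSK3 = 1 (clamped nodes
    at their clamp level) for every CT and integrated to steady state;
    channel outputs are scaled by their maximum over the grid.  Grid
    points that fail to converge are flagged and returned as computed.
    """
    ct = np.asarray(ct_grid, dtype=float)
    if ct.size == 0 or (ct.size > 1 and not np.all(np.diff(ct) > 0)):
        raise ValueError("ct_grid must be non-empty and ascending")
    init = np.ones((5, ct.size))
    init[4] = ct
    clamp_nodes = tuple(n for n, _ in perturbation.clamps)
    for node, level in perturbation.clamps:
        init[FATE_NODES.index(node)] = level
    state, converged = integrate_invitro(
        init, params, topology, step=step, max_time=max_time, tol=tol,
        clamp=clamp_nodes,
    )
    raw = state[:3].copy()
    scale = np.maximum(raw.max(axis=1, keepdims=True), 1e-300)
    return DoseResponse(
        ct_grid=ct,
        steady=raw / scale,
        raw=raw,
        condition=perturbation.label,
        converged=np.atleast_1d(converged),
    )


def mb_window(dr: DoseResponse, strong_threshold: float = 0.5, channel: str = "MB"):
    """CT-measure of strong, dominant expression of one fate channel.

    A grid cell counts when the channel is at or above ``strong_threshold``
    (on the 0-1 scaled axis) *and* is the maximal fate channel there.  The
    window width is grid measure: cell count times grid spacing.  Returns
    ``(width_uM, (ct_lo, ct_hi))``; an empty window has width 0 and empty
    bounds.
    """
    lv = dr.channel(channel)
    dominant = np.argmax(dr.steady, axis=0) == FATE_NODES.index(channel)
    strong = (lv >= strong_threshold) & dominant
    if not strong.any():
        return 0.0, ()
    spacing = float(np.median(np.diff(dr.ct_grid))) if dr.ct_grid.size > 1 else 0.0
    width = float(strong.sum()) * spacing
    ct_sel = dr.ct_grid[strong]
    return width, (float(ct_sel.min()), float(ct_sel.max()))


def onset_ct(dr: DoseResponse, channel: str, strong_threshold: float = 0.5):
    """Smallest CT at which the channel meets the strong threshold."""
    above = dr.channel(channel) >= strong_threshold
    if not above.any():
        return None
    return float(dr.ct_grid[np.argmax(above)])


def offset_ct(dr: DoseResponse, channel: str, strong_threshold: float = 0.5):
    """Largest CT at which the channel still meets the strong threshold."""
    above = dr.channel(channel) >= strong_threshold
    if not above.any():
        return None
    return float(dr.ct_grid[::-1][np.argmax(above[::-1])])


def sensitivity_scan(
    data,
    params,
    topology: Topology,
    rel_deltas=(-0.10, -0.05, 0.0, 0.05, 0.10),
    parameters: list[str] | None = None,
    include_global: bool = True,
):
    """Cost fold-change under single-parameter and global perturbations.

    For every parameter and every relative delta, the parameter is scaled
    by (1 + delta), the steady-state dose response recomputed and the cost
    reported as a fold-change of the optimum's cost.  The global mode
    scales *all* scanned parameters jointly.  Deltas that would make a
    parameter non-positive are skipped.

    Parameters
    ----------
    data : ExpressionDataset
        The (max-normalised) reference data; ``params`` should be the
        fitted optimum for it so that delta = 0 is the cost reference.

    Returns
    -------
    table : DataFrame with columns parameter, rel_delta, cost, fold_change
    means : Series of the mean fold-change across the +-10% deltas
    """
    from .fit import cost_Ed, scaled_response

    if parameters is None:
        parameters = [f"c{i}" for i in range(1, 14)] + \
                     [f"n{i}" for i in range(1, 14)] + \
                     [f"delta{i}" for i in range(1, 5)]

    def get(p, name):
        kind, idx = name[0] if name[0] in "cn" else "delta", int(name.lstrip("cndelta"))
        return {"c": p.c, "n": p.n, "delta": p.delta}[kind][idx]

    def scaled(p, names, factor):
        q = p.copy()
        for name in names:
            kind = "delta" if name.startswith("delta") else name[0]
            idx = int(name[len(kind):])
            arr = {"c": q.c, "n": q.n, "delta": q.delta}[kind]
            arr[idx] = arr[idx] * factor
        return q

    ref_cost = cost_Ed(data.values, scaled_response(params, topology, data.ct_levels))

    def fold(cost):
        # a vanishing reference cost (perfect fit) makes any equal cost a
        # unit fold-change and any worse cost unboundedly sensitive
        if ref_cost > 0:
            return cost / ref_cost
        return 1.0 if cost <= 1e-300 else np.inf

    rows = []
    scan_sets = [(name, [name]) for name in parameters]
    if include_global:
        scan_sets.append(("all", list(parameters)))
    for label, names in scan_sets:
        for delta in rel_deltas:
            if 1.0 + delta <= 0:
                continue
            q = scaled(params, names, 1.0 + delta)
            cost = cost_Ed(data.values, scaled_response(q, topology, data.ct_levels))
            rows.append(
                {"parameter": label, "rel_delta": delta, "cost": cost,
                 "fold_change": fold(cost)}
            )
    table = pd.DataFrame(rows)
    ten = table[np.isclose(np.abs(table.rel_delta), 0.10)]
    means = ten.groupby("parameter")["fold_change"].mean()
    return table, means
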