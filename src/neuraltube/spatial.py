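"""Coupled morphogen diffusion + per-cell network simulation on a voxel tube.

Morphogens (WNT, SHH) diffuse on the 6-connected lattice of occupied
voxels by the discrete Fick law, d[X_i]/dt = D * sum_j ([X_j] - [X_i]),
with first-order decay and zero-flux behaviour at the tissue boundary
(missing neighbours simply contribute nothing).  Source voxels are held
(clamped) at their production level after every update.  Each explicit
Euler step updates the morphogen fields first and the intracellular
network second.

Diffusivities are supplied in um^2/s and converted to lattice units with
the voxel edge length; the explicit scheme demands
``dt <= 1 / (12 * D_lattice)`` (half the formal 3D stability limit, for
margin), and a dt above the bound is an error, not a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grn import INVIVO_NODES, invivo_cell_rhs
from .tube import VoxelTube

#: published initial conditions of the 3D simulations
INITIAL_LEVELS = {
    "P": 0.0, "O": 0.0, "N": 0.0, "G": 3.0, "U": 0.0,
    "GSK3": 1.0, "FB": 1.0, "MB": 0.001, "HB": 0.001,
    "WNT": 0.0, "SHH": 0.0,
}

SPECIES = tuple(INVIVO_NODES) + ("WNT", "SHH")


class SimulationDiverged(RuntimeError):
    pass


@dataclass
class SpatialState:
    """Per-voxel levels of all species on a tube's occupied voxels."""

    tube: VoxelTube
    fields: dict[str, np.ndarray]
    time: float = 0.0
    n_steps: int = 0
    converged: bool = False
    condition: str = "wildtype"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.tube.n_occupied
        for name, arr in self.fields.items():
            if arr.shape != (n,):
                raise ValueError(f"field {name} has wrong shape")

    def dense(self, name: str) -> np.ndarray:
        """Field as a dense 3D array (NaN outside the tissue)."""
        out = np.full(self.tube.occupancy.shape, np.nan)
        out[self.tube.occupancy] = self.fields[name]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Per-voxel table: x, y, z (voxel indices) plus every species."""
        idx = self.tube.occupied_indices()
        cols = {"x": idx[:, 0], "y": idx[:, 1], "z": idx[:, 2]}
        cols.update({k: v for k, v in self.fields.items()})
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def initial_state(tube: VoxelTube, modifiers: dict | None = None) -> SpatialState:
    """Published initial conditions with sources clamped at production level."""
    n = tube.n_occupied
    fields = {k: np.full(n, v, dtype=float) for k, v in INITIAL_LEVELS.items()}
    return SpatialState(tube, fields, condition=_condition_name(modifiers))


def _condition_name(modifiers):
    if not modifiers:
        return "wildtype"
    return "+".join(f"{k}-{v}" for k, v in sorted(modifiers.items()))


def source_levels(params, modifiers: dict | None = None) -> dict[str, float]:
    """Clamped source levels per morphogen, after oex/kd modifiers.

    ``modifiers`` maps morphogen name to "oex" (ten-fold production),
    "kd" (silenced sources) or a numeric multiplier.
    """
    levels = {
        "WNT": float(params.morph["WNT_prod"]),
        "SHH": float(params.morph["SHH_prod"]),
    }
    for morph, mod in (modifiers or {}).items():
        if morph not in levels:
            raise ValueError(f"unknown morphogen {morph!r}")
        if mod == "oex":
            levels[morph] *= 10.0
        elif mod == "kd":
            levels[morph] = 0.0
        else:
            levels[morph] *= float(mod)
    return levels


def stability_limit(params, tube: VoxelTube) -> float:
    """Largest admissible Euler dt for the diffusion update (seconds)."""
    h2 = tube.voxel_edge**2
    d_lat = max(params.morph["D_WNT"], params.morph["D_SHH"]) / h2
    return 1.0 / (12.0 * d_lat)


class _Lattice:
    """Precomputed neighbour structure for fast Laplacians."""

    def __init__(self, tube: VoxelTube):
        pairs = tube.neighbour_pairs()
        self.a = pairs[:, 0]
        self.b = pairs[:, 1]
        self.n = tube.n_occupied

    def laplacian(self, x: np.ndarray) -> np.ndarray:
        diff = x[self.b] - x[self.a]
        lap = np.bincount(self.a, weights=diff, minlength=self.n)
        lap -= np.bincount(self.b, weights=diff, minlength=self.n)
        return lap


def diffusion_step(
    state: SpatialState,
    tube: VoxelTube,
    D: dict[str, float],
    decay: dict[str, float],
    dt: float,
    clamp: dict[str, float] | None = None,
    _lattice: _Lattice | None = None,
) -> SpatialState:
    """One explicit-Euler diffusion + decay update of both morphogens.

    ``D`` in um^2/s, ``decay`` per second.  ``clamp`` maps morphogen name
    to the level at which its source voxels are held; omit it (or a
    morphogen) to run free diffusion without sources.  Returns the same
    state object, updated in place.
    """
    lattice = _lattice or _Lattice(tube)
    h2 = tube.voxel_edge**2
    d_lat_max = max(D.values()) / h2
    if dt > 1.0 / (12.0 * d_lat_max) + 1e-15:
        raise ValueError(
            f"dt={dt} exceeds the stability bound {1.0 / (12.0 * d_lat_max):.4g}"
        )
    clamp = clamp or {}
    for morph in ("WNT", "SHH"):
        x = state.fields[morph]
        d_lat = D[morph] / h2
        x += dt * (d_lat * lattice.laplacian(x) - decay[morph] * x)
        if morph in clamp:
            x[tube.source_mask(morph)] = clamp[morph]
        np.clip(x, 0.0, None, out=x)
    return state


def simulate_to_steady(
    tube: VoxelTube,
    params,
    dt: float = 0.05,
    tol: float = 1e-6,
    max_steps: int = 200_000,
    modifiers: dict | None = None,
    clamp_nodes: tuple = (),
    check_every: int = 25,
    network_first: bool = False,
) -> SpatialState:
    """Run the coupled model to its steady-state pattern.

    Each step: morphogen diffusion/decay update with source clamping, then
    one Euler update of the intracellular network in every cell.  Stops
    when the largest per-step change of any field falls below ``tol``
    (checked every ``check_every`` steps), or flags ``converged=False`` at
    ``max_steps``.

    ``modifiers`` applies morphogen-level perturbations (see
    :func:`source_levels`); ``clamp_nodes`` pins intracellular nodes at 0
    from a zero initial value (in-silico null mutants).  ``network_first``
    flips the within-step update order (an experiment hook: the default
    order is morphogens before network).
    """
    state = initial_state(tube, modifiers)
    lattice = _Lattice(tube)
    D = {"WNT": params.morph["D_WNT"], "SHH": params.morph["D_SHH"]}
    decay = {"WNT": params.morph["delta_WNT"], "SHH": params.morph["delta_SHH"]}
    clamp = source_levels(params, modifiers)
    for node in clamp_nodes:
        if node not in INVIVO_NODES:
            raise ValueError(f"unknown network node {node!r}")
        state.fields[node][:] = 0.0
    clamp_idx = [INVIVO_NODES.index(c) for c in clamp_nodes]

    # clamp sources at t=0 so the very first network update sees them
    for morph, level in clamp.items():
        state.fields[morph][tube.source_mask(morph)] = level

    cell = np.stack([state.fields[k] for k in INVIVO_NODES])
    for istep in range(max_steps):
        checking = (istep + 1) % check_every == 0
        if checking:
            prev_morph = (state.fields["WNT"].copy(), state.fields["SHH"].copy())

        def network_update():
            d = invivo_cell_rhs(cell, params, state.fields["WNT"],
                                state.fields["SHH"])
            for i in clamp_idx:
                d[i] = 0.0
            return d

        if network_first:
            d_cell = network_update()
            cell += dt * d_cell
            np.clip(cell, 0.0, None, out=cell)
            diffusion_step(state, tube, D, decay, dt, clamp, _lattice=lattice)
        else:
            diffusion_step(state, tube, D, decay, dt, clamp, _lattice=lattice)
            d_cell = network_update()
            cell += dt * d_cell
            np.clip(cell, 0.0, None, out=cell)
        if not np.all(np.isfinite(cell)):
            raise SimulationDiverged(f"non-finite network state at step {istep}")
        if checking:
            change = float(np.max(np.abs(d_cell))) * dt
            change = max(
                change,
                float(np.max(np.abs(state.fields["WNT"] - prev_morph[0]))),
                float(np.max(np.abs(state.fields["SHH"] - prev_morph[1]))),
            )
            if change < tol:
                state.converged = True
                state.n_steps = istep + 1
                break
    else:
        state.converged = False
        state.n_steps = max_steps
    state.time = state.n_steps * dt
    for i, name in enumerate(INVIVO_NODES):
        state.fields[name] = cell[i]
    state.meta.update({"dt": dt, "tol": tol, "clamp_nodes": list(clamp_nodes)})
    return state
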