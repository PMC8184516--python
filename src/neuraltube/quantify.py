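"""Domain quantification of 3D steady-state patterns.

Expression on a tube slice is summarised as the percentage p_gene of
occupied slice voxels whose level exceeds a threshold; whole-tube fate
maps assign each voxel the maximal channel of each network branch.  The
two branches express at different absolute scales, so they use different
thresholds: 1 for the dorsoventral channels and (numerically) zero for the
rostrocaudal channels -- implemented as "> EPS" with EPS = 1e-6 so that
floating-point dust does not count as expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial import SpatialState, simulate_to_steady
from .tube import VoxelTube

#: strict-positivity epsilon for the rostrocaudal threshold T = 0
EPS = 1e-6

RC_CHANNELS = ("FB", "MB", "HB")
DV_CHANNELS = ("P", "O", "N")
#: anatomical names of the dorsoventral fates (Pax6, Olig2, Nkx2.2)
DV_FATES = {"P": "D", "O": "L", "N": "V"}
RC_THRESHOLD = EPS
DV_THRESHOLD = 1.0

AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class DomainQuant:
    """Per-gene slice percentages and per-fate volumes for one condition."""

    condition: str
    slice_axis: str
    slice_coord_um: float
    slice_layer: int
    p_gene: dict[str, float]
    fate_volume_um3: dict[str, float] = field(default_factory=dict)
    #: percentage of slice voxels whose *dominant* fate is each label --
    #: unlike p_gene this partitions the slice, so it resolves domains even
    #: while a losing channel still carries a slowly decaying residual
    fate_percent: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"condition": self.condition, "gene": g,
             "slice": f"{self.slice_axis}={self.slice_coord_um}um", "p_gene_percent": p}
            for g, p in self.p_gene.items()
        ]
        return pd.DataFrame(rows)


def _slice_layer(tube: VoxelTube, axis: str, coord_um: float) -> int:
    """Snap a physical coordinate to the nearest voxel layer index."""
    origin = tube.meta.get("origin_um", [0.0, 0.0, 0.0])[AXES[axis]]
    layer = int(round((coord_um - origin) / tube.voxel_edge - 0.5))
    return int(np.clip(layer, 0, tube.occupancy.shape[AXES[axis]] - 1))


def quantify_slice(
    state: SpatialState,
    tube: VoxelTube,
    axis: str,
    coord_um: float,
    gene: str,
    threshold: float,
) -> float:
    """Percentage of occupied slice voxels with ``gene`` above ``threshold``.

    The comparison is strict (> threshold); pass ``threshold=0`` for the
    rostrocaudal branch and it is interpreted as ``> EPS``.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {sorted(AXES)}")
    layer = _slice_layer(tube, axis, coord_um)
    sel = [slice(None)] * 3
    sel[AXES[axis]] = layer
    occ_slice = tube.occupancy[tuple(sel)]
    if not occ_slice.any():
        raise ValueError(f"slice {axis}={coord_um}um intersects no occupied voxels")
    dense = state.dense(gene)[tuple(sel)]
    thr = max(threshold, EPS)
    vals = dense[occ_slice]
    return 100.0 * float(np.mean(vals > thr))


def fate_map(state: SpatialState):
    """Classify each voxel's rostrocaudal and dorsoventral fate.

    Per branch: the maximal channel, if it exceeds the branch threshold
    (EPS rostrocaudally, 1 dorsoventrally), else "none".  Ties resolve in
    the fixed channel orders FB > MB > HB and D > L > V.

    Returns
    -------
    rc, dv : ndarray of str
        Flat fate labels over occupied voxels.
    """
    rc_levels = np.stack([state.fields[c] for c in RC_CHANNELS])
    rc_win = np.argmax(rc_levels, axis=0)  # argmax takes the first maximum: FB>MB>HB
    rc_top = np.max(rc_levels, axis=0)
    rc = np.where(rc_top > RC_THRESHOLD, np.array(RC_CHANNELS)[rc_win], "none")

    dv_levels = np.stack([state.fields[c] for c in DV_CHANNELS])
    dv_win = np.argmax(dv_levels, axis=0)
    dv_top = np.max(dv_levels, axis=0)
    dv_names = np.array([DV_FATES[c] for c in DV_CHANNELS])
    dv = np.where(dv_top > DV_THRESHOLD, dv_names[dv_win], "none")
    return rc, dv


def quantify(
    state: SpatialState,
    tube: VoxelTube,
    axis: str = "x",
    coord_um: float = 580.0,
) -> DomainQuant:
    """Slice percentages for all six channels plus whole-tube fate volumes."""
    p = {}
    for gene in RC_CHANNELS:
        p[gene] = quantify_slice(state, tube, axis, coord_um, gene, 0.0)
    for gene in DV_CHANNELS:
        p[DV_FATES[gene]] = quantify_slice(state, tube, axis, coord_um, gene, DV_THRESHOLD)
    rc, dv = fate_map(state)
    # dominant-fate shares on the slice
    flat_idx = tube.occupied_indices()
    layer = _slice_layer(tube, axis, coord_um)
    on_slice = flat_idx[:, AXES[axis]] == layer
    fate_percent = {}
    for name in RC_CHANNELS:
        fate_percent[f"rc_{name}"] = 100.0 * float(
            np.mean(rc[on_slice] == name)) if on_slice.any() else 0.0
    for name in DV_FATES.values():
        fate_percent[f"dv_{name}"] = 100.0 * float(
            np.mean(dv[on_slice] == name)) if on_slice.any() else 0.0
    vol = tube.voxel_edge**3
    volumes = {}
    for name in RC_CHANNELS + ("none_rc",):
        key = name if name != "none_rc" else "none"
        volumes[f"rc_{name}"] = float(np.sum(rc == key)) * vol
    for name in tuple(DV_FATES.values()) + ("none_dv",):
        key = name if name != "none_dv" else "none"
        volumes[f"dv_{name}"] = float(np.sum(dv == key)) * vol
    return DomainQuant(
        condition=state.condition,
        slice_axis=axis,
        slice_coord_um=coord_um,
        slice_layer=layer,
        p_gene=p,
        fate_volume_um3=volumes,
        fate_percent=fate_percent,
    )


def compare_conditions(wt: DomainQuant, cond: DomainQuant) -> pd.DataFrame:
    """Per-domain fold-change (condition / wildtype) and percent change.

    A domain absent in the wildtype has undefined fold-change, marked with
    ``inf`` (and NaN percent change if also absent in the condition).
    """
    if (wt.slice_axis, wt.slice_layer) != (cond.slice_axis, cond.slice_layer):
        raise ValueError("slice specifications differ between conditions")
    rows = []
    for gene in wt.p_gene:
        w, c = wt.p_gene[gene], cond.p_gene.get(gene, np.nan)
        if w > 0:
            fold = c / w
        else:
            fold = np.inf if c > 0 else np.nan
        rows.append(
            {"domain": gene, "wt_percent": w, "cond_percent": c,
             "fold_change": fold, "percent_change": c - w}
        )
    return pd.DataFrame(rows)


MUTANTS = {
    "O-null": ("O",),
    "P-null": ("P",),
    "double-null": ("O", "P"),
}


def mutant_simulation(tube: VoxelTube, params, mutant: str, **sim_kwargs) -> SpatialState:
    """Steady state with the named dorsoventral node(s) clamped at zero."""
    if mutant not in MUTANTS:
        raise ValueError(f"unknown mutant {mutant!r}; choose from {sorted(MUTANTS)}")
    state = simulate_to_steady(tube, params, clamp_nodes=MUTANTS[mutant], **sim_kwargs)
    state.condition = mutant
    return state
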