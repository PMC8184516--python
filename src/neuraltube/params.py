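"""Model parameters and their (de)serialisation.

All rate constants and levels are dimensionless except where noted: CT
carries the micromolar semantics of the inhibitor concentration supplied to
the cultures, morphogen diffusivities are in um^2/s and voxel geometry in
um.  A complete default set (the published optimum of the in-vitro fit plus
the morphogen and dorsoventral constants used for the 3D simulations) ships
with the package and is the single source of truth for "default" numbers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

#: canonical parameter index of every possible in-vitro edge
#: (index 0 is the forebrain self-interaction, pruned from the final model)
EDGE_PARAM_INDEX = {
    ("FB", "FB"): 0,
    ("FB", "GSK3"): 1,
    ("FB", "MB"): 2,
    ("FB", "HB"): 3,
    ("MB", "MB"): 4,
    ("MB", "FB"): 5,
    ("MB", "HB"): 6,
    ("MB", "GSK3"): 7,
    ("HB", "HB"): 8,
    ("HB", "FB"): 9,
    ("HB", "MB"): 10,
    ("HB", "GSK3"): 11,
    ("GSK3", "GSK3"): 12,
    ("GSK3", "CT"): 13,
}

DV_KEYS = (
    "alpha", "beta", "gamma", "deltaG",
    "k1", "k2", "k3", "k4",
    "h1", "h2", "h3", "h4", "h5", "h6",
    "NcritP", "OcritP", "NcritO", "OcritN", "PcritN", "WcritG",
)

MORPH_KEYS = (
    "D_WNT", "D_SHH", "delta_WNT", "delta_SHH", "WNT_prod", "SHH_prod",
)


@dataclass
class ParameterSet:
    """Rate constants, Hill coefficients and degradation rates.

    Attributes
    ----------
    c, n
        Arrays of length 17; entry ``i`` is c_i / n_i.  Index 0 is the
        forebrain self-interaction used only during topology selection.
        c1..c13 parametrise the in-vitro network (see EDGE_PARAM_INDEX),
        c14..c16 the WNT-driven buffer node of the in-vivo system.
    delta
        Array of length 6; entry ``i`` (1-based) is the degradation rate of
        FB, MB, HB, GSK3 and the buffer node U respectively.
    dv
        Dorsoventral-branch constants (Gli/Pax6/Olig2/Nkx2.2 dynamics).
    morph
        Morphogen diffusivities, decay rates and clamped source levels.
    """

    c: np.ndarray
    n: np.ndarray
    delta: np.ndarray
    dv: dict = field(default_factory=dict)
    morph: dict = field(default_factory=dict)

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.c.shape != (17,) or self.n.shape != (17,):
            raise ValueError("c and n must have 17 entries (index 0..16)")
        if self.delta.shape != (6,):
            raise ValueError("delta must have 6 entries (index 0 unused)")
        if np.any(self.c[1:] <= 0) or np.any(self.n[1:] <= 0):
            raise ValueError("all rate constants and Hill coefficients must be positive")
        if np.any(self.delta[1:] <= 0):
            raise ValueError("all degradation rates must be positive")
        for k, v in {**self.dv, **self.morph}.items():
            if k.endswith("_prod"):
                if v < 0:
                    raise ValueError(f"{k} must be non-negative")
            elif v <= 0:
                raise ValueError(f"{k} must be positive")

    # -- flat key/value config interface ---------------------------------
    def to_dict(self) -> dict:
        out = {f"c{i}": float(self.c[i]) for i in range(1, 17)}
        out.update({f"n{i}": float(self.n[i]) for i in range(1, 17)})
        out.update({f"delta{i}": float(self.delta[i]) for i in range(1, 6)})
        out.update({k: float(v) for k, v in self.dv.items()})
        out.update({k: float(v) for k, v in self.morph.items()})
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        d = dict(d)
        c = np.zeros(17)
        n = np.ones(17)
        delta = np.ones(6)
        c[0], n[0] = d.pop("c0", 0.0), d.pop("n0", 1.0)
        for i in range(1, 17):
            c[i] = d.pop(f"c{i}")
            n[i] = d.pop(f"n{i}")
        for i in range(1, 6):
            delta[i] = d.pop(f"delta{i}")
        dv = {k: d.pop(k) for k in DV_KEYS if k in d}
        morph = {k: d.pop(k) for k in MORPH_KEYS if k in d}
        if d:
            raise ValueError(f"unknown parameter keys: {sorted(d)}")
        return cls(c=c, n=n, delta=delta, dv=dv, morph=morph)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def copy(self) -> "ParameterSet":
        return replace(
            self,
            c=self.c.copy(),
            n=self.n.copy(),
            delta=self.delta.copy(),
            dv=dict(self.dv),
            morph=dict(self.morph),
        )


def published_defaults() -> ParameterSet:
    """The published parameter set (in-vitro optimum + 3D constants)."""
    ref = importlib.resources.files("neuraltube") / "data" / "published_defaults.yaml"
    with ref.open() as fh:
        return ParameterSet.from_dict(yaml.safe_load(fh))
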