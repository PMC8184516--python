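"""Parametric 3D voxel neural-tube geometries.

The simulated tissue is a hollow tube of cells on a cubic lattice (voxel
edge 10 um by default, one cell per voxel).  The tube runs rostro-caudally
along x, with y the ventral-to-dorsal axis and z left-right; the rostral
portion is bent ventrally, emulating the cephalic flexure, so that the
dorsal wall lies on the outer side of the curve.

Morphogen secretion sites are painted onto the wall as voxel roles:

=====  ========  =============================================
role   morphogen location
=====  ========  =============================================
fp     SHH       floor plate: ventral stripe along the tube
zli    SHH       zona limitans: transverse ring in the forebrain
rp     WNT       roof plate: dorsal stripe (by default starting
                 caudal of the forebrain territory)
io     WNT       isthmic organiser: transverse ring at the
                 midbrain-hindbrain boundary
v      WNT       ventral midbrain patch
=====  ========  =============================================

Where stripes and rings overlap, the transverse sources win (precedence
io > zli > v > fp > rp); every labelled voxel is part of the occupied wall.

This is a deliberately schematic, parametric stand-in for the anatomical
voxel model used in the original study, which is not derivable from the
publication; all quantitative 3D outputs are therefore geometry-preset
dependent and validated as qualitative properties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

ROLE_NAMES = ("plain", "rp", "fp", "zli", "io", "v")
ROLE_CODES = {name: i for i, name in enumerate(ROLE_NAMES)}
WNT_ROLES = ("rp", "io", "v")
SHH_ROLES = ("fp", "zli")


@dataclass
class VoxelTube:
    """Labelled 3D occupancy grid.

    ``occupancy`` is a boolean array (nx, ny, nz); ``roles`` an int8 array
    of the same shape holding ROLE_CODES (0 = plain wall cell).
    ``voxel_edge`` is the lattice spacing in um.
    """

    occupancy: np.ndarray
    roles: np.ndarray
    voxel_edge: float = 10.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.roles = np.asarray(self.roles, dtype=np.int8)
        if self.occupancy.shape != self.roles.shape:
            raise ValueError("occupancy and roles shapes differ")
        if np.any(self.roles[~self.occupancy] != 0):
            raise ValueError("role labels on unoccupied voxels")
        if self.voxel_edge <= 0:
            raise ValueError("voxel_edge must be positive")

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    def occupied_indices(self) -> np.ndarray:
        """(n_occupied, 3) integer voxel coordinates, C-order."""
        return np.argwhere(self.occupancy)

    def role_mask(self, role: str) -> np.ndarray:
        """Flat boolean mask over occupied voxels for one role."""
        code = ROLE_CODES[role]
        return self.roles[self.occupancy] == code

    def source_mask(self, morphogen: str) -> np.ndarray:
        """Flat mask over occupied voxels of all sources of WNT or SHH."""
        roles = {"WNT": WNT_ROLES, "SHH": SHH_ROLES}[morphogen]
        flat = self.roles[self.occupancy]
        return np.isin(flat, [ROLE_CODES[r] for r in roles])

    def neighbour_pairs(self) -> np.ndarray:
        """(m, 2) flat-index pairs of 6-connected occupied neighbours.

        Flat indices refer to positions in :meth:`occupied_indices` order.
        Each unordered pair appears once.
        """
        occ = self.occupancy
        flat = -np.ones(occ.shape, dtype=np.int64)
        flat[occ] = np.arange(self.n_occupied)
        pairs = []
        for axis in range(3):
            a = flat[tuple(slice(None, -1) if ax == axis else slice(None) for ax in range(3))]
            b = flat[tuple(slice(1, None) if ax == axis else slice(None) for ax in range(3))]
            ok = (a >= 0) & (b >= 0)
            pairs.append(np.stack([a[ok], b[ok]], axis=1))
        return np.concatenate(pairs, axis=0)

    def n_connected_components(self) -> int:
        """Number of 6-connected components of the occupied set."""
        from scipy.ndimage import label

        structure = np.zeros((3, 3, 3), dtype=bool)
        structure[1, 1, 1] = structure[0, 1, 1] = structure[2, 1, 1] = True
        structure[1, 0, 1] = structure[1, 2, 1] = True
        structure[1, 1, 0] = structure[1, 1, 2] = True
        _, n = label(self.occupancy, structure=structure)
        return int(n)

    # -- plain-text persistence ------------------------------------------
    def to_json(self, path) -> None:
        """Write the grid as JSON: run-length-encoded occupancy + role list."""
        occ = self.occupancy.ravel()
        runs, start = [], 0
        current = bool(occ[0]) if occ.size else False
        for i in range(1, occ.size):
            if occ[i] != current:
                runs.append([int(current), i - start])
                start, current = i, bool(occ[i])
        if occ.size:
            runs.append([int(current), occ.size - start])
        roles = [
            [int(x), int(y), int(z), ROLE_NAMES[self.roles[x, y, z]]]
            for x, y, z in np.argwhere(self.roles > 0)
        ]
        doc = {
            "shape": list(self.occupancy.shape),
            "voxel_edge_um": self.voxel_edge,
            "occupancy_rle": runs,
            "roles": roles,
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "VoxelTube":
        with open(path) as fh:
            doc = json.load(fh)
        shape = tuple(doc["shape"])
        occ = np.zeros(int(np.prod(shape)), dtype=bool)
        pos = 0
        for val, length in doc["occupancy_rle"]:
            occ[pos : pos + length] = bool(val)
            pos += length
        occ = occ.reshape(shape)
        roles = np.zeros(shape, dtype=np.int8)
        for x, y, z, name in doc["roles"]:
            roles[x, y, z] = ROLE_CODES[name]
        return cls(occ, roles, doc["voxel_edge_um"], doc.get("meta", {}))


def _centreline(length, bend_angle, bend_start, bend_end, ds):
    """Sampled centreline points, headings and local dorsal normals.

    The curve lies in the x-y plane.  Arc length s runs rostral (0) to
    caudal (length); the segment [bend_start, bend_end] is a circular arc
    of total turning ``bend_angle`` (radians) and the caudal segment is
    parallel to +x.  The local dorsal direction is the in-plane normal on
    the outer side of the bend.
    """
    s = np.arange(0.0, length + 0.5 * ds, ds)
    # heading angle relative to +x, measured so that rostral of the bend
    # the tube points ventral-ward (cephalic flexure)
    ang = np.zeros_like(s)
    inside = (s >= bend_start) & (s <= bend_end)
    before = s < bend_start
    span = max(bend_end - bend_start, ds)
    ang[inside] = -bend_angle * (bend_end - s[inside]) / span
    ang[before] = -bend_angle
    heading = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    # integrate positions
    pos = np.zeros((len(s), 2))
    pos[1:] = np.cumsum(0.5 * (heading[1:] + heading[:-1]) * ds, axis=0)
    # dorsal normal: heading rotated +90 deg in the x-y plane
    dorsal = np.stack([-heading[:, 1], heading[:, 0]], axis=1)
    return s, pos, heading, dorsal


def build_tube(
    length: float = 1000.0,
    outer_radius: float = 120.0,
    wall_thickness: float = 30.0,
    bend_angle_deg: float = 90.0,
    bend_start: float = 200.0,
    bend_end: float = 450.0,
    voxel_edge: float = 10.0,
    zli_s: float = 300.0,
    io_s: float = 700.0,
    v_range: tuple = (450.0, 600.0),
    rp_range: tuple = (350.0, 1000.0),
    ring_width: float = 30.0,
    stripe_half_angle_deg: float = 30.0,
    patch_half_angle_deg: float = 60.0,
    sources: tuple = ("rp", "fp", "zli", "io", "v"),
) -> VoxelTube:
    """Voxelise a bent hollow tube and paint the morphogen sources.

    All lengths in um.  ``bend_angle_deg = 0`` gives a straight cylinder.
    ``sources`` selects which roles are painted (e.g. drop ``"rp"`` to
    disable roof-plate secretion).  Deterministic for fixed parameters.
    """
    if not (outer_radius > wall_thickness > 0):
        raise ValueError("need outer_radius > wall_thickness > 0")
    if length <= 0 or voxel_edge <= 0:
        raise ValueError("degenerate dimensions")
    inner_radius = outer_radius - wall_thickness
    ds = voxel_edge / 4.0
    s, pos, heading, dorsal = _centreline(
        length, np.deg2rad(bend_angle_deg), bend_start, bend_end, ds
    )
    tree = cKDTree(pos)

    lo = pos.min(axis=0) - outer_radius - voxel_edge
    hi = pos.max(axis=0) + outer_radius + voxel_edge
    nx = int(np.ceil((hi[0] - lo[0]) / voxel_edge)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / voxel_edge)) + 1
    nz = 2 * int(np.ceil(outer_radius / voxel_edge)) + 3

    xs = lo[0] + (np.arange(nx) + 0.5) * voxel_edge
    ys = lo[1] + (np.arange(ny) + 0.5) * voxel_edge
    zs = (np.arange(nz) - (nz - 1) / 2.0) * voxel_edge
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    centres_xy = np.stack([X.ravel(), Y.ravel()], axis=1)

    _, nearest = tree.query(centres_xy)
    rel = centres_xy - pos[nearest]
    h = heading[nearest]
    d = dorsal[nearest]
    along = np.einsum("ij,ij->i", rel, h)
    r_dorsal = np.einsum("ij,ij->i", rel, d)
    r_z = Z.ravel()
    # radial distance is measured in the plane normal to the local heading
    rho = np.sqrt(r_dorsal**2 + r_z**2)
    s_here = s[nearest] + along
    occ = (
        (rho > inner_radius)
        & (rho <= outer_radius)
        & (s_here >= 0.0)
        & (s_here <= length)
        & (np.abs(along) <= 2 * ds + voxel_edge)
    )

    phi = np.abs(np.arctan2(r_z, r_dorsal))  # 0 = dorsal, pi = ventral
    stripe = np.deg2rad(stripe_half_angle_deg)
    patch = np.deg2rad(patch_half_angle_deg)
    role = np.zeros(occ.shape, dtype=np.int8)

    def paint(name, mask):
        if name in sources:
            role[occ & mask & (role == 0)] = ROLE_CODES[name]

    # transverse sources take precedence over the longitudinal stripes
    paint("io", np.abs(s_here - io_s) <= ring_width / 2)
    paint("zli", np.abs(s_here - zli_s) <= ring_width / 2)
    paint("v", (s_here >= v_range[0]) & (s_here <= v_range[1]) & (np.pi - phi <= patch))
    paint("fp", np.pi - phi <= stripe)
    paint("rp", (phi <= stripe) & (s_here >= rp_range[0]) & (s_here <= rp_range[1]))

    occupancy = occ.reshape(X.shape)
    roles = role.reshape(X.shape)
    meta = {
        "length_um": length,
        "outer_radius_um": outer_radius,
        "wall_thickness_um": wall_thickness,
        "bend_angle_deg": bend_angle_deg,
        "origin_um": [float(lo[0]), float(lo[1]), float(zs[0] - 0.5 * voxel_edge)],
        "sources": list(sources),
    }
    return VoxelTube(occupancy, roles, voxel_edge, meta)


def default_tube(**overrides) -> VoxelTube:
    """The package's default bent-tube preset (~1000 um rostral tube)."""
    return build_tube(**overrides)
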