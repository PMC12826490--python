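"""Cubed-spheroid surface mesh.

The prolate spheroid (semi-axes ``L_AP`` along z, ``L_DV`` along x and y) is
meshed by the cubed-sphere construction: regular grids on the faces of the
inscribed cube of half-side ``a = L_AP/sqrt(3)`` are projected radially onto
the sphere of radius ``L_AP`` and then onto the spheroid orthogonally to the
z-axis (scaling x and y by ``L_DV/L_AP``).  This avoids the polar degeneracy
of prolate spheroidal coordinates.

By the dorsoventral mirror symmetry of the problem only the half-spheroid
``y >= 0`` is represented; it is covered by 8 logically rectangular n-by-n
zones (posterior pole cap, dorsal, lateral, ventral; mirrored in z for the
anterior half).  Nodes shared by adjacent zones are stored once: a global
node table carries coordinates, and each zone holds an (n, n) index array
into it, which makes inter-zone continuity automatic.  Surface integrals
over the half mesh are doubled to give full-spheroid values; the y = 0 rim
carries the reflection (Neumann) symmetry condition.

For differential operators the quads of each zone are split into triangles;
the triangulation, node areas and the minimum edge length are computed here.
Because the cube-face direction vectors are resolution-fixed, remeshing to
new semi-axes only rescales coordinate columns, preserving every logical
node identity (the coordinate-preserving growth map).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

__all__ = ["CubedSpheroidMesh", "build_mesh", "surface_area", "remesh_to"]

_SQRT3 = math.sqrt(3.0)

# zone layout: (face, u-range spec, v-range spec); see _build_unit_nodes
ZONE_NAMES = [
    "posterior_cap",
    "dorsal_posterior",
    "lateral_posterior",
    "ventral_posterior",
    "anterior_cap",
    "dorsal_anterior",
    "lateral_anterior",
    "ventral_anterior",
]


def _unit_cache() -> Dict[int, tuple]:
    return _UNIT_CACHE


_UNIT_CACHE: Dict[int, tuple] = {}


def _build_unit_structure(n: int):
    """Resolution-only part of the construction.

    Returns unit direction vectors (radial projections of the cube grid
    points), per-zone global index arrays, the triangulation, and boundary
    bookkeeping.  Cached per n.
    """
    if n in _UNIT_CACHE:
        return _UNIT_CACHE[n]
    if n < 4:
        raise ValueError("mesh resolution n must be at least 4")

    # integer lattice, spacing a/(n-1); full span [-(n-1), n-1]
    full = np.arange(-(n - 1), n, 2)          # n values, step 2
    half_pos = np.arange(0, n, 1)             # n values, step 1, [0, n-1]
    half_neg = -half_pos[::-1]                # [-(n-1), 0]

    def grid(us, vs, maker):
        U, V = np.meshgrid(us, vs, indexing="ij")
        return maker(U, V)

    m = n - 1
    zones_int: List[np.ndarray] = []
    # posterior cap: face z=+a; u=x in [-a,a], v=y in [0,a]
    zones_int.append(grid(full, half_pos, lambda U, V: np.stack(
        [U, V, np.full_like(U, m)], axis=-1)))
    # dorsal posterior: face x=+a; u=y in [0,a], v=z in [0,a]
    zones_int.append(grid(half_pos, half_pos, lambda U, V: np.stack(
        [np.full_like(U, m), U, V], axis=-1)))
    # lateral posterior: face y=+a; u=x in [-a,a], v=z in [0,a]
    zones_int.append(grid(full, half_pos, lambda U, V: np.stack(
        [U, np.full_like(U, m), V], axis=-1)))
    # ventral posterior: face x=-a; u=y in [0,a], v=z in [0,a]
    zones_int.append(grid(half_pos, half_pos, lambda U, V: np.stack(
        [np.full_like(U, -m), U, V], axis=-1)))
    # anterior mirrors (z -> -z)
    for zi in range(4):
        mirrored = zones_int[zi].copy()
        mirrored[..., 2] *= -1
        zones_int.append(mirrored)

    # global dedup on the exact integer lattice
    flat = np.concatenate([z.reshape(-1, 3) for z in zones_int], axis=0)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    zone_index: List[np.ndarray] = []
    off = 0
    for z in zones_int:
        cnt = z.shape[0] * z.shape[1]
        zone_index.append(inverse[off:off + cnt].reshape(z.shape[:2]))
        off += cnt

    # unit direction vectors: cube point (scaled to half-side 1) normalized
    cube = uniq.astype(float) / m
    unit = cube / np.linalg.norm(cube, axis=1, keepdims=True)

    # triangulation: split each quad along its shorter diagonal is not
    # needed; a fixed diagonal suffices on this quasi-uniform grid
    tris = []
    for zidx in zone_index:
        i00 = zidx[:-1, :-1].ravel()
        i10 = zidx[1:, :-1].ravel()
        i01 = zidx[:-1, 1:].ravel()
        i11 = zidx[1:, 1:].ravel()
        tris.append(np.stack([i00, i10, i11], axis=1))
        tris.append(np.stack([i00, i11, i01], axis=1))
    tri = np.concatenate(tris, axis=0)
    # drop degenerate triangles from shared cube edges (duplicate vertices)
    good = (
        (tri[:, 0] != tri[:, 1])
        & (tri[:, 1] != tri[:, 2])
        & (tri[:, 0] != tri[:, 2])
    )
    tri = tri[good]
    # deduplicate triangles that appear in two zones (cube-edge quads)
    tri_sorted = np.sort(tri, axis=1)
    _, keep = np.unique(tri_sorted, axis=0, return_index=True)
    tri = tri[np.sort(keep)]

    # fix orientation so triangle normals point outward
    p0, p1, p2 = cube[tri[:, 0]], cube[tri[:, 1]], cube[tri[:, 2]]
    nvec = np.cross(p1 - p0, p2 - p0)
    centroid = (p0 + p1 + p2) / 3.0
    flip = np.einsum("ij,ij->i", nvec, centroid) < 0
    tri[flip] = tri[flip][:, [0, 2, 1]]

    symmetry_nodes = np.abs(uniq[:, 1]) == 0

    result = (unit, zone_index, tri, symmetry_nodes)
    _UNIT_CACHE[n] = result
    return result


@dataclass
class CubedSpheroidMesh:
    """Structured multi-zone mesh of the half-spheroid ``y >= 0``.

    Attributes
    ----------
    n : nodes per zone edge.
    node_xyz : (N, 3) global node coordinates, µm.
    zone_index : list of 8 (n, n) arrays of global node ids.
    tri : (T, 3) triangle connectivity (outward-oriented).
    node_area : (N,) lumped control areas, µm² (one third of each incident
        triangle); half-surface values.
    symmetry_nodes : boolean mask of nodes on the y = 0 reflection rim.
    """

    n: int
    L_AP: float
    L_DV: float
    node_xyz: np.ndarray
    zone_index: List[np.ndarray]
    tri: np.ndarray
    symmetry_nodes: np.ndarray
    _unit: np.ndarray

    # geometry-derived, filled by _update_metrics
    tri_area: np.ndarray = None
    node_area: np.ndarray = None
    h_min: float = None
    eta: np.ndarray = None
    theta: np.ndarray = None

    def _update_metrics(self) -> None:
        xyz = self.node_xyz
        p0 = xyz[self.tri[:, 0]]
        p1 = xyz[self.tri[:, 1]]
        p2 = xyz[self.tri[:, 2]]
        cr = np.cross(p1 - p0, p2 - p0)
        self.tri_area = 0.5 * np.linalg.norm(cr, axis=1)
        area = np.zeros(xyz.shape[0])
        np.add.at(area, self.tri.ravel(), np.repeat(self.tri_area / 3.0, 3))
        self.node_area = area
        e = np.concatenate(
            [
                np.linalg.norm(p1 - p0, axis=1),
                np.linalg.norm(p2 - p1, axis=1),
                np.linalg.norm(p0 - p2, axis=1),
            ]
        )
        self.h_min = float(e.min())
        rho = np.hypot(xyz[:, 0], xyz[:, 1])
        self.eta = np.arctan2(rho / self.L_DV, xyz[:, 2] / self.L_AP)
        self.theta = np.arctan2(xyz[:, 1], xyz[:, 0])

    @property
    def n_nodes(self) -> int:
        return self.node_xyz.shape[0]

    def ellipsoid_residual(self) -> np.ndarray:
        """|(x/L_DV)^2 + (y/L_DV)^2 + (z/L_AP)^2 - 1| per node."""
        x, y, z = self.node_xyz.T
        return np.abs(
            (x / self.L_DV) ** 2 + (y / self.L_DV) ** 2 + (z / self.L_AP) ** 2 - 1.0
        )

    def interface_pairs(self) -> List[Tuple[Tuple[int, np.ndarray], Tuple[int, np.ndarray]]]:
        """Pairs of (zone, flat node positions) sharing global nodes between
        adjacent zones.  Because zones index a global node table, paired
        entries refer to the same coordinates; the pairing is involutive by
        construction."""
        pairs = []
        for zi in range(8):
            for zj in range(zi + 1, 8):
                a = self.zone_index[zi].ravel()
                b = self.zone_index[zj].ravel()
                shared, ia, ib = np.intersect1d(a, b, return_indices=True)
                if shared.size:
                    pairs.append(((zi, ia), (zj, ib)))
        return pairs

    def export_arrays(self) -> Dict[str, np.ndarray]:
        """Portable array snapshot (coordinates + connectivity) for
        visualization or archiving."""
        out = {
            "node_xyz": self.node_xyz,
            "tri": self.tri,
            "node_area": self.node_area,
            "symmetry_nodes": self.symmetry_nodes,
        }
        for i, zidx in enumerate(self.zone_index):
            out[f"zone_{i}_index"] = zidx
        return out


def build_mesh(n: int, L_AP: float, L_DV: float) -> CubedSpheroidMesh:
    """Build the cubed-spheroid mesh (cube grid -> radial projection to the
    sphere of radius L_AP -> z-orthogonal projection to the spheroid)."""
    if L_AP <= 0 or L_DV <= 0:
        raise ValueError("semi-axes must be positive")
    unit, zone_index, tri, symmetry_nodes = _build_unit_structure(n)
    xyz = np.column_stack(
        [L_DV * unit[:, 0], L_DV * unit[:, 1], L_AP * unit[:, 2]]
    )
    mesh = CubedSpheroidMesh(
        n=n,
        L_AP=L_AP,
        L_DV=L_DV,
        node_xyz=xyz,
        zone_index=zone_index,
        tri=tri,
        symmetry_nodes=symmetry_nodes,
        _unit=unit,
    )
    mesh._update_metrics()
    return mesh


def remesh_to(mesh: CubedSpheroidMesh, L_AP: float, L_DV: float) -> CubedSpheroidMesh:
    """Same logical mesh on new semi-axes; node (eta, theta) identities are
    preserved so field arrays carry over index-wise."""
    return build_mesh(mesh.n, L_AP, L_DV)


def surface_area(mesh: CubedSpheroidMesh) -> float:
    """Total spheroid surface area (µm²): half-mesh sum doubled."""
    return float(2.0 * mesh.tri_area.sum())


def prolate_area_closed_form(L_AP: float, L_DV: float) -> float:
    """Analytic prolate-spheroid area 2 pi b^2 + 2 pi a b asin(e)/e."""
    a, b = L_AP, L_DV
    if abs(a - b) < 1e-12 * a:
        return 4.0 * math.pi * a * b
    e = math.sqrt(1.0 - (b / a) ** 2)
    return 2.0 * math.pi * b**2 + 2.0 * math.pi * a * b * math.asin(e) / e
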