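"""Discrete surface operators on the cubed-spheroid mesh.

The Laplace–Beltrami operator is assembled as a linear (cotangent) finite
element stiffness matrix with a lumped mass matrix: for the piecewise-linear
triangulated surface,

    (K f)_i = sum_j  (cot a_ij + cot b_ij)/2 (f_i - f_j),
    Delta f ~ -K f / A,

where ``A`` holds the lumped node areas.  ``K`` is symmetric with zero row
sums, so constants are in its kernel and the semi-discrete heat equation
conserves the discrete surface integral *exactly* — the property the growth
and conservation contracts of the integrator rely on.  The y = 0 mirror rim
needs no special treatment: the natural (do-nothing) boundary condition of
the element formulation is the reflection/Neumann condition.

Surface transport ``div(u f)`` is discretized by a vertex-centered
finite-volume scheme on the median dual mesh with first-order upwinding:
fluxes are antisymmetric per dual face, so the surface integral of the
output vanishes identically (mass conservation) on the closed surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .geometry import spheroid_normals
from .mesh import CubedSpheroidMesh

__all__ = [
    "SurfaceField",
    "SurfaceOperators",
    "laplace_beltrami",
    "surface_divergence_transport",
    "integrate_surface",
    "TangencyError",
]

#: tolerance for |u.n|/max|u| of tangential vector fields
TANGENCY_TOL = 1e-8


class TangencyError(ValueError):
    """Raised when a vector field handed to a transport operator has a
    non-negligible component along the surface normal."""


@dataclass
class SurfaceField:
    """One scalar per mesh node with light metadata."""

    values: np.ndarray
    time_hr: Optional[float] = None
    species: Optional[str] = None


def _values(field) -> np.ndarray:
    if isinstance(field, SurfaceField):
        return np.asarray(field.values, dtype=float)
    return np.asarray(field, dtype=float)


def cotan_stiffness(xyz: np.ndarray, tri: np.ndarray) -> sp.csr_matrix:
    """Symmetric zero-row-sum stiffness matrix of the triangulated surface."""
    i0, i1, i2 = tri[:, 0], tri[:, 1], tri[:, 2]
    p0, p1, p2 = xyz[i0], xyz[i1], xyz[i2]
    # cotangent at each vertex = dot of adjacent edges / (2 * area)
    cr = np.cross(p1 - p0, p2 - p0)
    dbl_area = np.linalg.norm(cr, axis=1)
    cot0 = np.einsum("ij,ij->i", p1 - p0, p2 - p0) / dbl_area
    cot1 = np.einsum("ij,ij->i", p0 - p1, p2 - p1) / dbl_area
    cot2 = np.einsum("ij,ij->i", p0 - p2, p1 - p2) / dbl_area
    # edge (1,2) opposite vertex 0 gets cot0/2, etc.
    rows = np.concatenate([i1, i2, i0, i2, i0, i1])
    cols = np.concatenate([i2, i1, i2, i0, i1, i0])
    w = np.concatenate([cot0, cot0, cot1, cot1, cot2, cot2]) / 2.0
    n = xyz.shape[0]
    W = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    K = sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W
    return K.tocsr()


class SurfaceOperators:
    """Operator bundle for one mesh snapshot.

    Holds the stiffness matrix, lumped areas, node normals and the edge
    structure reused by the transport scheme.
    """

    def __init__(self, mesh: CubedSpheroidMesh):
        self.mesh = mesh
        self.K = cotan_stiffness(mesh.node_xyz, mesh.tri)
        self.area = mesh.node_area
        self.normals = spheroid_normals(mesh.node_xyz, mesh.L_AP, mesh.L_DV)
        self._edge_struct = None

    # -- Laplace-Beltrami -------------------------------------------------
    def laplacian(self, f: np.ndarray) -> np.ndarray:
        f = _values(f)
        if f.shape[0] != self.mesh.n_nodes:
            raise ValueError("field length does not match mesh size")
        return -(self.K @ f) / self.area

    def rayleigh_quotient(self, f: np.ndarray) -> float:
        """Discrete eigenvalue estimate f'Kf / f'Af (positive for -Delta)."""
        f = _values(f)
        return float((f @ (self.K @ f)) / (f @ (self.area * f)))

    # -- transport --------------------------------------------------------
    def _edges(self):
        """Median-dual edge structure: for every directed triangle half-edge
        (i, j) the dual-face vector (normal scaled by segment length) from
        the edge midpoint to the triangle centroid."""
        if self._edge_struct is not None:
            return self._edge_struct
        mesh = self.mesh
        xyz = mesh.node_xyz
        tri = mesh.tri
        p = xyz[tri]                       # (T, 3 vertices, 3)
        centroid = p.mean(axis=1)
        nvec = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        nhat = nvec / np.linalg.norm(nvec, axis=1, keepdims=True)
        ii, jj, dual = [], [], []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            i, j = tri[:, a], tri[:, b]
            mid = 0.5 * (xyz[i] + xyz[j])
            seg = centroid - mid
            nd = np.cross(nhat, seg)       # in-plane normal, |nd| = |seg|
            # orient from i-side toward j-side
            sgn = np.sign(np.einsum("ij,ij->i", nd, xyz[j] - xyz[i]))
            nd *= sgn[:, None]
            ii.append(i)
            jj.append(j)
            dual.append(nd)
        self._edge_struct = (
            np.concatenate(ii),
            np.concatenate(jj),
            np.concatenate(dual, axis=0),
        )
        return self._edge_struct

    def check_tangent(self, u: np.ndarray) -> None:
        u = np.asarray(u, dtype=float)
        umax = np.abs(u).max()
        if umax == 0:
            return
        normal_part = np.abs(np.einsum("ij,ij->i", u, self.normals)).max()
        if normal_part / umax > TANGENCY_TOL:
            raise TangencyError(
                f"vector field is not tangent: |u.n|/|u| = {normal_part / umax:.2e}"
            )

    def transport_coefficients(self, u: np.ndarray):
        """Signed dual-face volume fluxes u_ij (µm²/hr) for a node vector
        field ``u``; antisymmetric per undirected dual face by construction."""
        self.check_tangent(u)
        ii, jj, dual = self._edges()
        umid = 0.5 * (u[ii] + u[jj])
        return ii, jj, np.einsum("ij,ij->i", umid, dual)

    def divergence_transport(self, u: np.ndarray, f: np.ndarray) -> np.ndarray:
        """First-order upwind div(u f); integrates to zero over the surface."""
        f = _values(f)
        ii, jj, uflux = self.transport_coefficients(u)
        fup = np.where(uflux >= 0, f[ii], f[jj])
        flux = uflux * fup
        out = np.zeros_like(f)
        np.add.at(out, ii, flux)
        np.add.at(out, jj, -flux)
        return out / self.area

    def advect(self, f: np.ndarray, coeffs, dt: float) -> np.ndarray:
        """One conservative upwind Euler step f <- f - dt div(u f), with
        precomputed transport coefficients."""
        ii, jj, uflux = coeffs
        fup = np.where(uflux >= 0, f[ii], f[jj])
        flux = uflux * fup
        out = np.zeros_like(f)
        np.add.at(out, ii, flux)
        np.add.at(out, jj, -flux)
        return f - dt * out / self.area

    def max_outflux_rate(self, coeffs) -> float:
        """Max per-node outgoing volume rate / area — the CFL rate (1/hr)."""
        ii, jj, uflux = coeffs
        rate = np.zeros_like(self.area)
        np.add.at(rate, ii, np.maximum(uflux, 0.0))
        np.add.at(rate, jj, np.maximum(-uflux, 0.0))
        return float((rate / self.area).max())

    # -- integration ------------------------------------------------------
    def integrate(self, f: np.ndarray) -> float:
        """Surface integral over the *full* spheroid (half-mesh doubled)."""
        return float(2.0 * np.sum(_values(f) * self.area))


# -- module-level functional API (spec surface) ---------------------------

def laplace_beltrami(mesh: CubedSpheroidMesh, field) -> np.ndarray:
    return SurfaceOperators(mesh).laplacian(field)


def surface_divergence_transport(mesh: CubedSpheroidMesh, vector_field, field) -> np.ndarray:
    return SurfaceOperators(mesh).divergence_transport(
        np.asarray(vector_field, dtype=float), field
    )


def integrate_surface(mesh: CubedSpheroidMesh, field) -> float:
    return float(2.0 * np.sum(_values(field) * mesh.node_area))
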