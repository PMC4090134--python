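"""Shared element-level machinery for the mixed 9/3 solvers."""

from __future__ import annotations

import numpy as np

from .elements import (
    gauss_1d,
    gauss_2d,
    gauss_to_node_extrapolation,
    pressure_basis,
    shape_edge3,
    shape_q9,
)
from .mesh import Mesh

_FIX_ALIASES = {
    "fix_x": (0,), "fix_r": (0,),
    "fix_y": (1,), "fix_z": (1,),
    "fix_all": (0, 1),
}


def dirichlet_mask(mesh: Mesh) -> np.ndarray:
    """Boolean (nn*2,) mask of constrained dofs from the mesh node sets."""
    fixed = np.zeros(mesh.n_nodes * 2, dtype=bool)
    for name, dofs in _FIX_ALIASES.items():
        nodes = mesh.node_sets.get(name)
        if nodes is None:
            continue
        for d in dofs:
            fixed[2 * nodes + d] = True
    return fixed


class ElementData:
    """Precomputed reference-configuration quantities shared by the solvers."""

    def __init__(self, mesh: Mesh, formulation: str):
        self.mesh = mesh
        self.axisym = formulation == "axisymmetric"
        pts, w = gauss_2d(3)
        N, dN = shape_q9(pts[:, 0], pts[:, 1])       # (ng,9), (ng,9,2)
        self.N, self.w = N, w
        self.ng = len(w)
        X = mesh.nodes[mesh.elements]                # (ne,9,2)
        J = np.einsum("eai,gaj->egij", X, dN)        # (ne,ng,2,2)
        detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
        if np.any(detJ <= 0):
            bad = np.unique(np.nonzero(detJ <= 0)[0])
            raise ValueError(f"non-positive Jacobian in elements {bad[:10]}")
        invJ = np.empty_like(J)
        invJ[..., 0, 0] = J[..., 1, 1] / detJ
        invJ[..., 1, 1] = J[..., 0, 0] / detJ
        invJ[..., 0, 1] = -J[..., 0, 1] / detJ
        invJ[..., 1, 0] = -J[..., 1, 0] / detJ
        # dN/dX: (ne,ng,9,2)
        self.dNdX = np.einsum("gaj,egji->egai", dN, invJ)
        self.detJ = detJ
        self.Rg = np.einsum("ga,ea->eg", N, X[..., 0]) if self.axisym else np.ones_like(detJ)
        self.weight = self.w[None, :] * detJ * self.Rg   # (ne,ng) volume weights
        self.qb = pressure_basis(pts[:, 0], pts[:, 1])   # (ng,3)
        # pressure mass matrix (without 1/kappa) and its inverse
        Mhat = np.einsum("eg,gi,gj->eij", self.weight, self.qb, self.qb)
        self.Mhat_inv = np.linalg.inv(Mhat)
        # global dof indices per element, interleaved (node*2 + dof)
        conn = mesh.elements
        edof = np.empty((mesh.n_elements, 18), dtype=np.int64)
        edof[:, 0::2] = 2 * conn
        edof[:, 1::2] = 2 * conn + 1
        self.edof = edof
        self.rows = np.repeat(edof, 18, axis=1).ravel()
        self.cols = np.tile(edof, (1, 18)).ravel()
        self.extrap = gauss_to_node_extrapolation(3)     # (9, ng)

    def region_values(self, per_region: dict) -> np.ndarray:
        """Map a {region_id: value} dict to a per-element array."""
        out = np.empty(self.mesh.n_elements)
        for rid, val in per_region.items():
            out[self.mesh.region_id == rid] = val
        return out


class EdgeLoad:
    """Pressure traction on a named edge set (quadratic 3-node edges).

    The orientation sign per edge is fixed from the reference mesh so that
    the traction pushes into the domain; with ``follower=True`` the force
    is evaluated on the current (deformed) surface.
    """

    def __init__(self, mesh: Mesh, name: str, axisym: bool):
        self.edges = mesh.edge_sets[name]
        self.signs = mesh.edge_orientation(name)
        self.axisym = axisym
        xg, wg = gauss_1d(3)
        self.Ne, self.dNe = shape_edge3(xg)          # (3g,3)
        self.wg = wg
        # global dofs per edge, interleaved
        edof = np.empty((len(self.edges), 6), dtype=np.int64)
        edof[:, 0::2] = 2 * self.edges
        edof[:, 1::2] = 2 * self.edges + 1
        self.edof = edof

    def local_force(self, x_edge: np.ndarray, p: float) -> np.ndarray:
        """Consistent nodal forces (nedge, 3, 2) of pressure p acting on the
        surface whose edge-node coordinates are ``x_edge`` (may be complex)."""
        xq = np.einsum("ga,eai->egi", self.Ne, x_edge)   # (nedge,g,2)
        tq = np.einsum("ga,eai->egi", self.dNe, x_edge)  # tangent dx/dxi
        # outward raw normal (t2, -t1) times orientation sign
        n1 = tq[..., 1] * self.signs[:, None]
        n2 = -tq[..., 0] * self.signs[:, None]
        radius = xq[..., 0] if self.axisym else np.ones_like(n1)
        w = self.wg[None, :] * radius
        # traction = -p * outward normal
        f_edge = np.empty(x_edge.shape, dtype=x_edge.dtype)
        f_edge[..., 0] = -p * np.einsum("eg,ga->ea", w * n1, self.Ne)
        f_edge[..., 1] = -p * np.einsum("eg,ga->ea", w * n2, self.Ne)
        return f_edge

    def force(self, coords, p: float, n_dofs: int):
        """Scatter :meth:`local_force` into a global vector of length n_dofs."""
        f_edge = self.local_force(coords[self.edges], p)
        f = np.zeros(n_dofs, dtype=coords.dtype)
        np.add.at(f, self.edof.reshape(-1), f_edge.reshape(-1))
        return f


def average_to_nodes(data: ElementData, gauss_vals: np.ndarray) -> np.ndarray:
    """Extrapolate per-Gauss-point values to nodes and average across
    elements.  gauss_vals: (ne, ng, ncomp) -> (nn, ncomp)."""
    mesh = data.mesh
    nodal = np.einsum("ag,egc->eac", data.extrap, gauss_vals)  # (ne,9,ncomp)
    out = np.zeros((mesh.n_nodes, gauss_vals.shape[-1]))
    counts = np.zeros(mesh.n_nodes)
    np.add.at(out, mesh.elements.ravel(), nodal.reshape(-1, gauss_vals.shape[-1]))
    np.add.at(counts, mesh.elements.ravel(), 1.0)
    return out / counts[:, None]


def vonmises(s: np.ndarray) -> np.ndarray:
    """Effective stress from components (s11, s22, s33, s12)."""
    s11, s22, s33, s12 = s[..., 0], s[..., 1], s[..., 2], s[..., 3]
    return np.sqrt(
        0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2 + (s33 - s11) ** 2)
        + 3.0 * s12**2
    )
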