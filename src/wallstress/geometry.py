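"""Deterministic geometry generators for every model family studied:
straight tubes, variable-thickness tubes (longitudinal and
circumferential), the curved axisymmetric aneurysm profile with optional
intraluminal thrombus, and seeded synthetic "patient-like" bumpy
axisymmetric profiles standing in for image-derived geometries.

All generators are pure functions of their arguments (plus seed); meshes
are structured 9-node quadratic quads with tagged boundary sets.
Coordinates: axisymmetric (r, Z) with Z in [0, height]; plane-strain
rings in (x, y).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .fem.mesh import Mesh, REGION_THROMBUS, REGION_WALL
from .tube import TubeGeometry

__all__ = [
    "AAAProfile",
    "ThicknessModulation",
    "make_tube_mesh",
    "make_ring_mesh",
    "make_aaa_profile",
    "make_aaa_mesh",
    "make_patient_like_profile",
]


@dataclass
class AAAProfile:
    """Axisymmetric aneurysm sac: outer wall radius and lumen radius as
    functions of the height Z (mm).  Thrombus is present wherever the
    lumen radius falls below the inner wall radius."""

    height: float = 130.0
    max_diameter: float = 50.0
    wall_thickness: float = 1.5
    outer_radius_of_Z: Callable[[np.ndarray], np.ndarray] | None = None
    lumen_radius_of_Z: Callable[[np.ndarray], np.ndarray] | None = None

    def inner_radius_of_Z(self, Z):
        return self.outer_radius_of_Z(Z) - self.wall_thickness


@dataclass(frozen=True)
class ThicknessModulation:
    """Cosine wall-thickness modulation.

    mode "longitudinal": thickness h(Z) = h0 + amplitude cos(2 pi Z / wavelength)
    mode "circumferential": thickness h(theta) = h0 + amplitude cos(n_waves theta)
    """

    mode: str
    amplitude: float
    wavelength: float = 40.0
    n_waves: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("longitudinal", "circumferential"):
            raise ValueError(f"unknown modulation mode {self.mode!r}")


def _structured_quad9(n_u: int, n_v: int):
    """Connectivity of an n_u x n_v structured grid of 9-node quads over a
    (2 n_u + 1) x (2 n_v + 1) node lattice; returns (conn, node index fn)."""
    nu2, nv2 = 2 * n_u + 1, 2 * n_v + 1

    def nid(i, j):  # i along u (radial), j along v (axial)
        return j * nu2 + i

    conn = []
    for j in range(n_v):
        for i in range(n_u):
            i0, j0 = 2 * i, 2 * j
            conn.append(
                [
                    nid(i0, j0), nid(i0 + 2, j0), nid(i0 + 2, j0 + 2), nid(i0, j0 + 2),
                    nid(i0 + 1, j0), nid(i0 + 2, j0 + 1), nid(i0 + 1, j0 + 2),
                    nid(i0, j0 + 1), nid(i0 + 1, j0 + 1),
                ]
            )
    return np.array(conn, dtype=np.int64), nid


def make_tube_mesh(
    geom: TubeGeometry,
    n_thickness: int = 6,
    n_axial: int = 20,
    length: float | None = None,
    thickness_mod: ThicknessModulation | None = None,
) -> Mesh:
    """Axisymmetric straight-tube mesh with lumen/outer/end boundary sets.

    With a longitudinal :class:`ThicknessModulation` the outer radius varies
    along Z while the lumen stays cylindrical.
    """
    if n_thickness < 1 or n_axial < 1:
        raise ValueError("element counts must be >= 1")
    L = length if length is not None else 4.0 * (geom.B - geom.A)
    nu2, nv2 = 2 * n_thickness + 1, 2 * n_axial + 1
    zs = np.linspace(0.0, L, nv2)
    if thickness_mod is None:
        outer = np.full(nv2, geom.B)
    elif thickness_mod.mode == "longitudinal":
        h0 = geom.B - geom.A
        h = h0 + thickness_mod.amplitude * np.cos(
            2.0 * np.pi * zs / thickness_mod.wavelength
        )
        if np.any(h <= 0):
            raise ValueError("thickness modulation produces non-positive thickness")
        outer = geom.A + h
    else:
        raise ValueError("circumferential modulation requires make_ring_mesh")
    s = np.linspace(0.0, 1.0, nu2)
    nodes = np.empty((nu2 * nv2, 2))
    for j, z in enumerate(zs):
        r = geom.A + s * (outer[j] - geom.A)
        nodes[j * nu2:(j + 1) * nu2, 0] = r
        nodes[j * nu2:(j + 1) * nu2, 1] = z
    conn, nid = _structured_quad9(n_thickness, n_axial)

    lumen, outer_edges = [], []
    for j in range(n_axial):
        j0 = 2 * j
        lumen.append([nid(0, j0), nid(0, j0 + 2), nid(0, j0 + 1)])
        outer_edges.append([nid(nu2 - 1, j0), nid(nu2 - 1, j0 + 2), nid(nu2 - 1, j0 + 1)])
    ends = np.concatenate([np.arange(nu2), (nv2 - 1) * nu2 + np.arange(nu2)])
    mesh = Mesh(
        nodes,
        conn,
        edge_sets={"lumen": np.array(lumen), "outer": np.array(outer_edges)},
        node_sets={"fix_z": ends},
    )
    mesh.check()
    return mesh


def make_ring_mesh(
    geom: TubeGeometry,
    n_thickness: int = 3,
    n_circ: int = 60,
    thickness_mod: ThicknessModulation | None = None,
) -> Mesh:
    """Plane-strain full-ring mesh (x, y), optionally with circumferentially
    varying thickness; rigid motions are removed by constraining u_y on the
    theta = 0 and theta = pi rays (the modulation is symmetric about them).
    """
    if n_circ % 2:
        raise ValueError("n_circ must be even so the symmetry rays hit nodes")
    nu2 = 2 * n_thickness + 1
    nv2 = 2 * n_circ  # periodic: last column wraps to the first
    thetas = np.arange(nv2) * (2.0 * np.pi / nv2)
    if thickness_mod is None:
        h = np.full(nv2, geom.B - geom.A)
    elif thickness_mod.mode == "circumferential":
        h = (geom.B - geom.A) + thickness_mod.amplitude * np.cos(
            thickness_mod.n_waves * thetas
        )
        if np.any(h <= 0):
            raise ValueError("thickness modulation produces non-positive thickness")
    else:
        raise ValueError("longitudinal modulation requires make_tube_mesh")
    s = np.linspace(0.0, 1.0, nu2)
    nodes = np.empty((nu2 * nv2, 2))
    for j, th in enumerate(thetas):
        r = geom.A + s * h[j]
        nodes[j * nu2:(j + 1) * nu2, 0] = r * np.cos(th)
        nodes[j * nu2:(j + 1) * nu2, 1] = r * np.sin(th)

    def nid(i, j):
        return (j % nv2) * nu2 + i

    conn = []
    for j in range(n_circ):
        for i in range(n_thickness):
            i0, j0 = 2 * i, 2 * j
            conn.append(
                [
                    nid(i0, j0), nid(i0 + 2, j0), nid(i0 + 2, j0 + 2), nid(i0, j0 + 2),
                    nid(i0 + 1, j0), nid(i0 + 2, j0 + 1), nid(i0 + 1, j0 + 2),
                    nid(i0, j0 + 1), nid(i0 + 1, j0 + 1),
                ]
            )
    lumen = [
        [nid(0, 2 * j), nid(0, 2 * j + 2), nid(0, 2 * j + 1)] for j in range(n_circ)
    ]
    sym = np.concatenate([np.arange(nu2), nid(np.arange(nu2), n_circ)])
    mesh = Mesh(
        nodes,
        np.array(conn, dtype=np.int64),
        edge_sets={"lumen": np.array(lumen)},
        node_sets={"fix_y": sym},
    )
    mesh.check()
    return mesh


def make_aaa_profile(
    height: float = 130.0,
    max_diameter: float = 50.0,
    wall_thickness: float = 1.5,
    neck_outer_radius: float = 12.5,
    bulge_length: float = 100.0,
    lumen_radius: float | None = None,
) -> AAAProfile:
    """Idealized curved axisymmetric aneurysm sac.

    The outer wall is a C1 cosine-squared bulge on a cylindrical neck,
    peaking at max_diameter/2 at mid-height, with cylindrical ends; the
    lumen is a coaxial cylinder (default: the neck inner radius), so the
    thrombus fills the dilated portion of the sac.
    """
    z_mid = 0.5 * height
    r_max = 0.5 * max_diameter
    if r_max <= neck_outer_radius:
        raise ValueError("max diameter must exceed the neck diameter")
    amp = r_max - neck_outer_radius
    L_target = (
        lumen_radius if lumen_radius is not None
        else neck_outer_radius - wall_thickness
    )

    def outer(Z):
        Z = np.asarray(Z, dtype=float)
        u = (Z - z_mid) / bulge_length  # bump support |u| < 1/2
        bump = np.where(np.abs(u) < 0.5, np.cos(np.pi * u) ** 2, 0.0)
        return neck_outer_radius + amp * bump

    def lumen(Z):
        Z = np.asarray(Z, dtype=float)
        inner = outer(Z) - wall_thickness
        return np.minimum(np.full_like(Z, L_target), inner)

    return AAAProfile(height, max_diameter, wall_thickness, outer, lumen)


def make_aaa_mesh(
    profile: AAAProfile,
    with_thrombus: bool = False,
    n_thickness: int = 3,
    n_axial: int = 48,
    n_thrombus: int = 10,
    min_thrombus_thickness: float = 0.8,
) -> Mesh:
    """Axisymmetric mesh of the curved aneurysm wall and, when flagged, the
    conforming thrombus region between lumen and inner wall.

    The lumen edge set carries the pressure: the thrombus inner surface and
    end faces where thrombus exists, the wall inner surface elsewhere.
    Wall ends and thrombus end faces are constrained longitudinally.
    """
    nu2, nv2 = 2 * n_thickness + 1, 2 * n_axial + 1
    zs = np.linspace(0.0, profile.height, nv2)
    r_out = profile.outer_radius_of_Z(zs)
    r_in = r_out - profile.wall_thickness
    if np.any(r_in <= 0):
        raise ValueError("degenerate profile: non-positive inner radius")
    s = np.linspace(0.0, 1.0, nu2)
    wall_nodes = np.empty((nu2 * nv2, 2))
    for j in range(nv2):
        wall_nodes[j * nu2:(j + 1) * nu2, 0] = r_in[j] + s * (r_out[j] - r_in[j])
        wall_nodes[j * nu2:(j + 1) * nu2, 1] = zs[j]
    conn, nid = _structured_quad9(n_thickness, n_axial)
    region = np.full(len(conn), REGION_WALL, dtype=np.int64)
    edge_sets: dict = {}
    node_sets: dict = {}
    outer_edges = [
        [nid(nu2 - 1, 2 * j), nid(nu2 - 1, 2 * j + 2), nid(nu2 - 1, 2 * j + 1)]
        for j in range(n_axial)
    ]
    wall_ends = np.concatenate([np.arange(nu2), (nv2 - 1) * nu2 + np.arange(nu2)])

    if not with_thrombus:
        lumen = [
            [nid(0, 2 * j), nid(0, 2 * j + 2), nid(0, 2 * j + 1)]
            for j in range(n_axial)
        ]
        mesh = Mesh(
            wall_nodes, conn, region,
            edge_sets={"lumen": np.array(lumen), "outer": np.array(outer_edges)},
            node_sets={"fix_z": wall_ends},
        )
        mesh.check()
        return mesh

    L = profile.lumen_radius_of_Z(zs)
    if np.any(L > r_in + 1e-9):
        raise ValueError("lumen radius exceeds inner wall radius")
    gap = r_in - L
    if not np.any(gap >= min_thrombus_thickness):
        raise ValueError("thrombus requested but lumen meets the wall everywhere")
    # thrombus axial extent snapped to wall element columns
    cols = np.arange(n_axial)
    col_ok = gap[2 * cols] >= min_thrombus_thickness
    col_ok &= gap[2 * cols + 2] >= min_thrombus_thickness
    j1 = int(np.argmax(col_ok))
    j2 = int(n_axial - np.argmax(col_ok[::-1]))  # exclusive
    nodes = [wall_nodes]
    offset = len(wall_nodes)
    mu2 = 2 * n_thrombus + 1
    thr_cols = {}  # z-node index -> array of node ids from lumen to wall inner
    for jz in range(2 * j1, 2 * j2 + 1):
        rr = L[jz] + np.linspace(0.0, 1.0, mu2)[:-1] * (r_in[jz] - L[jz])
        ids = np.concatenate(
            [offset + np.arange(mu2 - 1), [nid(0, jz)]]
        )
        col = np.empty((mu2 - 1, 2))
        col[:, 0] = rr
        col[:, 1] = zs[jz]
        nodes.append(col)
        offset += mu2 - 1
        thr_cols[jz] = ids
    thr_conn = []
    for j in range(j1, j2):
        c0, c1, c2 = thr_cols[2 * j], thr_cols[2 * j + 1], thr_cols[2 * j + 2]
        for i in range(n_thrombus):
            i0 = 2 * i
            thr_conn.append(
                [
                    c0[i0], c0[i0 + 2], c2[i0 + 2], c2[i0],
                    c0[i0 + 1], c1[i0 + 2], c2[i0 + 1], c1[i0], c1[i0 + 1],
                ]
            )
    all_nodes = np.vstack(nodes)
    all_conn = np.vstack([conn, np.array(thr_conn, dtype=np.int64)])
    region = np.concatenate(
        [region, np.full(len(thr_conn), REGION_THROMBUS, dtype=np.int64)]
    )
    # lumen edges: wall inner outside [j1, j2), thrombus inner + end faces inside
    lumen = []
    for j in range(n_axial):
        if j < j1 or j >= j2:
            lumen.append([nid(0, 2 * j), nid(0, 2 * j + 2), nid(0, 2 * j + 1)])
    for j in range(j1, j2):
        c0, c1, c2 = thr_cols[2 * j], thr_cols[2 * j + 1], thr_cols[2 * j + 2]
        lumen.append([c0[0], c2[0], c1[0]])
    for jz in (2 * j1, 2 * j2):  # pressure-wetted thrombus end faces
        col = thr_cols[jz]
        for i in range(n_thrombus):
            i0 = 2 * i
            lumen.append([col[i0], col[i0 + 2], col[i0 + 1]])
    thr_end_nodes = np.concatenate([thr_cols[2 * j1][:-1], thr_cols[2 * j2][:-1]])
    mesh = Mesh(
        all_nodes, all_conn, region,
        edge_sets={"lumen": np.array(lumen), "outer": np.array(outer_edges)},
        node_sets={"fix_z": np.concatenate([wall_ends, thr_end_nodes])},
    )
    mesh.check()
    return mesh


def make_patient_like_profile(
    seed: int,
    n_bumps: int | None = None,
    base_outer_radius: float = 20.0,
    wall_thickness: float = 1.5,
    height: float = 130.0,
    amplitude_range: tuple[float, float] = (2.0, 6.0),
    width_range: tuple[float, float] = (10.0, 22.0),
) -> AAAProfile:
    """Reproducible synthetic "patient-like" axisymmetric profile: a sum of
    smooth Gaussian dilation bumps, asymmetric in Z, on a cylindrical tube,
    with a uniform wall.  Bit-identical for equal arguments."""
    rng = np.random.default_rng(seed)
    k = int(n_bumps) if n_bumps is not None else int(rng.integers(2, 5))
    centers = rng.uniform(0.25 * height, 0.75 * height, size=k)
    widths = rng.uniform(*width_range, size=k)
    amps = rng.uniform(*amplitude_range, size=k)

    def outer(Z):
        Z = np.asarray(Z, dtype=float)
        r = np.full_like(Z, base_outer_radius)
        for c, w, a in zip(centers, widths, amps):
            r = r + a * np.exp(-0.5 * ((Z - c) / w) ** 2)
        return r

    prof = AAAProfile(height, 2.0 * float(outer(np.linspace(0, height, 521)).max()),
                      wall_thickness, outer, None)
    if np.any(outer(np.linspace(0.0, height, 1042)) <= wall_thickness):
        raise ValueError("bump parameters produce a self-intersecting profile")
    return prof
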