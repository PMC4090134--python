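"""Mesh container plus plain-text mesh I/O (legacy VTK and Abaqus-style .inp).

A mesh stores 2D nodal coordinates -- (r, z) for axisymmetric domains,
(x, y) for plane strain -- 9-node quadratic quad connectivity, a region id
per element (wall = 0, thrombus = 1), named edge sets (3-node quadratic
edges, e.g. the lumen surface carrying pressure) and named node sets for
kinematic constraints ("fix_x" first dof, "fix_y" second dof, "fix_all").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import shape_q9, gauss_2d

VTK_BIQUADRATIC_QUAD = 28

REGION_WALL = 0
REGION_THROMBUS = 1


@dataclass
class Mesh:
    nodes: np.ndarray                     # (nn, 2)
    elements: np.ndarray                  # (ne, 9) int
    region_id: np.ndarray | None = None   # (ne,) int
    edge_sets: dict = field(default_factory=dict)   # name -> (nedge, 3) int
    node_sets: dict = field(default_factory=dict)   # name -> (n,) int

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.region_id is None:
            self.region_id = np.zeros(len(self.elements), dtype=np.int64)
        else:
            self.region_id = np.asarray(self.region_id, dtype=np.int64)
        self.edge_sets = {
            k: np.asarray(v, dtype=np.int64).reshape(-1, 3)
            for k, v in self.edge_sets.items()
        }
        self.node_sets = {
            k: np.asarray(v, dtype=np.int64) for k, v in self.node_sets.items()
        }

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def jacobians(self) -> np.ndarray:
        """det J at every quadrature point, shape (ne, 9)."""
        pts, _ = gauss_2d(3)
        _, dN = shape_q9(pts[:, 0], pts[:, 1])       # (ng, 9, 2)
        X = self.nodes[self.elements]                # (ne, 9, 2)
        J = np.einsum("eai,gaj->egij", X, dN)        # (ne, ng, 2, 2)
        return J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]

    def check(self) -> None:
        """Raise if any element is inverted (non-positive Jacobian)."""
        det = self.jacobians()
        if np.any(det <= 0):
            bad = np.unique(np.nonzero(det <= 0)[0])
            raise ValueError(f"non-positive Jacobian in elements {bad[:10]}")

    def edge_orientation(self, name: str) -> np.ndarray:
        """Sign s per edge so that s*(t2, -t1) is the domain-outward normal,
        t being the edge tangent d x / d xi."""
        edges = self.edge_sets[name]
        signs = np.empty(len(edges))
        # map: element membership via corner/mid node lookup
        node2elems: dict[int, list[int]] = {}
        for e, conn in enumerate(self.elements):
            for nid in conn:
                node2elems.setdefault(int(nid), []).append(e)
        for i, (n1, n2, nm) in enumerate(edges):
            cands = set(node2elems.get(int(nm), []))
            cands &= set(node2elems.get(int(n1), []))
            cands &= set(node2elems.get(int(n2), []))
            if not cands:
                raise ValueError(f"edge {i} of set {name!r} has no parent element")
            parent = min(cands)
            centroid = self.nodes[self.elements[parent]].mean(axis=0)
            x1, x2, xm = self.nodes[[n1, n2, nm]]
            t = 0.5 * (x2 - x1)          # tangent at the midpoint node
            n = np.array([t[1], -t[0]])
            signs[i] = 1.0 if np.dot(n, centroid - xm) < 0 else -1.0
        return signs


def write_vtk(mesh: Mesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write a legacy ASCII VTK unstructured grid (biquadratic quads)."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nwallstress mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.nodes:
            fh.write(f"{x:.12g} {y:.12g} 0\n")
        ne = mesh.n_elements
        fh.write(f"CELLS {ne} {ne * 10}\n")
        for conn in mesh.elements:
            fh.write("9 " + " ".join(str(int(c)) for c in conn) + "\n")
        fh.write(f"CELL_TYPES {ne}\n")
        fh.write("\n".join([str(VTK_BIQUADRATIC_QUAD)] * ne) + "\n")
        fh.write(f"CELL_DATA {ne}\nSCALARS region_id int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(r)) for r in mesh.region_id) + "\n")
        if cell_data:
            for name, vals in cell_data.items():
                vals = np.asarray(vals)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.12g}" for v in vals) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, vals in point_data.items():
                vals = np.asarray(vals)
                if vals.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.12g}" for v in vals) + "\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for row in vals:
                        row3 = list(row) + [0.0] * (3 - len(row))
                        fh.write(" ".join(f"{v:.12g}" for v in row3) + "\n")


def read_vtk(path) -> tuple[Mesh, dict, dict]:
    """Read a legacy ASCII VTK unstructured grid written by write_vtk.

    Returns (mesh, point_data, cell_data); edge and node sets are not part
    of the VTK payload and come back empty.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    i = 0

    def expect(word):
        nonlocal i
        while tokens[i].upper() != word:
            i += 1
        i += 1

    expect("POINTS")
    nn = int(tokens[i]); i += 2  # skip dtype
    pts = np.array(tokens[i:i + 3 * nn], dtype=float).reshape(nn, 3)[:, :2]
    i += 3 * nn
    expect("CELLS")
    ne = int(tokens[i]); total = int(tokens[i + 1]); i += 2
    raw = np.array(tokens[i:i + total], dtype=np.int64)
    i += total
    conn = raw.reshape(ne, 10)[:, 1:]
    expect("CELL_TYPES")
    i += ne
    region = np.zeros(ne, dtype=np.int64)
    point_data: dict = {}
    cell_data: dict = {}
    n_tok = len(tokens)
    mode, count = None, 0
    while i < n_tok:
        tok = tokens[i].upper()
        if tok == "CELL_DATA":
            mode, count = "cell", int(tokens[i + 1]); i += 2
        elif tok == "POINT_DATA":
            mode, count = "point", int(tokens[i + 1]); i += 2
        elif tok == "SCALARS":
            name = tokens[i + 1]; i += 4  # SCALARS name dtype ncomp
            i += 2  # LOOKUP_TABLE default
            vals = np.array(tokens[i:i + count], dtype=float)
            i += count
            if mode == "cell":
                if name == "region_id":
                    region = vals.astype(np.int64)
                else:
                    cell_data[name] = vals
            else:
                point_data[name] = vals
        elif tok == "VECTORS":
            name = tokens[i + 1]; i += 3
            vals = np.array(tokens[i:i + 3 * count], dtype=float).reshape(count, 3)
            i += 3 * count
            point_data[name] = vals[:, :2]
        else:
            i += 1
    mesh = Mesh(pts, conn, region)
    return mesh, point_data, cell_data


def read_inp(path) -> Mesh:
    """Minimal Abaqus-style .inp reader: *NODE and *ELEMENT blocks with
    9-node connectivity, plus optional *NSET blocks (stored as node sets)."""
    nodes: dict[int, tuple[float, float]] = {}
    elems: list[list[int]] = []
    nsets: dict[str, list[int]] = {}
    section = None
    current_set = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                key = line.split(",")[0].strip().upper()
                if key == "*NODE":
                    section = "node"
                elif key == "*ELEMENT":
                    section = "element"
                elif key == "*NSET":
                    section = "nset"
                    for part in line.split(",")[1:]:
                        k, _, v = part.partition("=")
                        if k.strip().upper() == "NSET":
                            current_set = v.strip()
                    nsets.setdefault(current_set, [])
                else:
                    section = None
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            if section == "node":
                nid = int(parts[0])
                nodes[nid] = (float(parts[1]), float(parts[2]))
            elif section == "element":
                elems.append([int(p) for p in parts[1:10]])
            elif section == "nset" and current_set is not None:
                nsets[current_set].extend(int(p) for p in parts)
    ids = sorted(nodes)
    remap = {nid: k for k, nid in enumerate(ids)}
    coords = np.array([nodes[nid] for nid in ids])
    conn = np.array([[remap[n] for n in e] for e in elems], dtype=np.int64)
    node_sets = {
        name: np.array([remap[n] for n in lst], dtype=np.int64)
        for name, lst in nsets.items()
    }
    return Mesh(coords, conn, node_sets=node_sets)
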