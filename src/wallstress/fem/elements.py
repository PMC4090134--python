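"""9-node Lagrange quadrilateral and 3-node quadratic edge elements.

Node ordering follows the VTK biquadratic quad (cell type 28): corners
(-1,-1),(1,-1),(1,1),(-1,1), then mid-edges bottom/right/top/left, then
the centre.  Quadrature is 3x3 Gauss for the quad and 3-point Gauss for
edges.
"""

from __future__ import annotations

import numpy as np

# natural coordinates of the 9 nodes (VTK biquadratic quad ordering)
NODE_XI = np.array(
    [
        [-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0],
        [0.0, -1.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0],
        [0.0, 0.0],
    ]
)

# quadratic edge node natural coordinates: end, end, middle
EDGE_XI = np.array([-1.0, 1.0, 0.0])


def _lag1d(x):
    """1D quadratic Lagrange basis at nodes -1, 0, +1, and derivative."""
    x = np.asarray(x)
    vals = np.stack([0.5 * x * (x - 1.0), 1.0 - x * x, 0.5 * x * (x + 1.0)], axis=-1)
    ders = np.stack([x - 0.5, -2.0 * x, x + 0.5], axis=-1)
    return vals, ders


_IDX_1D = {-1.0: 0, 0.0: 1, 1.0: 2}


def shape_q9(xi, eta):
    """Shape functions N (..., 9) and derivatives dN/d(xi,eta) (..., 9, 2)."""
    lx, dlx = _lag1d(xi)
    ly, dly = _lag1d(eta)
    N = np.empty(np.shape(xi) + (9,))
    dN = np.empty(np.shape(xi) + (9, 2))
    for a, (xa, ya) in enumerate(NODE_XI):
        i, j = _IDX_1D[xa], _IDX_1D[ya]
        N[..., a] = lx[..., i] * ly[..., j]
        dN[..., a, 0] = dlx[..., i] * ly[..., j]
        dN[..., a, 1] = lx[..., i] * dly[..., j]
    return N, dN


def shape_edge3(xi):
    """Quadratic edge shape functions (..., 3) and d/dxi (..., 3),
    ordered end(-1), end(+1), middle(0)."""
    v, d = _lag1d(xi)
    order = [0, 2, 1]
    return v[..., order], d[..., order]


def gauss_2d(n: int = 3):
    """Tensor Gauss rule: points (n*n, 2), weights (n*n,)."""
    x, w = np.polynomial.legendre.leggauss(n)
    XI, ETA = np.meshgrid(x, x, indexing="ij")
    W = np.outer(w, w)
    return np.column_stack([XI.ravel(), ETA.ravel()]), W.ravel()


def gauss_1d(n: int = 3):
    return np.polynomial.legendre.leggauss(n)


# pressure basis for the 9/3 mixed pair: 1, xi, eta (discontinuous per element)
def pressure_basis(xi, eta):
    xi = np.asarray(xi)
    return np.stack([np.ones_like(xi), xi, np.asarray(eta) * np.ones_like(xi)], axis=-1)


def gauss_to_node_extrapolation(n: int = 3) -> np.ndarray:
    """Matrix E (9, n*n) mapping Gauss-point values of a biquadratic field
    to its nodal values (exact for biquadratic data)."""
    pts, _ = gauss_2d(n)

    def vander(P):
        x, y = P[:, 0], P[:, 1]
        cols = [x**i * y**j for i in range(3) for j in range(3)]
        return np.column_stack(cols)

    Vg = vander(pts)
    Vn = vander(NODE_XI)
    return Vn @ np.linalg.pinv(Vg)
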