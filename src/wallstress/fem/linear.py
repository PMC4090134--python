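"""Mixed u/p linear-elastic solver (nearly incompressible, small strain).

One sparse solve: pressure is applied as a traction on the undeformed
lumen surface and the geometry is never updated, consistent with the
infinitesimal-displacement assumption of the linear wall-stress model.
The per-element discontinuous pressure is statically condensed, leaving a
symmetric positive-definite displacement system.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from ..materials import LinearMaterial
from ._core import ElementData, EdgeLoad, average_to_nodes, dirichlet_mask, vonmises
from .mesh import Mesh
from .settings import SolveSettings, SolutionField


def _strain_B(data: ElementData):
    """Strain-displacement operator B: (ne, ng, 4, 18) for components
    (e11, e22, e33, g12); e33 = u1/r in axisymmetry, 0 in plane strain."""
    ne, ng = data.detJ.shape
    B = np.zeros((ne, ng, 4, 18))
    dNdX = data.dNdX
    B[:, :, 0, 0::2] = dNdX[..., 0]
    B[:, :, 1, 1::2] = dNdX[..., 1]
    if data.axisym:
        B[:, :, 2, 0::2] = data.N[None, :, :] / data.Rg[:, :, None]
    B[:, :, 3, 0::2] = dNdX[..., 1]
    B[:, :, 3, 1::2] = dNdX[..., 0]
    return B


def solve_linear(
    mesh: Mesh,
    mats: dict[int, LinearMaterial] | LinearMaterial,
    p: float,
    settings: SolveSettings | None = None,
    lumen_set: str = "lumen",
) -> SolutionField:
    """Single linear mixed solve under lumen pressure p."""
    settings = settings or SolveSettings()
    if isinstance(mats, LinearMaterial):
        mats = {0: mats}
    data = ElementData(mesh, settings.formulation)
    mu = data.region_values({rid: m.mu for rid, m in mats.items()})
    kappa = data.region_values({rid: m.bulk for rid, m in mats.items()})

    B = _strain_B(data)
    w = data.weight  # (ne, ng)
    # deviatoric operator: 2 mu (I - J/3) on normals, mu on engineering shear
    P = np.eye(4)
    P[:3, :3] -= 1.0 / 3.0
    P[3, 3] = 0.5
    Ddev = 2.0 * P
    K_dev = np.einsum("eg,e,egca,cd,egdb->eab", w, mu, B, Ddev, B, optimize=True)
    bvol = B[:, :, 0, :] + B[:, :, 1, :] + B[:, :, 2, :]      # (ne,ng,18)
    G = np.einsum("eg,ega,gi->eai", w, bvol, data.qb)          # (ne,18,3)
    K_vol = np.einsum("e,eai,eij,ebj->eab", kappa, G, data.Mhat_inv, G)
    K_e = K_dev + K_vol

    n_dofs = mesh.n_nodes * 2
    K = sparse.coo_matrix(
        (K_e.ravel(), (data.rows, data.cols)), shape=(n_dofs, n_dofs)
    ).tocsr()

    if lumen_set not in mesh.edge_sets:
        raise ValueError(f"mesh has no edge set {lumen_set!r} to carry the pressure")
    load = EdgeLoad(mesh, lumen_set, data.axisym)
    f = load.force(mesh.nodes, p, n_dofs)

    fixed = dirichlet_mask(mesh)
    free = ~fixed
    if not fixed.any():
        raise ValueError("no kinematic constraints: system has rigid-body modes")
    u = np.zeros(n_dofs)
    Kff = K[free][:, free]
    u[free] = spsolve(Kff, f[free])
    if not np.all(np.isfinite(u)):
        raise RuntimeError(
            "singular stiffness system: constraints insufficient to remove "
            "rigid-body modes"
        )

    u2 = u.reshape(-1, 2)
    u_e = u2[mesh.elements].reshape(mesh.n_elements, 18)
    # element pressure variable (positive in compression)
    p_coef = -np.einsum("e,eij,eaj,ea->ei", kappa, data.Mhat_inv, G, u_e)
    eps = np.einsum("egca,ea->egc", B, u_e)                    # (ne,ng,4)
    tr = eps[..., 0] + eps[..., 1] + eps[..., 2]
    pbar = np.einsum("gi,ei->eg", data.qb, p_coef)
    sig = np.empty_like(eps)
    for c in range(3):
        sig[..., c] = 2.0 * mu[:, None] * (eps[..., c] - tr / 3.0) - pbar
    sig[..., 3] = mu[:, None] * eps[..., 3]
    stress_nodes = average_to_nodes(data, sig)
    return SolutionField(
        mesh=mesh,
        displacement=u2,
        pressure_coeffs=p_coef,
        stress_nodes=stress_nodes,
        effective_stress_nodes=vonmises(stress_nodes),
        stress_gauss=sig,
        history={"solver": "linear"},
    )
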