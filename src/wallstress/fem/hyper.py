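"""Incompressible hyperelastic solver: total Lagrangian, mixed 9/3,
incremental loading with full Newton iterations.

The strain energy uses the isochoric split W(I1_bar, I2_bar) plus a
volumetric penalty whose element-wise discontinuous pressure is condensed
exactly, so near-incompressibility never locks the quadratic
displacement field.  Element tangents are obtained by complex-step
differentiation of the analytic element residual (exact to machine
precision), vectorized over all elements; the lumen pressure is a
follower load on the deforming surface by default.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import MatrixRankWarning, spsolve

from ..materials import HyperelasticMaterial, ThrombusMaterial
from ._core import ElementData, EdgeLoad, average_to_nodes, dirichlet_mask, vonmises
from .mesh import Mesh
from .settings import SolveSettings, SolutionField

_CS_H = 1e-30  # complex-step size; derivative exact at this magnitude


class NewtonError(RuntimeError):
    """Raised when Newton iterations fail to converge; carries the
    residual-energy history."""

    def __init__(self, message: str, history: list):
        super().__init__(message)
        self.history = history


class _HyperProblem:
    def __init__(self, mesh: Mesh, mats: dict, settings: SolveSettings,
                 lumen_set: str):
        self.mesh = mesh
        self.settings = settings
        self.data = ElementData(mesh, settings.formulation)
        ne = mesh.n_elements
        # polynomial coefficients per element: first-invariant wall terms
        # (alpha..eta) and second-invariant thrombus terms (D1, D2)
        self.cw = np.zeros((ne, 5))
        self.ct = np.zeros((ne, 2))
        for rid, mat in mats.items():
            sel = mesh.region_id == rid
            if isinstance(mat, HyperelasticMaterial):
                self.cw[sel] = mat.coefficients
            elif isinstance(mat, ThrombusMaterial):
                self.ct[sel] = (mat.D1, mat.D2)
            else:
                raise TypeError(f"unsupported material {type(mat)!r} for region {rid}")
        if lumen_set not in mesh.edge_sets:
            raise ValueError(f"mesh has no edge set {lumen_set!r} to carry the pressure")
        self.load = EdgeLoad(mesh, lumen_set, self.data.axisym)
        self.fixed = dirichlet_mask(mesh)
        self.free = ~self.fixed
        self.n_dofs = mesh.n_nodes * 2
        self.kappa = settings.kappa

    # -- element-level residual ------------------------------------------
    def _state(self, ue):
        """Kinematics, stresses and element pressure from element
        displacements ue (ne, 9, 2); complex-safe."""
        d = self.data
        gradu = np.einsum("eai,egaj->egij", ue, d.dNdX)
        F2 = gradu.copy()
        F2[..., 0, 0] += 1.0
        F2[..., 1, 1] += 1.0
        if d.axisym:
            ur = np.einsum("ga,ea->eg", d.N, ue[..., 0])
            F33 = 1.0 + ur / d.Rg
        else:
            F33 = np.ones(F2.shape[:2], dtype=ue.dtype)
        detF2 = F2[..., 0, 0] * F2[..., 1, 1] - F2[..., 0, 1] * F2[..., 1, 0]
        J = detF2 * F33
        invF2T = np.empty_like(F2)
        invF2T[..., 0, 0] = F2[..., 1, 1] / detF2
        invF2T[..., 1, 1] = F2[..., 0, 0] / detF2
        invF2T[..., 0, 1] = -F2[..., 1, 0] / detF2
        invF2T[..., 1, 0] = -F2[..., 0, 1] / detF2
        B2 = np.einsum("egik,egjk->egij", F2, F2)
        trB2 = B2[..., 0, 0] + B2[..., 1, 1]
        I1 = trB2 + F33**2
        trBsq = np.einsum("egij,egij->eg", B2, B2) + F33**4
        I2 = 0.5 * (I1 * I1 - trBsq)
        Jm23 = J ** (-2.0 / 3.0)
        Jm43 = Jm23 * Jm23
        I1b = Jm23 * I1
        I2b = Jm43 * I2
        x = I1b - 3.0
        a, b, c, z, e = (self.cw[:, i][:, None] for i in range(5))
        W1 = a + x * (2 * b + x * (3 * c + x * (4 * z + x * 5 * e)))
        y = I2b - 3.0
        W2 = self.ct[:, 0][:, None] + 2.0 * self.ct[:, 1][:, None] * y

        # element pressure from exact condensation of the volumetric term
        g = np.einsum("eg,gi,eg->ei", d.weight, d.qb, J - 1.0)
        p_coef = self.kappa * np.einsum("eij,ej->ei", d.Mhat_inv, g)
        ptil = np.einsum("gi,ei->eg", d.qb, p_coef)

        # first Piola-Kirchhoff stress, in-plane block and hoop component
        BF2 = np.einsum("egik,egkj->egij", B2, F2)
        P2 = (
            W1[..., None, None] * Jm23[..., None, None]
            * (2.0 * F2 - (2.0 / 3.0) * I1[..., None, None] * invF2T)
            + W2[..., None, None]
            * (
                Jm43[..., None, None] * 2.0
                * (I1[..., None, None] * F2 - BF2)
                - (4.0 / 3.0) * I2b[..., None, None] * invF2T
            )
            + (ptil * J)[..., None, None] * invF2T
        )
        P33 = (
            W1 * Jm23 * (2.0 * F33 - (2.0 / 3.0) * I1 / F33)
            + W2 * (Jm43 * 2.0 * (I1 * F33 - F33**3) - (4.0 / 3.0) * I2b / F33)
            + ptil * J / F33
        )
        return {
            "F2": F2, "F33": F33, "J": J, "P2": P2, "P33": P33,
            "p_coef": p_coef,
        }

    def element_residual(self, ue):
        """Internal-force element residual (ne, 18) from ue (ne, 9, 2).

        Trial states during Newton may transiently invert elements
        (negative J -> nan); the Newton driver detects and recovers, so
        floating-point warnings are silenced here.
        """
        d = self.data
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            st = self._state(ue)
        w = d.weight
        r = np.einsum("eg,egij,egaj->eai", w, st["P2"], d.dNdX)
        if d.axisym:
            r = r.copy()
            r[..., 0] += np.einsum("eg,eg,ga->ea", w, st["P33"] / d.Rg, d.N)
        return r.reshape(len(ue), 18)

    # -- global residual and tangent -------------------------------------
    def residual(self, u: np.ndarray, p: float) -> np.ndarray:
        ue = u.reshape(-1, 2)[self.mesh.elements]
        r_e = self.element_residual(ue)
        r = np.zeros(self.n_dofs, dtype=u.dtype)
        np.add.at(r, self.data.edof.reshape(-1), r_e.reshape(-1))
        coords = (
            self.mesh.nodes + u.reshape(-1, 2)
            if self.settings.pressure_config == "deformed"
            else self.mesh.nodes.astype(u.dtype)
        )
        r -= self.load.force(coords, p, self.n_dofs)
        return r

    def tangent(self, u: np.ndarray, p: float) -> sparse.csr_matrix:
        d = self.data
        ue0 = u.reshape(-1, 2)[self.mesh.elements].astype(complex)
        ne = len(ue0)
        K_e = np.empty((ne, 18, 18))
        for k in range(18):
            ue = ue0.copy()
            ue.reshape(ne, 18)[:, k] += 1j * _CS_H
            K_e[:, :, k] = self.element_residual(ue).imag / _CS_H
        K = sparse.coo_matrix(
            (K_e.ravel(), (d.rows, d.cols)), shape=(self.n_dofs, self.n_dofs)
        )
        if self.settings.pressure_config == "deformed":
            # follower-load tangent by complex step on edge coordinates
            xe0 = (self.mesh.nodes + u.reshape(-1, 2))[self.load.edges].astype(complex)
            nedge = len(xe0)
            Kl = np.empty((nedge, 6, 6))
            for k in range(6):
                xe = xe0.copy()
                xe.reshape(nedge, 6)[:, k] += 1j * _CS_H
                Kl[:, :, k] = -self.load.local_force(xe, p).reshape(nedge, 6).imag / _CS_H
            rows = np.repeat(self.load.edof, 6, axis=1).ravel()
            cols = np.tile(self.load.edof, (1, 6)).ravel()
            K = K + sparse.coo_matrix(
                (Kl.ravel(), (rows, cols)), shape=(self.n_dofs, self.n_dofs)
            )
        return K.tocsr()

    # -- Newton driver ----------------------------------------------------
    def newton(self, u: np.ndarray, p: float) -> tuple[np.ndarray, list]:
        s = self.settings
        free = self.free
        history = []
        E1 = None
        for it in range(s.max_iterations_per_step):
            r = self.residual(u, p)
            K = self.tangent(u, p)
            du = np.zeros_like(u)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", MatrixRankWarning)
                du[free] = spsolve(K[free][:, free], -r[free])
            if not np.all(np.isfinite(du)):
                raise NewtonError("singular tangent system", history)
            energy = abs(float(du[free] @ r[free]))
            history.append(energy)
            if E1 is None:
                E1 = energy
                if E1 < 1e-30:
                    return u, history
            u = u + du
            if energy <= s.energy_tolerance * E1:
                return u, history
        raise NewtonError(
            f"Newton did not converge in {s.max_iterations_per_step} iterations "
            f"at p={p}", history
        )


def solve_hyperelastic(
    mesh: Mesh,
    mats: dict | HyperelasticMaterial,
    p: float,
    settings: SolveSettings | None = None,
    lumen_set: str = "lumen",
) -> SolutionField:
    """Incremental-load hyperelastic solve to lumen pressure p.

    ``mats`` maps region ids to wall (first-invariant) or thrombus
    (second-invariant) materials; a bare material applies to region 0.
    On Newton failure a load step is halved once before giving up.
    """
    settings = settings or SolveSettings()
    if isinstance(mats, (HyperelasticMaterial, ThrombusMaterial)):
        mats = {0: mats}
    prob = _HyperProblem(mesh, mats, settings, lumen_set)
    if not prob.fixed.any():
        raise ValueError("no kinematic constraints: system has rigid-body modes")

    u = np.zeros(prob.n_dofs)
    levels = list(np.linspace(0.0, p, settings.n_load_steps + 1)[1:])
    all_hist = []
    p_prev = 0.0
    i = 0
    halved = False
    while i < len(levels):
        p_step = levels[i]
        try:
            u_new, hist = prob.newton(u.copy(), p_step)
        except NewtonError as err:
            if halved:
                raise NewtonError(
                    f"Newton failed after step halving at p={p_step}; "
                    f"energy history {err.history}", err.history
                ) from err
            halved = True
            levels.insert(i, 0.5 * (p_prev + p_step))
            continue
        all_hist.append(hist)
        u = u_new
        p_prev = p_step
        i += 1

    return _postprocess(prob, u, {"solver": "hyperelastic", "newton_energy": all_hist})


def _postprocess(prob: _HyperProblem, u: np.ndarray, history: dict) -> SolutionField:
    mesh = prob.mesh
    ue = u.reshape(-1, 2)[mesh.elements]
    st = prob._state(ue)
    J, F2, F33 = st["J"], st["F2"], st["F33"]
    sig2 = np.einsum("egik,egjk->egij", st["P2"], F2) / J[..., None, None]
    sig33 = st["P33"] * F33 / J
    sig = np.stack(
        [
            sig2[..., 0, 0],
            sig2[..., 1, 1],
            sig33,
            0.5 * (sig2[..., 0, 1] + sig2[..., 1, 0]),
        ],
        axis=-1,
    )
    stress_nodes = average_to_nodes(prob.data, sig)
    return SolutionField(
        mesh=mesh,
        displacement=u.reshape(-1, 2),
        pressure_coeffs=st["p_coef"],
        stress_nodes=stress_nodes,
        effective_stress_nodes=vonmises(stress_nodes),
        stress_gauss=sig,
        history=history,
    )
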