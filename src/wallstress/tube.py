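"""Closed-form / root-finding solutions for a pressurized thick-wall tube.

Three solution families for a longitudinally constrained circular tube
under internal pressure p:

* nonlinear incompressible hyperelastic (plane strain, lam_z = 1), solved
  by integrating the radial equilibrium ODE and root-finding the deformed
  outer radius so that the outer wall is traction-free;
* linear-elastic small-displacement (Lame), whose stresses are independent
  of the Young's modulus;
* the von Mises effective stress and the global force-balance integral
  used as a solver-quality diagnostic.

Sign convention: tension positive, lumen pressure p > 0 enters as
sigma_rr(a) = -p.  Units mm / N / N/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .materials import HyperelasticMaterial, LinearMaterial, strain_energy_derivative

__all__ = [
    "TubeGeometry",
    "DeformedTube",
    "TubeStressProfile",
    "solve_nonlinear_tube",
    "find_unloaded_tube",
    "solve_linear_tube",
    "linear_tube_displacement",
    "effective_stress",
    "equilibrium_integral",
]

#: number of radial sample points in a stress profile
N_PROFILE = 201
#: composite Gauss panels for the sigma_rr integral
N_PANELS = 64


@dataclass(frozen=True)
class TubeGeometry:
    """Unloaded tube: inner radius A, outer radius B (mm)."""

    A: float
    B: float

    def __post_init__(self) -> None:
        if not (0.0 < self.A < self.B):
            raise ValueError("require 0 < A < B")

    @property
    def thickness(self) -> float:
        return self.B - self.A


@dataclass(frozen=True)
class DeformedTube:
    """Deformed tube radii under pressure p."""

    a: float
    b: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.a < self.b):
            raise ValueError("require 0 < a < b")

    @property
    def thickness(self) -> float:
        return self.b - self.a


@dataclass
class TubeStressProfile:
    """Through-wall stress profile on deformed radii ``r_nodes``.

    ``normalized_thickness`` is (r - a)/(b - a): 0 at the lumen, 1 at the
    outer wall.
    """

    r_nodes: np.ndarray
    sigma_rr: np.ndarray
    sigma_tt: np.ndarray
    sigma_zz: np.ndarray
    sigma_eff: np.ndarray
    p: float

    @property
    def a(self) -> float:
        return float(self.r_nodes[0])

    @property
    def b(self) -> float:
        return float(self.r_nodes[-1])

    @property
    def normalized_thickness(self) -> np.ndarray:
        return (self.r_nodes - self.a) / (self.b - self.a)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "r_mm": self.r_nodes,
                "r_norm": self.normalized_thickness,
                "sigma_rr": self.sigma_rr,
                "sigma_tt": self.sigma_tt,
                "sigma_zz": self.sigma_zz,
                "sigma_eff": self.sigma_eff,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def effective_stress(sigma_rr, sigma_tt, sigma_zz, tau_rt=0.0, tau_tz=0.0, tau_zr=0.0):
    """Von Mises effective stress from cylindrical components."""
    sigma_rr, sigma_tt, sigma_zz = (
        np.asarray(sigma_rr), np.asarray(sigma_tt), np.asarray(sigma_zz)
    )
    dev = (
        (sigma_rr - sigma_tt) ** 2
        + (sigma_tt - sigma_zz) ** 2
        + (sigma_zz - sigma_rr) ** 2
    )
    shear = np.asarray(tau_rt) ** 2 + np.asarray(tau_tz) ** 2 + np.asarray(tau_zr) ** 2
    out = np.sqrt(0.5 * dev + 3.0 * shear)
    return out if out.ndim else float(out)


def _gauss_panels(lo, hi, n_panels: int = N_PANELS, n_gauss: int = 4):
    """Composite Gauss-Legendre nodes/weights on [lo, hi]."""
    x, w = np.polynomial.legendre.leggauss(n_gauss)
    edges = np.linspace(lo, hi, n_panels + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    half = 0.5 * np.diff(edges)
    nodes = (mids[:, None] + half[:, None] * x[None, :]).ravel()
    weights = (half[:, None] * w[None, :]).ravel()
    return nodes, weights


def _hoop_minus_radial(mat: HyperelasticMaterial, r, a, A):
    """sigma_tt - sigma_rr = 2 W'(I_B) (lam_t^2 - lam_r^2) at deformed radius r.

    Incompressible plane strain: R^2 = r^2 - a^2 + A^2, lam_t = r/R.
    """
    r = np.asarray(r, dtype=float)
    R2 = r * r - a * a + A * A
    lt2 = r * r / R2
    lr2 = R2 / (r * r)
    IB = lt2 + lr2 + 1.0
    return 2.0 * strain_energy_derivative(mat, IB) * (lt2 - lr2)


def _sigma_rr_outer_residual(b, geom: TubeGeometry, mat, p):
    """sigma_rr(b) when integrating equilibrium from sigma_rr(a) = -p."""
    a2 = b * b - geom.B**2 + geom.A**2
    if a2 <= 0:
        return -p  # degenerate; keeps the bracket sign sensible
    a = np.sqrt(a2)
    nodes, weights = _gauss_panels(a, b)
    integrand = _hoop_minus_radial(mat, nodes, a, geom.A) / nodes
    return -p + float(np.dot(weights, integrand))


def solve_nonlinear_tube(
    geom: TubeGeometry,
    mat: HyperelasticMaterial,
    p: float,
    n_nodes: int = N_PROFILE,
) -> tuple[DeformedTube, TubeStressProfile]:
    """Inflate an incompressible hyperelastic tube (plane strain).

    The deformed outer radius b is found by bracketed root-finding on the
    outer-wall traction residual; the inner radius follows from
    cross-section area preservation a^2 = b^2 - B^2 + A^2.
    """
    if p < 0:
        raise ValueError("pressure must be non-negative")
    if p == 0.0:
        deformed = DeformedTube(geom.A, geom.B, 0.0)
        r = np.linspace(geom.A, geom.B, n_nodes)
        z = np.zeros_like(r)
        return deformed, TubeStressProfile(r, z.copy(), z.copy(), z.copy(), z.copy(), 0.0)

    lo = geom.B
    # inflation estimate from the leading coefficient; generous margin
    hi = geom.B * (1.0 + p * geom.B / (max(mat.alpha, 1e-6) * geom.thickness) + 0.5)
    f_lo = _sigma_rr_outer_residual(lo, geom, mat, p)
    f_hi = _sigma_rr_outer_residual(hi, geom, mat, p)
    n_expand = 0
    while f_lo * f_hi > 0 and n_expand < 60:
        hi *= 1.5
        f_hi = _sigma_rr_outer_residual(hi, geom, mat, p)
        if not np.isfinite(f_hi):
            raise ValueError(
                f"pressure p={p} too large: traction residual diverges at b={hi}"
            )
        n_expand += 1
    if f_lo * f_hi > 0:
        raise RuntimeError(
            "no bracketing interval for the deformed outer radius: "
            f"residual({lo})={f_lo:.3e}, residual({hi})={f_hi:.3e}"
        )
    b = optimize.brentq(
        _sigma_rr_outer_residual, lo, hi, args=(geom, mat, p), xtol=1e-10
    )
    a = float(np.sqrt(b * b - geom.B**2 + geom.A**2))
    deformed = DeformedTube(a, b, p)

    profile = _nonlinear_profile(mat, a, b, geom.A, p, n_nodes)
    return deformed, profile


def _nonlinear_profile(mat, a, b, A, p, n_nodes) -> TubeStressProfile:
    """Stress profile for the incompressible tube with inner reference
    radius A mapped to deformed inner radius a."""
    r = np.linspace(a, b, n_nodes)
    # cumulative integral of (sigma_tt - sigma_rr)/r via per-interval Gauss
    x4, w4 = np.polynomial.legendre.leggauss(4)
    mids = 0.5 * (r[:-1] + r[1:])
    half = 0.5 * np.diff(r)
    nodes = mids[:, None] + half[:, None] * x4[None, :]
    vals = _hoop_minus_radial(mat, nodes, a, A) / nodes
    seg = (vals * w4[None, :]).sum(axis=1) * half
    sigma_rr = -p + np.concatenate([[0.0], np.cumsum(seg)])
    dsig = _hoop_minus_radial(mat, r, a, A)
    sigma_tt = sigma_rr + dsig
    R2 = r * r - a * a + A * A
    lr2 = R2 / (r * r)
    dw = strain_energy_derivative(mat, lr2 + r * r / R2 + 1.0)
    sigma_zz = sigma_rr + 2.0 * dw * (1.0 - lr2)
    sigma_eff = effective_stress(sigma_rr, sigma_tt, sigma_zz)
    return TubeStressProfile(r, sigma_rr, sigma_tt, sigma_zz, sigma_eff, p)


def find_unloaded_tube(
    deformed: DeformedTube | tuple,
    mat: HyperelasticMaterial,
    p: float,
) -> TubeGeometry:
    """Inverse problem of :func:`solve_nonlinear_tube`: the unloaded radii
    (A, B) whose inflation to pressure p produces the given deformed radii.

    Used to build reference models whose deformed configuration matches a
    prescribed (imaged) geometry.  Root-finds the unloaded inner radius;
    the outer follows from area preservation.
    """
    if isinstance(deformed, tuple):
        deformed = DeformedTube(deformed[0], deformed[1], p)
    a_t, b_t = deformed.a, deformed.b
    area = b_t * b_t - a_t * a_t

    def resid(A):
        nodes, weights = _gauss_panels(a_t, b_t)
        integrand = _hoop_minus_radial(mat, nodes, a_t, A) / nodes
        return -p + float(np.dot(weights, integrand))

    lo, hi = 1e-3 * a_t, a_t
    f_lo, f_hi = resid(lo), resid(hi)
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"unloaded inner radius not bracketed (residuals {f_lo:.3e}, {f_hi:.3e})"
        )
    A = optimize.brentq(resid, lo, hi, xtol=1e-10)
    return TubeGeometry(A, float(np.sqrt(A * A + area)))


def solve_linear_tube(
    geom_deformed: TubeGeometry,
    p: float,
    nu: float = 0.4999,
    n_nodes: int = N_PROFILE,
) -> TubeStressProfile:
    """Lame plane-strain stresses for the linear small-displacement tube.

    The geometry is the imaged (deformed) one and does not change; stresses
    depend on p and the radii only, never on E.  sigma_zz = nu
    (sigma_rr + sigma_tt) from the plane-strain constraint eps_zz = 0.
    """
    if p < 0:
        raise ValueError("pressure must be non-negative")
    a, b = geom_deformed.A, geom_deformed.B
    r = np.linspace(a, b, n_nodes)
    c1 = p * a * a / (b * b - a * a)
    c2 = c1 * b * b
    sigma_rr = c1 - c2 / (r * r)
    sigma_tt = c1 + c2 / (r * r)
    sigma_zz = nu * (sigma_rr + sigma_tt)
    sigma_eff = effective_stress(sigma_rr, sigma_tt, sigma_zz)
    return TubeStressProfile(r, sigma_rr, sigma_tt, sigma_zz, sigma_eff, p)


def linear_tube_displacement(
    geom: TubeGeometry,
    mat: LinearMaterial,
    p: float,
    n_nodes: int = N_PROFILE,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial displacement u_r(r) = c1 r + c2/r of the Lame tube.

    Returns (r, u_r); u_r scales as 1/E.
    """
    a, b = geom.A, geom.B
    r = np.linspace(a, b, n_nodes)
    k1 = p * a * a / (b * b - a * a)
    k2 = k1 * b * b
    u = (1.0 + mat.nu) / mat.E * ((1.0 - 2.0 * mat.nu) * k1 * r + k2 / r)
    return r, u


def equilibrium_integral(profile: TubeStressProfile) -> tuple[float, float]:
    """(integral of sigma_tt dr across the wall, p * a).

    For an equilibrated tube the two agree; their relative gap is a
    solver-quality diagnostic.
    """
    if profile.r_nodes.size < 2:
        raise ValueError("profile needs at least 2 radial nodes")
    integral = float(np.trapezoid(profile.sigma_tt, profile.r_nodes))
    return integral, float(profile.p * profile.a)
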