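"""Opening-angle residual stress model for a circular artery ring.

A radially cut, stress-free open sector (opening angle phi) is closed
into a full ring of prescribed unloaded radii (a0, b0), generating
self-equilibrated circumferential residual stresses; the closed ring can
then be inflated.  With exact incompressible plane-strain kinematics both
states reduce to one-unknown root-finds:

* closing: r^2 = a0^2 + (R^2 - open_A^2)/k with k = pi/(pi - phi_rad),
  lam_theta = k r / R; the single unknown open_A is fixed by the
  traction-free outer wall of the closed ring;
* loading: the same map composed with inflation, the loaded inner radius a
  fixed by sigma_rr(a) = -p, sigma_rr(b) = 0.

The closed unloaded configuration is held fixed independent of the
opening angle, so profiles at different angles are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy import optimize

from .materials import HyperelasticMaterial, strain_energy_derivative
from .tube import TubeStressProfile, effective_stress

__all__ = [
    "ResidualConfig",
    "ResidualState",
    "solve_residual_state",
    "load_with_residual",
    "find_uniformizing_angle",
]

_NP = 201  # profile nodes


@dataclass(frozen=True)
class ResidualConfig:
    """Closed unloaded ring radii (a0, b0) and opening angle phi (degrees)."""

    a0: float
    b0: float
    phi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.a0 < self.b0):
            raise ValueError("require 0 < a0 < b0")
        if self.phi < 0 or self.phi >= 180.0:
            raise ValueError("opening angle must lie in [0, 180) degrees")

    @property
    def k(self) -> float:
        """Angle-mapping factor: closed sweep / open sweep = pi/(pi - phi)."""
        return math.pi / (math.pi - math.radians(self.phi))


@dataclass
class ResidualState:
    """Converged open-sector radii and residual stress profile (p = 0)."""

    config: ResidualConfig
    material: HyperelasticMaterial
    open_A: float
    open_B: float
    residual_profile: TubeStressProfile


def _delta_sigma(mat, r, inner_r, open_A, k):
    """sigma_tt - sigma_rr at ring radius r for the open->current map
    r^2 = inner_r^2 + (R^2 - open_A^2)/k."""
    r = np.asarray(r, dtype=float)
    R2 = open_A**2 + k * (r * r - inner_r**2)
    lt2 = k * k * r * r / R2
    lr2 = 1.0 / lt2
    IB = lt2 + lr2 + 1.0
    return 2.0 * strain_energy_derivative(mat, IB) * (lt2 - lr2)


def _profile(mat, inner_r, outer_r, open_A, k, p, n=_NP) -> TubeStressProfile:
    """Integrate d sigma_rr/dr = (sigma_tt - sigma_rr)/r from
    sigma_rr(inner_r) = -p and assemble the full profile."""
    r = np.linspace(inner_r, outer_r, n)
    x4, w4 = np.polynomial.legendre.leggauss(4)
    mids = 0.5 * (r[:-1] + r[1:])
    half = 0.5 * np.diff(r)
    nodes = mids[:, None] + half[:, None] * x4[None, :]
    vals = _delta_sigma(mat, nodes, inner_r, open_A, k) / nodes
    seg = (vals * w4[None, :]).sum(axis=1) * half
    sigma_rr = -p + np.concatenate([[0.0], np.cumsum(seg)])
    dsig = _delta_sigma(mat, r, inner_r, open_A, k)
    sigma_tt = sigma_rr + dsig
    R2 = open_A**2 + k * (r * r - inner_r**2)
    lr2 = R2 / (k * k * r * r)
    dw = strain_energy_derivative(mat, lr2 + 1.0 / lr2 + 1.0)
    sigma_zz = sigma_rr + 2.0 * dw * (1.0 - lr2)
    sigma_eff = effective_stress(sigma_rr, sigma_tt, sigma_zz)
    return TubeStressProfile(r, sigma_rr, sigma_tt, sigma_zz, sigma_eff, p)


def _outer_traction(mat, inner_r, outer_r, open_A, k, p) -> float:
    nodes, weights = _gauss(inner_r, outer_r)
    vals = _delta_sigma(mat, nodes, inner_r, open_A, k) / nodes
    return -p + float(np.dot(weights, vals))


def _gauss(lo, hi, n_panels=64, n_gauss=4):
    x, w = np.polynomial.legendre.leggauss(n_gauss)
    edges = np.linspace(lo, hi, n_panels + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    half = 0.5 * np.diff(edges)
    return (mids[:, None] + half[:, None] * x[None, :]).ravel(), (
        half[:, None] * w[None, :]
    ).ravel()


def solve_residual_state(
    cfg: ResidualConfig, mat: HyperelasticMaterial
) -> ResidualState:
    """Find the stress-free open sector that closes into the ring (a0, b0).

    Root-finds the open-sector inner radius so the closed ring is
    traction-free on both faces; the outer open radius follows from area
    preservation open_B^2 = open_A^2 + k (b0^2 - a0^2).
    """
    k = cfg.k
    if cfg.phi == 0.0:
        r = np.linspace(cfg.a0, cfg.b0, _NP)
        z = np.zeros_like(r)
        prof = TubeStressProfile(r, z.copy(), z.copy(), z.copy(), z.copy(), 0.0)
        return ResidualState(cfg, mat, cfg.a0, cfg.b0, prof)

    def resid(open_A):
        return _outer_traction(mat, cfg.a0, cfg.b0, open_A, k, 0.0)

    # initial guess: mid-wall circumferentially unstretched
    rm = 0.5 * (cfg.a0 + cfg.b0)
    x_guess = math.sqrt(max(k * k * rm * rm - k * (rm * rm - cfg.a0**2), 1e-12))
    lo, hi = 0.5 * x_guess, 2.0 * x_guess
    f_lo, f_hi = resid(lo), resid(hi)
    n = 0
    while f_lo * f_hi > 0 and n < 60:
        lo *= 0.8
        hi *= 1.25
        f_lo, f_hi = resid(lo), resid(hi)
        n += 1
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"open-sector root not bracketed for phi={cfg.phi} deg "
            f"(residuals {f_lo:.3e}, {f_hi:.3e}); opening angle too extreme "
            "for this material"
        )
    open_A = optimize.brentq(resid, lo, hi, xtol=1e-10)
    open_B = math.sqrt(open_A**2 + k * (cfg.b0**2 - cfg.a0**2))
    prof = _profile(mat, cfg.a0, cfg.b0, open_A, k, 0.0)
    return ResidualState(cfg, mat, open_A, open_B, prof)


def load_with_residual(state: ResidualState, p: float) -> TubeStressProfile:
    """Inflate the residually stressed closed ring to pressure p.

    Composes the open->closed->loaded map; the loaded inner radius a is
    root-found so the outer wall is traction-free, with the outer radius
    tied by area preservation b^2 = a^2 + (b0^2 - a0^2).
    """
    if p < 0:
        raise ValueError("pressure must be non-negative")
    cfg = state.config
    k = cfg.k
    wall_area = cfg.b0**2 - cfg.a0**2

    def resid(a):
        b = math.sqrt(a * a + wall_area)
        return _outer_traction(state.material, a, b, state.open_A, k, p)

    lo = cfg.a0
    hi = cfg.a0 * 3.0
    f_lo, f_hi = resid(lo), resid(hi)
    n = 0
    while f_lo * f_hi > 0 and n < 60:
        lo *= 0.9
        hi *= 1.3
        f_lo, f_hi = resid(lo), resid(hi)
        n += 1
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"loaded inner radius not bracketed (residuals {f_lo:.3e}, {f_hi:.3e})"
        )
    a = optimize.brentq(resid, lo, hi, xtol=1e-10)
    b = math.sqrt(a * a + wall_area)
    return _profile(state.material, a, b, state.open_A, k, p)


def find_uniformizing_angle(
    cfg: ResidualConfig,
    mat: HyperelasticMaterial,
    p: float,
    phi_max: float = 120.0,
    n_grid: int = 25,
) -> dict:
    """Opening angle minimizing the loaded hoop-stress non-uniformity.

    Scans phi in [0, phi_max] for the (max - min) spread of loaded
    sigma_tt across the wall, then polishes with a bounded scalar
    minimization.  Returns the angle, the residual non-uniformity, and a
    ``unimodal`` flag (False when the grid shows multiple local minima, in
    which case the grid minimum is refined anyway).
    """
    if p <= 0:
        raise ValueError("a positive pressure is required to uniformize")

    def spread(phi):
        c = ResidualConfig(cfg.a0, cfg.b0, float(phi))
        prof = load_with_residual(solve_residual_state(c, mat), p)
        return float(prof.sigma_tt.max() - prof.sigma_tt.min())

    phis = np.linspace(0.0, phi_max, n_grid)
    vals = np.array([spread(phi) for phi in phis])
    i_min = int(np.argmin(vals))
    interior = vals[1:-1]
    n_local_min = int(
        np.sum((interior < vals[:-2]) & (interior <= vals[2:]))
    )
    unimodal = n_local_min <= 1
    lo = phis[max(i_min - 1, 0)]
    hi = phis[min(i_min + 1, n_grid - 1)]
    res = optimize.minimize_scalar(spread, bounds=(lo, hi), method="bounded")
    return {
        "phi_deg": float(res.x),
        "nonuniformity": float(res.fun),
        "unimodal": unimodal,
    }
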