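"""Stress-difference metrics and the model-comparison workflows.

Pointwise percent differences, the integrated-normalized difference over
the normalized wall thickness, the analytic material/geometry sweep
(reference vs conventional vs linear tube models), and the
material-property-ratio (MPR) thrombus experiments on the curved
axisymmetric aneurysm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AAAProfile, make_aaa_mesh, make_aaa_profile
from .materials import (
    HyperelasticMaterial,
    LinearMaterial,
    ThrombusMaterial,
    get_material,
)
from .fem import SolveSettings, three_model_run
from .fem.mesh import Mesh, REGION_WALL
from .tube import (
    TubeGeometry,
    TubeStressProfile,
    solve_linear_tube,
    solve_nonlinear_tube,
)

__all__ = [
    "StressComparison",
    "SweepSpec",
    "percent_diff",
    "integrated_diff",
    "compare_profiles",
    "run_sweep",
    "mpr_experiment",
    "wall_section_profile",
]


@dataclass
class StressComparison:
    """Differences of a test stress field against the reference field:
    pointwise percent (masked where the reference vanishes), the
    integrated-normalized scalar, and the percent difference of maxima.
    Positive values mean the test model overestimates."""

    pointwise_pct: np.ma.MaskedArray
    integrated_pct: float
    max_eff_pct: float


def percent_diff(field_test, field_ref) -> np.ma.MaskedArray:
    """Pointwise 100 (sigma - sigma*)/sigma*; reference zeros are masked."""
    t = np.asarray(field_test, dtype=float)
    r = np.asarray(field_ref, dtype=float)
    if t.shape != r.shape:
        raise ValueError(f"field shapes differ: {t.shape} vs {r.shape}")
    mask = r == 0.0
    if mask.any():
        warnings.warn(f"{int(mask.sum())} reference zeros masked in percent_diff")
    safe = np.where(mask, 1.0, r)
    return np.ma.MaskedArray(100.0 * (t - r) / safe, mask=mask)


def _as_grid(profile, component: str):
    if isinstance(profile, TubeStressProfile):
        return profile.normalized_thickness, getattr(profile, component)
    r, v = profile
    return np.asarray(r, dtype=float), np.asarray(v, dtype=float)


def integrated_diff(profile_test, profile_ref, component: str = "sigma_eff",
                    signed: bool = False) -> float:
    """Integrated-normalized percent difference over normalized thickness:

        100 * integral(|sigma - sigma*| dr') / integral(sigma* dr')

    (the signed integrand is available via ``signed=True``).  Profiles may
    be TubeStressProfile objects or (r_norm, values) pairs; a test profile
    on a different grid is resampled onto the reference grid.
    """
    rt, vt = _as_grid(profile_test, component)
    rr, vr = _as_grid(profile_ref, component)
    if rt.shape != rr.shape or not np.allclose(rt, rr):
        warnings.warn("profiles on different grids; resampling test profile")
        vt = np.interp(rr, rt, vt)
    diff = vt - vr
    if not signed:
        diff = np.abs(diff)
    num = np.trapezoid(diff, rr)
    den = np.trapezoid(vr, rr)
    return float(100.0 * num / den)


def compare_profiles(profile_test, profile_ref, component: str = "sigma_eff",
                     signed: bool = False) -> StressComparison:
    rt, vt = _as_grid(profile_test, component)
    rr, vr = _as_grid(profile_ref, component)
    if rt.shape != rr.shape or not np.allclose(rt, rr):
        vt = np.interp(rr, rt, vt)
    return StressComparison(
        pointwise_pct=percent_diff(vt, vr),
        integrated_pct=integrated_diff((rr, vt), (rr, vr), signed=signed),
        max_eff_pct=float(100.0 * (vt.max() - vr.max()) / vr.max()),
    )


@dataclass
class SweepSpec:
    """Material/geometry sweep of the analytic tube pipeline.

    The reference wall coefficients (alpha, beta; gamma = 0) vary over the
    grid; the conventional model always uses the population-average wall
    and the linear model a fixed high modulus.  Geometries are unloaded
    (outer radius B, thickness h0) pairs.  ``alpha_physiological`` marks
    the physiological band of alpha for downstream plotting.
    """

    alpha_ref: np.ndarray = field(
        default_factory=lambda: np.linspace(0.05, 0.5, 10)
    )
    beta_ref: np.ndarray = field(
        default_factory=lambda: np.linspace(0.5, 4.0, 8)
    )
    geometries: list = field(
        default_factory=lambda: [(16.1, 1.3), (25.0, 1.5), (16.1, 2.6)]
    )
    pressure: float = 0.016
    conventional_material: str = "RV"
    linear_nu: float = 0.4999
    alpha_physiological: tuple = (0.104, 0.244)
    signed_integrand: bool = False


def _sweep_cell(alpha, beta, B, h0, p, conv_mat, nu, signed):
    ref_mat = HyperelasticMaterial(alpha=alpha, beta=beta)
    geom = TubeGeometry(B - h0, B)
    deformed, prof_ref = solve_nonlinear_tube(geom, ref_mat, p)
    imaged = TubeGeometry(deformed.a, deformed.b)
    _, prof_conv = solve_nonlinear_tube(imaged, conv_mat, p)
    prof_lin = solve_linear_tube(imaged, p, nu=nu)
    out = {}
    for name, prof in (("linear", prof_lin), ("conventional", prof_conv)):
        cmp_ = compare_profiles(prof, prof_ref, signed=signed)
        out[name] = (cmp_.integrated_pct, cmp_.max_eff_pct)
    return out


def run_sweep(spec: SweepSpec | None = None) -> pd.DataFrame:
    """Long-format table of integrated and maximum effective-stress
    differences (percent, vs reference) per sweep cell and model.

    Cells whose solver fails are recorded with NaN metrics and the sweep
    continues.  The result is deterministic.
    """
    spec = spec or SweepSpec()
    conv_mat = get_material(spec.conventional_material)
    rows = []
    for B, h0 in spec.geometries:
        for alpha in spec.alpha_ref:
            for beta in spec.beta_ref:
                base = {
                    "alpha_ref": float(alpha), "beta_ref": float(beta),
                    "B": float(B), "h0": float(h0), "p": spec.pressure,
                }
                try:
                    cell = _sweep_cell(
                        float(alpha), float(beta), B, h0, spec.pressure,
                        conv_mat, spec.linear_nu, spec.signed_integrand,
                    )
                except Exception as err:  # record and continue
                    for model in ("linear", "conventional"):
                        rows.append({**base, "model": model,
                                     "integrated_pct": np.nan,
                                     "max_pct": np.nan, "error": str(err)})
                    continue
                for model, (ipct, mpct) in cell.items():
                    rows.append({**base, "model": model,
                                 "integrated_pct": ipct, "max_pct": mpct,
                                 "error": ""})
    return pd.DataFrame(rows)


def plot_sweep(table: pd.DataFrame, value: str = "integrated_pct",
               alpha_band: tuple | None = (0.104, 0.244)):
    """Heat maps of a sweep metric, one row of panels per geometry,
    linear vs conventional columns; returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    geoms = sorted(set(zip(table.B, table.h0)))
    fig, axes = plt.subplots(
        len(geoms), 2, figsize=(9, 3.2 * len(geoms)), squeeze=False
    )
    for gi, (B, h0) in enumerate(geoms):
        sub = table[(table.B == B) & (table.h0 == h0)]
        for mi, model in enumerate(("linear", "conventional")):
            pivot = sub[sub.model == model].pivot_table(
                index="beta_ref", columns="alpha_ref", values=value
            )
            ax = axes[gi][mi]
            im = ax.pcolormesh(pivot.columns, pivot.index, np.abs(pivot.values),
                               shading="nearest", cmap="viridis")
            fig.colorbar(im, ax=ax, label=f"|{value}| (%)")
            if alpha_band:
                for a in alpha_band:
                    ax.axvline(a, color="w", ls="--", lw=1)
            ax.set_title(f"{model}, B={B}, h0={h0}")
            ax.set_xlabel("alpha_ref (N/mm^2)")
            ax.set_ylabel("beta_ref (N/mm^2)")
    fig.tight_layout()
    return fig


def wall_section_profile(field, mesh: Mesh, z: float, tol: float = 1e-6):
    """Through-wall effective-stress profile of a SolutionField at height z:
    (normalized thickness from lumen, effective stress) over wall-region
    nodes, ordered by radius."""
    wall_nodes = np.unique(mesh.elements[mesh.region_id == REGION_WALL])
    sel = np.zeros(mesh.n_nodes, dtype=bool)
    sel[wall_nodes] = True
    sel &= np.abs(mesh.nodes[:, 1] - z) < tol
    if sel.sum() < 2:
        raise ValueError(f"no through-wall node line found at z={z}")
    r = mesh.nodes[sel, 0]
    order = np.argsort(r)
    r = r[order]
    vals = field.effective_stress_nodes[sel][order]
    rnorm = (r - r[0]) / (r[-1] - r[0])
    return rnorm, vals


# material pairs realizing the printed wall-to-thrombus property ratios
_MPR_PAIRS = {
    4.0: ("wall-weak", "ILT-stiff"),
    6.7: ("RV", "ILT-mean"),
    10.25: ("wall-stiff", "ILT-weak"),
}


def mpr_pair(mpr: float) -> tuple[HyperelasticMaterial, ThrombusMaterial]:
    """Wall/thrombus material pair with alpha/D1 equal to the given MPR."""
    for key, (wname, tname) in _MPR_PAIRS.items():
        if abs(mpr - key) < 1e-6:
            return get_material(wname), get_material(tname)
    raise KeyError(
        f"no material pair for MPR={mpr}; available: {sorted(_MPR_PAIRS)}"
    )


def mpr_experiment(
    profile: AAAProfile | None = None,
    mpr_values: tuple = (4.0, 6.7, 10.25),
    p: float = 0.016,
    settings: SolveSettings | None = None,
    linear_E: float = 8.4e9,
    n_axial: int = 40,
    n_thickness: int = 3,
    n_thrombus: int = 10,
    section_z: float | None = None,
) -> dict:
    """Matched-MPR thrombus experiments on the curved aneurysm.

    For each MPR, runs the reference/conventional (hyperelastic wall +
    thrombus) and linear (wall-to-thrombus modulus ratio = MPR) models and
    compares wall effective stress through the thickness at the
    maximum-diameter section.  Returns per-MPR profiles and metrics plus a
    summary DataFrame under key "table".
    """
    profile = profile or make_aaa_profile()
    settings = settings or SolveSettings()
    mesh = make_aaa_mesh(profile, with_thrombus=True, n_thickness=n_thickness,
                         n_axial=n_axial, n_thrombus=n_thrombus)
    z = section_z if section_z is not None else 0.5 * profile.height
    results = {}
    rows = []
    for mpr in mpr_values:
        wall, thrombus = mpr_pair(mpr)
        res = three_model_run(
            mesh, {0: wall, 1: thrombus}, p, settings,
            linear_E=linear_E, linear_mpr=mpr,
        )
        rn_ref, v_ref = wall_section_profile(res.reference, mesh, z)
        rn_lin, v_lin = wall_section_profile(res.linear, mesh, z)
        rn_con, v_con = wall_section_profile(res.conventional, mesh, z)
        cmp_lin = compare_profiles((rn_lin, v_lin), (rn_ref, v_ref))
        cmp_con = compare_profiles((rn_con, v_con), (rn_ref, v_ref))
        results[mpr] = {
            "r_norm": rn_ref,
            "reference": v_ref, "linear": v_lin, "conventional": v_con,
            "linear_cmp": cmp_lin, "conventional_cmp": cmp_con,
            "run": res,
        }
        for model, c in (("linear", cmp_lin), ("conventional", cmp_con)):
            rows.append({
                "mpr": mpr, "model": model,
                "max_abs_pointwise_pct": float(np.abs(c.pointwise_pct).max()),
                "integrated_pct": c.integrated_pct,
                "max_eff_pct": c.max_eff_pct,
            })
    results["table"] = pd.DataFrame(rows)
    return results
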