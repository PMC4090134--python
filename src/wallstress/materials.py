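"""Constitutive models for the aneurysm wall and intraluminal thrombus.

The wall is an isotropic, (nearly) incompressible hyperelastic solid with a
polynomial strain-energy density in the first invariant of the left
Cauchy-Green tensor B,

    W(I_B) = alpha (I_B - 3) + beta (I_B - 3)^2 + gamma (I_B - 3)^3
             + zeta (I_B - 3)^4 + eta (I_B - 3)^5 ,

the two-term (gamma = zeta = eta = 0) case being the classical
Raghavan-Vorp population-average model.  The intraluminal thrombus uses a
second-invariant energy W = D1 (II_B - 3) + D2 (II_B - 3)^2.  The linear
model wall is isotropic linear elastic (E, nu).

Units: stresses and energy densities in N/mm^2 (MPa), stretches
dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HyperelasticMaterial",
    "LinearMaterial",
    "ThrombusMaterial",
    "StretchState",
    "builtin_materials",
    "strain_energy",
    "strain_energy_derivative",
    "cauchy_stress",
    "dump_catalog",
    "load_catalog",
]


@dataclass(frozen=True)
class HyperelasticMaterial:
    """Isotropic first-invariant polynomial hyperelastic wall material.

    Coefficients in N/mm^2; ``alpha`` is the leading (shear-like) term.
    """

    alpha: float
    beta: float = 0.0
    gamma: float = 0.0
    zeta: float = 0.0
    eta: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        coeffs = (self.alpha, self.beta, self.gamma, self.zeta, self.eta)
        if not all(np.isfinite(coeffs)):
            raise ValueError("material coefficients must be finite")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    @property
    def coefficients(self) -> tuple[float, float, float, float, float]:
        return (self.alpha, self.beta, self.gamma, self.zeta, self.eta)

    def energy(self, IB):
        """Strain-energy density W(I_B)."""
        return strain_energy(self, IB)

    def denergy(self, IB):
        """dW/dI_B."""
        return strain_energy_derivative(self, IB)


@dataclass(frozen=True)
class LinearMaterial:
    """Isotropic linear-elastic material (Young's modulus E, Poisson nu)."""

    E: float
    nu: float = 0.4999

    def __post_init__(self) -> None:
        if not (self.E > 0):
            raise ValueError("E must be positive")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("nu must lie in [0, 0.5)")

    @property
    def mu(self) -> float:
        """Shear modulus."""
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def bulk(self) -> float:
        """Bulk modulus."""
        return self.E / (3.0 * (1.0 - 2.0 * self.nu))


@dataclass(frozen=True)
class ThrombusMaterial:
    """Intraluminal thrombus: W = D1 (II_B - 3) + D2 (II_B - 3)^2."""

    D1: float
    D2: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.D1 > 0):
            raise ValueError("D1 must be positive")
        if self.D2 < 0:
            raise ValueError("D2 must be non-negative")

    def energy(self, IIB):
        x = np.asarray(IIB) - 3.0
        return self.D1 * x + self.D2 * x * x

    def denergy(self, IIB):
        """dW/dII_B."""
        x = np.asarray(IIB) - 3.0
        return self.D1 + 2.0 * self.D2 * x


@dataclass
class StretchState:
    """Principal stretches plus the hydrostatic pressure H of an
    incompressible state.  H must be supplied by the boundary-value solver;
    it is not a material property."""

    lam_r: float
    lam_theta: float
    lam_z: float = 1.0
    H: float | None = None
    incompressible: bool = True

    def __post_init__(self) -> None:
        if self.incompressible:
            J = self.lam_r * self.lam_theta * self.lam_z
            if abs(J - 1.0) > 1e-8:
                raise ValueError(
                    f"incompressible state requires lam_r*lam_theta*lam_z = 1, got {J!r}"
                )

    @property
    def IB(self) -> float:
        """First invariant of B = F F^T (principal form)."""
        return self.lam_r**2 + self.lam_theta**2 + self.lam_z**2


# Coefficients from uniaxial (Raghavan-Vorp) and biaxial (Polzer et al.)
# tensile tests on human AAA tissue; thrombus range from Di Martino et al.
_WALL_CATALOG = {
    "RV": HyperelasticMaterial(alpha=0.174, beta=1.881, gamma=0.0, label="RV"),
    "P1": HyperelasticMaterial(alpha=0.0145, beta=0.0, gamma=2.259, label="P1"),
    "P2": HyperelasticMaterial(alpha=0.022, beta=1.461, gamma=1.0, label="P2"),
}

_THROMBUS_CATALOG = {
    # population mean D1; D2 mid-range of the reported 95% interval
    "ILT-mean": ThrombusMaterial(D1=0.026, D2=0.0286, label="ILT-mean"),
    "ILT-stiff": ThrombusMaterial(D1=0.036, D2=0.0356, label="ILT-stiff"),
    "ILT-weak": ThrombusMaterial(D1=0.0199, D2=0.0216, label="ILT-weak"),
}

# Weak/stiff wall variants used in the material-property-ratio study.
_WALL_VARIANTS = {
    "wall-weak": HyperelasticMaterial(alpha=0.144, beta=1.152, label="wall-weak"),
    "wall-stiff": HyperelasticMaterial(alpha=0.204, beta=2.61, label="wall-stiff"),
}


def builtin_materials() -> dict[str, HyperelasticMaterial | ThrombusMaterial]:
    """Catalog of named built-in materials.

    Wall models RV, P1, P2, the weak/stiff wall variants, and the mean /
    stiff / weak intraluminal thrombus.
    """
    cat: dict = {}
    cat.update(_WALL_CATALOG)
    cat.update(_WALL_VARIANTS)
    cat.update(_THROMBUS_CATALOG)
    return cat


def get_material(name: str):
    """Look up a built-in material by name (KeyError on unknown name)."""
    cat = builtin_materials()
    try:
        return cat[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; available: {sorted(cat)}"
        ) from None


def strain_energy(mat: HyperelasticMaterial, IB):
    """Polynomial strain-energy density W(I_B); rejects I_B < 3 - 1e-9."""
    IB = np.asarray(IB, dtype=float)
    if not np.all(np.isfinite(IB)):
        raise ValueError("I_B must be finite")
    if np.any(IB < 3.0 - 1e-9):
        raise ValueError("I_B < 3 is unphysical for an incompressible state")
    x = IB - 3.0
    a, b, c, z, e = mat.coefficients
    # Horner form in x
    w = x * (a + x * (b + x * (c + x * (z + x * e))))
    return w if w.ndim else float(w)


def strain_energy_derivative(mat: HyperelasticMaterial, IB):
    """dW/dI_B from the same polynomial evaluation."""
    IB = np.asarray(IB, dtype=float)
    if not np.all(np.isfinite(IB)):
        raise ValueError("I_B must be finite")
    x = IB - 3.0
    a, b, c, z, e = mat.coefficients
    dw = a + x * (2 * b + x * (3 * c + x * (4 * z + x * 5 * e)))
    return dw if dw.ndim else float(dw)


def cauchy_stress(mat: HyperelasticMaterial, s: StretchState):
    """Principal Cauchy stresses (sigma_rr, sigma_tt, sigma_zz).

    For an incompressible state, sigma_ii = -H + 2 (dW/dI_B) (lam_ii^2 - 1);
    the hydrostatic pressure H must have been set by the solver.  Because
    the hydrostatic pressure of an incompressible material is fixed only by
    boundary conditions, it is gauged here so that the undeformed state with
    H = 0 is stress-free; stress differences are independent of the gauge.
    """
    if s.H is None:
        raise ValueError(
            "StretchState.H is unset: the hydrostatic pressure must be "
            "supplied by the boundary-value solver"
        )
    if not s.incompressible:
        raise ValueError("cauchy_stress requires an incompressible state")
    dw = strain_energy_derivative(mat, s.IB)
    return tuple(
        -s.H + 2.0 * dw * (lam**2 - 1.0)
        for lam in (s.lam_r, s.lam_theta, s.lam_z)
    )


def _format_block(name: str, mat) -> str:
    lines = [f"[{name}]"]
    if isinstance(mat, HyperelasticMaterial):
        lines.append("kind = hyperelastic")
        for key in ("alpha", "beta", "gamma", "zeta", "eta"):
            lines.append(f"{key} = {getattr(mat, key)!r}")
    elif isinstance(mat, LinearMaterial):
        lines.append("kind = linear")
        lines.append(f"E = {mat.E!r}")
        lines.append(f"nu = {mat.nu!r}")
    elif isinstance(mat, ThrombusMaterial):
        lines.append("kind = thrombus")
        lines.append(f"D1 = {mat.D1!r}")
        lines.append(f"D2 = {mat.D2!r}")
    else:  # pragma: no cover
        raise TypeError(f"unknown material type {type(mat)!r}")
    return "\n".join(lines)


def dump_catalog(catalog: dict, path) -> None:
    """Write a material catalog as plain-text key-value blocks."""
    text = "\n\n".join(_format_block(name, mat) for name, mat in catalog.items())
    with open(path, "w") as fh:
        fh.write(text + "\n")


def load_catalog(path) -> dict:
    """Read a material catalog written by :func:`dump_catalog`."""
    catalog: dict = {}
    name = None
    fields: dict = {}

    def _flush():
        if name is None:
            return
        kind = fields.pop("kind")
        if kind == "hyperelastic":
            catalog[name] = HyperelasticMaterial(label=name, **fields)
        elif kind == "linear":
            catalog[name] = LinearMaterial(**fields)
        elif kind == "thrombus":
            catalog[name] = ThrombusMaterial(label=name, **fields)
        else:
            raise ValueError(f"unknown material kind {kind!r}")

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                _flush()
                name = line[1:-1]
                fields = {}
            else:
                key, _, value = line.partition("=")
                key = key.strip()
                value = value.strip()
                fields[key] = value if key == "kind" else float(value)
    _flush()
    return catalog
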