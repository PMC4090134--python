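"""Solver settings and solution container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SolveSettings:
    """Controls for the FE solvers.

    energy_tolerance: Newton convergence ratio of out-of-balance energy.
    max_iterations_per_step: Newton iterations allowed per load step.
    n_load_steps: incremental pressure steps for the hyperelastic solve.
    formulation: "axisymmetric" (coords = (r, z)) or "plane_strain" ((x, y)).
    pressure_config: apply the lumen pressure on the "deformed" (follower)
        or "undeformed" surface in the hyperelastic solve.
    kappa: volumetric penalty modulus (N/mm^2) enforcing near
        incompressibility of the hyperelastic material.
    """

    energy_tolerance: float = 1e-3
    max_iterations_per_step: int = 15
    n_load_steps: int = 15
    formulation: str = "axisymmetric"
    pressure_config: str = "deformed"
    kappa: float = 1000.0

    def __post_init__(self) -> None:
        if self.energy_tolerance <= 0:
            raise ValueError("energy_tolerance must be positive")
        if self.formulation not in ("axisymmetric", "plane_strain"):
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if self.pressure_config not in ("deformed", "undeformed"):
            raise ValueError(f"unknown pressure_config {self.pressure_config!r}")


@dataclass
class SolutionField:
    """FE solution: nodal displacements, element pressure coefficients and
    recovered Cauchy stresses.

    ``stress_nodes`` holds nodal-averaged components in the order
    (s11, s22, s33(hoop/out-of-plane), s12); averaging from quadrature
    points is a post-processing step (``postprocessed=True``).
    ``stress_gauss`` keeps the raw quadrature-point values (ne, ng, 4).
    """

    mesh: "object"
    displacement: np.ndarray
    pressure_coeffs: np.ndarray
    stress_nodes: np.ndarray
    effective_stress_nodes: np.ndarray
    stress_gauss: np.ndarray
    postprocessed: bool = True
    history: dict = field(default_factory=dict)

    @property
    def deformed_nodes(self) -> np.ndarray:
        return self.mesh.nodes + self.displacement
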