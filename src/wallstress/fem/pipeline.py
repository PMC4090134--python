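"""Three-model comparison pipeline on a shared geometry.

Reference: hyperelastic solve from the supplied (truly unloaded)
configuration.  Its deformed configuration stands in for the imaged
patient geometry and becomes the initial configuration of the
conventional (hyperelastic, wrongly assumed unloaded) and linear
(small-displacement) runs.  All three stress fields live on the same
nodes of that shared configuration, so pointwise comparison is by
material point.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..materials import HyperelasticMaterial, LinearMaterial, ThrombusMaterial
from .hyper import solve_hyperelastic
from .linear import solve_linear
from .mesh import Mesh, REGION_THROMBUS
from .settings import SolveSettings, SolutionField


@dataclass
class ThreeModelResult:
    reference: SolutionField
    conventional: SolutionField
    linear: SolutionField
    imaged_mesh: Mesh  # reference deformed configuration


def three_model_run(
    mesh: Mesh,
    mats_reference: dict | HyperelasticMaterial,
    p: float,
    settings: SolveSettings | None = None,
    mats_conventional: dict | HyperelasticMaterial | None = None,
    linear_E: float = 8.4e9,
    linear_nu: float = 0.4999,
    linear_mpr: float | None = None,
) -> ThreeModelResult:
    """Run reference, conventional and linear models on one geometry.

    ``mats_reference`` supplies per-region materials for the reference
    solve; the conventional solve reuses them unless
    ``mats_conventional`` overrides (the clinically common choice is the
    population-average wall).  The linear wall modulus is ``linear_E``;
    with a thrombus region, its modulus is ``linear_E / linear_mpr``
    (wall-to-thrombus material property ratio, required in that case).
    """
    settings = settings or SolveSettings()
    if isinstance(mats_reference, (HyperelasticMaterial, ThrombusMaterial)):
        mats_reference = {0: mats_reference}
    try:
        reference = solve_hyperelastic(mesh, mats_reference, p, settings)
    except Exception as err:
        raise RuntimeError(f"reference stage failed: {err}") from err

    imaged = Mesh(
        mesh.nodes + reference.displacement,
        mesh.elements,
        mesh.region_id,
        edge_sets=dict(mesh.edge_sets),
        node_sets=dict(mesh.node_sets),
    )

    mats_conv = mats_conventional if mats_conventional is not None else mats_reference
    if isinstance(mats_conv, (HyperelasticMaterial, ThrombusMaterial)):
        mats_conv = {0: mats_conv}
    try:
        conventional = solve_hyperelastic(imaged, mats_conv, p, settings)
    except Exception as err:
        raise RuntimeError(f"conventional stage failed: {err}") from err

    lin_mats = {0: LinearMaterial(E=linear_E, nu=linear_nu)}
    if (imaged.region_id == REGION_THROMBUS).any():
        if linear_mpr is None:
            raise ValueError(
                "linear_mpr (wall/thrombus modulus ratio) is required when the "
                "mesh has a thrombus region"
            )
        lin_mats[REGION_THROMBUS] = LinearMaterial(E=linear_E / linear_mpr,
                                                   nu=linear_nu)
    try:
        linear = solve_linear(imaged, lin_mats, p, settings)
    except Exception as err:
        raise RuntimeError(f"linear stage failed: {err}") from err

    return ThreeModelResult(reference, conventional, linear, imaged)
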