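# Methods

## The three-model framework

Clinical images show an aneurysm *under load*: the geometry segmented from a
CT scan is the deformed configuration at (roughly) systolic pressure, while
the unloaded, unstressed configuration is unknown. `wallstress` implements
the three models used to quantify what this does to computed wall stress:

* **Reference model** — a hypothetical run in which the unloaded
  configuration and the wall's hyperelastic properties are assumed known.
  Pressurizing it produces the "imaged" geometry and the ground-truth stress
  field.
* **Conventional model** — the common practice: the imaged geometry is
  (wrongly) treated as unloaded and pressurized with the same hyperelastic
  law, producing artificial over-expansion and stress overestimation.
* **Linear model** — the imaged geometry is kept, the wall is linear elastic
  with an arbitrarily high Young's modulus, and displacements are
  infinitesimal. The solve returns the equilibrium stress field of the
  imaged geometry directly; the stresses are independent of the modulus
  chosen, so no knowledge of patient tissue properties is needed.

The central quantitative claim the package reproduces is that the linear
model's stresses track the reference stresses more closely than the
conventional model's, across materials, geometries, pressures, and in the
presence of an intraluminal thrombus.

## Constitutive models

Wall: isotropic, (nearly) incompressible hyperelastic with polynomial
energy in the first invariant of B = F Fᵀ,

    W = α(I_B−3) + β(I_B−3)² + γ(I_B−3)³ + ζ(I_B−3)⁴ + η(I_B−3)⁵   [N/mm²]

The built-in catalog carries the Raghavan–Vorp population average
(α = 0.174, β = 1.881) and two patient-specific biaxial fits
(P1: α = 0.0145, γ = 2.259; P2: α = 0.022, β = 1.461, γ = 1.0), all with
ζ = η = 0; the five-term form is the single implementation.

Thrombus: second-invariant form W = D1(II_B−3) + D2(II_B−3)², with the
population-mean D1 = 0.026 N/mm² and stiff/weak variants spanning the
reported 95% ranges (D1 ∈ [0.0199, 0.036], D2 ∈ [0.0216, 0.0356]).  The
mean-entry D2 = 0.0286 N/mm² is the mid-range, since only the interval is
reported.  The wall-to-thrombus **material property ratio** MPR = α/D1
(or E_wall/E_ILT in the linear model) controls load sharing; the printed
pairs realize MPR = 4, 6.7 and 10.25.

Linear wall: isotropic (E, ν), defaults E = 8.4×10⁹ N/mm², ν = 0.4999.

For an incompressible material the hydrostatic pressure H is fixed only by
boundary conditions, so the materials-level `cauchy_stress` helper gauges
it such that the undeformed state with H = 0 is stress-free
(σᵢᵢ = −H + 2W′(I_B)(λᵢᵢ²−1)); every stress *difference* is independent of
this gauge, and the boundary-value solvers carry their own consistent H.

Units are fixed package-wide: mm, N, N/mm² (= MPa).  Pressures in mmHg are
converted explicitly (1 mmHg = 1.33322×10⁻⁴ N/mm²; 120 mmHg ↔ 0.016 N/mm²).

## Analytic tube solutions

For a longitudinally constrained thick-wall tube (plane strain, λ_z = 1,
incompressible), the radial map is r² = R² − A² + a², with λ_θ = r/R,
λ_r = R/r.  Radial equilibrium dσ_rr/dr = (σ_θθ−σ_rr)/r integrates from
σ_rr(a) = −p, with σ_θθ − σ_rr = 2W′(I_B)(λ_θ²−λ_r²).  The deformed outer
radius b is found by bracketed Brent root-finding (xtol 10⁻¹⁰ mm) on the
traction-free outer-wall condition, with the inner radius tied by exact
area preservation a² = b² − B² + A²; the initial bracket is
[B, B(1 + pB/(α(B−A)) + margin)] with geometric expansion as a fallback.
The σ_rr integral uses composite 4-point Gauss on 64 panels; profiles are
sampled on 201 evenly spaced radii with per-interval Gauss accumulation.
σ_zz follows from the hydrostatic pressure, σ_zz = σ_rr + 2W′(1−λ_r²).
The inverse problem (`find_unloaded_tube`) root-finds the unloaded inner
radius producing a prescribed deformed geometry — this is how reference
models matching an "imaged" tube are built.

Linear tube: the Lamé plane-strain solution with σ_rr(a) = −p, σ_rr(b) = 0
on the unchanged imaged radii; σ_zz = ν(σ_rr+σ_θθ).  The stresses contain
no E by construction.

Effective stress is the von Mises combination of the cylindrical
components, including σ_zz and any shear.  The force-balance diagnostic
∫σ_θθ dr = p·a holds for every equilibrated tube profile and is exposed by
`equilibrium_integral`; solver quality is its relative gap (≲10⁻⁶ for the
analytic solvers, ≲0.5% for FE).

Normalized thickness is r′ = (r−a)/(b−a), zero at the lumen.

## Opening-angle residual stress

A stress-free open sector with opening angle φ closes into a ring of
prescribed unloaded radii (a₀, b₀).  With the angle-map factor
k = π/(π−φ_rad) (closed sweep over open sweep), exact incompressible
plane-strain kinematics give r² = a₀² + (R²−open_A²)/k, λ_θ = k r/R.  The
single unknown open_A is root-found so the closed ring is traction-free on
both faces; open_B follows from area preservation.  The residual hoop
stress is compressive at the inner surface and tensile at the outer, and
integrates to zero net force (self-equilibration, verified to
10⁻⁶·max|σ_θθ|·h).  Loading composes the same map with inflation and
root-finds the loaded inner radius.  Because the closed configuration is
held fixed independent of φ, profiles at different angles are directly
comparable: increasing φ flattens the transmural gradient of the loaded
hoop stress and then reverses its sign; `find_uniformizing_angle` locates
the flattening angle by a grid scan plus bounded scalar minimization
(returning the grid minimum with a flag when the scan is not unimodal).
Since the integrand of the equilibrium ODE does not involve σ_rr itself,
the integration is performed as adaptive/composite Gaussian quadrature at
tolerance 10⁻¹⁰ — mathematically identical to integrating the ODE.

This semi-analytic route replaces a finite-element sector-closure
(imposing a closing displacement on a half sector): the closed unloaded
configuration constraint is honored exactly and the whole problem reduces
to one-dimensional root-finds.  The FE core can cross-validate it but is
not required.  Residual stresses in non-circular geometries are out of
scope (the construction needs a circular ring).

## Finite-element core

Element: 9-node Lagrange quadrilateral, 3×3 Gauss quadrature, with a
discontinuous per-element linear pressure (coefficients on {1, ξ, η}) —
the inf-sup stable "9/3" mixed pair — in axisymmetric (r, z) or
plane-strain (x, y) form.  Axisymmetric integrals carry the radius weight
and drop the common 2π.

*Linear solver*: small-strain mixed u/p with the pressure condensed
exactly per element, leaving an SPD displacement system solved by sparse
direct factorization.  Pressure is applied as a traction on the
*undeformed* lumen surface, consistent with the infinitesimal-displacement
assumption; the geometry is never updated.  With ν = 0.4999 the element
pair is locking-free, and computed stresses are invariant to E to
~10⁻⁷ % (roundoff), displacement scaling as 1/E.

*Hyperelastic solver*: total Lagrangian with the isochoric split
W(Ī₁, Ī₂), Īₖ = J^(−2k/3)Iₖ, plus a volumetric penalty whose per-element
pressure p̃ = κ(J−1) is condensed exactly (perturbed Lagrangian).  The
penalty modulus κ (default 1000 N/mm², i.e. ≥10³× the wall shear scale)
sets the residual compressibility J−1 ≈ p̃/κ ~ 10⁻⁴ at systolic load —
small enough that deformed radii match the incompressible closed form to
<0.01%.  The lumen pressure is a follower load evaluated on the current
surface (switchable to the undeformed surface via
`pressure_config="undeformed"`; the dead-load variant expands the tube
less, as expected).  Loading is incremental (default 15 steps) with full
Newton per step; convergence is the out-of-balance energy ratio
|Δu·r| / |Δu₁·r₀| ≤ 10⁻³, at most 15 iterations per step, one level of
step halving on failure.  Element tangents are computed by complex-step
differentiation of the analytic element residual — exact to machine
precision and immune to step-size choice — vectorized over all elements
(19 residual sweeps per iteration), so Newton converges quadratically.
Transiently inverted trial elements produce NaN residuals that the driver
detects and recovers from.

Stress recovery evaluates Cauchy stress σ = J⁻¹PFᵀ at Gauss points,
extrapolates with the exact biquadratic map to nodes and averages across
elements; both raw Gauss and averaged nodal values are kept, the latter
flagged as post-processed.  The assembly contains no randomness and the
default linear algebra is a sparse direct solve, so repeated runs are
bit-identical.

Verification: a one-element uniform-pressure patch test is exact to
machine precision; tube meshes converge monotonically to the Lamé and
incompressible closed forms (≤1% at 6 elements through the wall); global
force balance holds to 0.5%.

Default through-thickness element counts: 6 for the tube studies, 3 for
the wall of residual/curved models, 10 for the thrombus.

## Geometries and the synthetic patient-like profile

The idealized curved axisymmetric sac is parameterized by height (130 mm),
maximum diameter (50 mm), and uniform wall thickness (1.5 mm, the reported
median).  The published figure constraints fix only these numbers, so the
outer wall is modeled as a C¹ cosine-squared bulge of length 100 mm on a
cylindrical neck (outer radius 12.5 mm), peaking at mid-height with
cylindrical ends.  The lumen is a coaxial cylinder at the neck's inner
radius, so the thrombus fills the dilated part of the sac; the thrombus
region is meshed conformally (node-matched interface) over the axial span
where it is at least 0.8 mm thick, its end faces are pressure-wetted and
constrained longitudinally, and the wall ends are constrained
longitudinally.  Variable-thickness tubes modulate the wall cosine-wise,
longitudinally (axisymmetric) or circumferentially (plane-strain ring);
the published modulation functions are not printed, so amplitude and
wavelength are free parameters.

The seeded "patient-like" generator replaces the out-of-scope CT-derived
mesh: a sum of 2–4 smooth Gaussian dilation bumps (amplitudes 2–6 mm,
widths 10–22 mm, centers in the middle half of the vessel) on a
20 mm-radius tube with a uniform 1.5 mm wall, bit-reproducible per seed.
It emulates the axisymmetric essentials of a patient sac — irregular,
Z-asymmetric dilation with smooth curvature — but *not* non-axisymmetric
bulging, local wall thinning, branch vessels, imaging noise, or real
lumen/thrombus topology.  Tests passing on it therefore demonstrate the
solvers and the model-comparison logic on patient-like curvature, not
clinical fidelity of any particular stress value.

Mesh I/O uses legacy ASCII VTK unstructured grids (biquadratic quads) and
a minimal Abaqus-style `.inp` node/element reader, both implemented in the
package; VTK files carry no boundary-set payload, so the CLI reconstructs
lumen/end sets for structured meshes heuristically.

## Comparison metrics and workflows

Pointwise differences are 100(σᵢ−σᵢ*)/σᵢ* (reference zeros masked and
reported).  The thickness-integrated metric is
100·∫|σᵢ−σᵢ*|dr′ / ∫σᵢ*dr′ on the shared normalized-thickness grid; the
absolute value makes it a norm — the published formula's sign convention
is not recoverable, so a `signed` option is provided (a signed integrand
can cancel over/under-shoots to zero).  The maximum-stress metric applies
the pointwise formula to the independently located maxima of each field.
Both metrics are invariant to a common positive rescaling of the fields.

The sweep engine varies the reference wall's (α, β) over a grid (γ = 0)
and the unloaded geometry (B, h₀), holding the conventional model at the
population-average wall and the linear model at fixed high E, and tabulates
both metrics per cell — the analytic tube pipeline makes each cell three
fast root-finds.  Expected orderings reproduced: linear ≤ conventional
error over the physiological α band; both errors decrease with α;
conventional error grows with diameter and with pressure while the linear
stress field remains exact in equilibrium.

The MPR experiments mesh the curved sac with thrombus, run the reference
and conventional models with a printed wall/thrombus pair and the linear
model at the matching E ratio, and compare wall effective stress through
the thickness at the maximum-diameter section.  At matched MPR = 6.7 the
linear model is within ~1.4% of reference pointwise (well under the 5%
benchmark) on the default 360-element mesh, while the conventional model
overestimates by ~32%.

## Problem sizes and tolerances used in the shipped workflows

Validation and acceptance workflows use: 201-point analytic profiles;
6×4-element tube meshes for FE/analytic cross-checks; a 360-element
(40 axial × [3 wall + 10 thrombus]) curved-sac mesh with 15 load steps for
the thrombus experiment (the test suite uses a 24-axial, 2+5 variant of
the same workflow).  These sizes sit on the flat part of the convergence
curves established by the refinement tests; halving them changes the
matched-MPR result by well under a percentage point.

## Known limitations

2D axisymmetric/plane-strain only (no 3D hexahedra, no patient meshes);
isotropic, homogeneous tissue; no axial pre-stretch (λ_z = 1) or closed-end
force balance; no viscoelasticity, damage, growth/remodeling, contact with
external organs, or fluid–structure interaction; residual stresses only
for circular rings; static loading only.  The conventional-model outer
radius printed for the benchmark tube is inconsistent with exact area
preservation by ~0.4%, consistent with nearly (not exactly) incompressible
FE output; the analytic solve matches the inner radius closely and the
outer radius is deliberately not pinned.
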