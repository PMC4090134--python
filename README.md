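# wallstress

Wall-stress computation for abdominal aortic aneurysms (AAAs), built to
benchmark a **linear-equilibrium** stress estimate against the
conventional nonlinear approach.

## The problem

Patient images (CT, MRI) show an aneurysm under blood pressure, yet wall
stress is conventionally computed by pressurizing that imaged geometry as
if it were unloaded, with a nonlinear hyperelastic wall model — an
assumption that artificially over-expands the vessel and overestimates
stress, and whose iterative solves are slow and fragile.  Because the
true stress field must satisfy equilibrium *in the imaged configuration*,
a linear-elastic model with an arbitrarily high Young's modulus and
infinitesimal displacements recovers the equilibrium stresses directly on
the patient geometry, in a single linear solve, without knowing the
patient's tissue properties.  This package implements that linear model
together with everything needed to judge it:

* closed-form solvers for the pressurized thick-wall tube — incompressible
  hyperelastic (energy `W = α(I_B−3) + β(I_B−3)² + …`, with the
  Raghavan–Vorp and Polzer patient coefficient sets built in) and linear
  (Lamé) — plus the force-balance diagnostic `∫σ_θθ dr = p·a`;
* a semi-analytic opening-angle model of circumferential residual stress
  (stress-free open sector closed into a ring, then inflated);
* a compact mixed displacement/pressure finite-element core (9-node
  quads with per-element linear pressure, axisymmetric and plane strain)
  for linear and incompressible hyperelastic problems, including
  two-material wall + intraluminal-thrombus domains;
* geometry generators: straight and variable-thickness tubes, an idealized
  curved axisymmetric AAA (130 mm tall, 50 mm max diameter, 1.5 mm wall)
  with optional thrombus, and seeded synthetic "patient-like" profiles;
* the three-model comparison pipeline (reference / conventional / linear),
  stress-difference metrics, material/geometry sweeps, and
  material-property-ratio (MPR) thrombus experiments.

Intended users: vascular-biomechanics researchers and students studying
how unloaded-configuration uncertainty, tissue properties, residual
stress, and thrombus affect computed AAA wall stress.

## Worked example

Build a reference tube whose pressurized (imaged) radii are 14.8/16.1 mm
at systolic pressure, then compare the conventional and linear estimates:

```python
from wallstress import (TubeGeometry, find_unloaded_tube, get_material,
                        solve_nonlinear_tube, solve_linear_tube,
                        equilibrium_integral)
from wallstress.compare import compare_profiles

rv, p = get_material("RV"), 0.016          # population-average wall, 120 mmHg
imaged = TubeGeometry(14.8, 16.1)          # radii seen on the image, mm

unloaded = find_unloaded_tube((14.8, 16.1), rv, p)   # A=13.499, B=14.913 mm
_, ref  = solve_nonlinear_tube(unloaded, rv, p)      # reference ground truth
conv_d, conv = solve_nonlinear_tube(imaged, rv, p)   # conventional model
lin = solve_linear_tube(imaged, p)                   # linear model

print(conv_d.a)                            # 16.364  (over-expanded lumen, mm)
print(equilibrium_integral(lin)[0])        # 0.2368  = p*a          (N/mm)
print(equilibrium_integral(conv)[0])       # 0.2618  (inflated force balance)
print(compare_profiles(lin,  ref).integrated_pct)    #  3.9 %
print(compare_profiles(conv, ref).integrated_pct)    # 20.6 %
```

The linear model reproduces the reference force balance exactly (both
0.2368 N/mm = p·a, since they share the imaged geometry) and tracks the
reference stress profile five times more closely than the conventional
model, which over-expands the lumen from 14.8 to 16.36 mm and carries an
inflated equilibrium integral.

The same comparison on the curved aneurysm with thrombus, from the shell:

```bash
wallstress --out-dir out mpr --mpr-values 6.7
```

prints the matched-MPR table — linear wall stress within ~1.4% of the
reference pointwise at the max-diameter section, conventional off by ~32%.
Other subcommands: `tube-solve`, `residual`, `make-geom`, `fea-solve`,
`sweep`, `compare` (see `wallstress --help`).

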