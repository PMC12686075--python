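# archstent

Virtual bare-metal stenting of a residually dissected aortic arch:
stent-deployment mechanics and pulsatile true/false-lumen hemodynamics,
at desk scale, in pure scientific Python.

After a hemiarch repair of a type A aortic dissection, a residual intimal
flap keeps separating a narrowed true lumen (TL) from a pressurized false
lumen (FL) in the arch and descending aorta. Placing an uncovered
self-expanding Z-stent in the true lumen pushes the flap back toward the
wall and is thought to restore healthier hemodynamics. This package
rebuilds that in-silico study end to end with a parametric synthetic
anatomy in place of the (non-public) patient CT:

* **synthetic anatomy** — curved arch with three branch vessels, a
  hyperelastic-scaled dissection flap dividing TL and FL, ground-truth
  centerlines, volumes and inscribed diameters;
* **stent model** — sinusoidal nitinol rings (9 rings, 185 mm) drawn flat,
  wrapped to a cylinder, joined by tension-only sutures;
* **deployment** — radial crimp by a kinematic crimper to the TL
  inscribed-sphere diameter, point-by-point centerline alignment
  `P_i(k) = R_i (i <= k), R_k + T_k (i-k) ds (i > k)`, and passive
  self-expansion against the rigid wall and the elastic flap, for flap-to-
  wall stiffness ratios 1, 0.1 and 0.01 (chronic to acute);
* **radial force** — paired-simulation subtraction (stent+crimper minus
  crimper alone), normalised per unit length; the wire radius is
  calibrated so the force at 30 mm diameter is 1.7 N/mm;
* **hemodynamics** — D3Q19 lattice-Boltzmann flow with the five-harmonic
  cardiac inlet-velocity series (mean 0.4248 m/s, base frequency
  14.77/2 rad/s) and constant 100 mmHg or oscillating 120/80 mmHg
  outlets, three cycles with the third analysed;
* **postprocess** — 20 TL/FL-separated slice profiles along the aorta,
  4 slices per branch vessel, pressure-gradient and remodeling summaries.

The wall and flap follow the Raghavan–Vorp strain energy
`W = C10 (I1 - 3) + C20 (I1 - 3)^2` (wall: C10 = 0.174 MPa,
C20 = 1.881 MPa; the flap scales both constants by the stiffness ratio);
nitinol and steel are linear elastic (83 GPa / 0.33 / 6450 kg/m^3 and
210 GPa / 0.3 / 7850 kg/m^3). See `docs/methods.md` for the full model
description, defaults and limitations.

## Worked example

```python
from archstent.anatomy import (AnatomyConfig, build_dissected_aorta,
                               largest_inscribed_sphere_diameter, lumen_volumes)
from archstent.deployment import deploy_in_anatomy, radial_force_profile
from archstent.materials import AORTIC_WALL, scale_flap_stiffness
from archstent.stent import DEFAULT_DESIGN

aorta = build_dissected_aorta(AnatomyConfig())
print(largest_inscribed_sphere_diameter(aorta))   # 11.79 mm crimp target
print(lumen_volumes(aorta)["FL"])                 # 20377 mm^3 false lumen

print(radial_force_profile(DEFAULT_DESIGN, [30.0]).at(30.0))   # 1.70 N/mm

state = deploy_in_anatomy(aorta, DEFAULT_DESIGN,
                          scale_flap_stiffness(AORTIC_WALL, 0.01))
print(state.tl_min_diameter, state.fl_volume, state.von_mises.max())
```

With the default (acute, ratio 0.01) flap the narrowest true lumen opens
from ~11.8 mm to ~23 mm, the false-lumen volume drops by several tens of
percent, and the peak beam stress lands in the 1300–1950 MPa range —
above the 1000 MPa nitinol surrogate, a consequence of holding a 36 mm
device inside a 12 mm synthetic channel (see the known-limitations note
in `docs/methods.md`).

The full study (baseline + three stiffness ratios, flow, tables, report)
runs from the command line:

```sh
archstent run-all --out study_out --seed 1
```

which writes STL/VTK geometry products, `radial_force.csv`, per-slice CSV
tables, `remodeling_summary.csv` and a Markdown report.

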