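# Methods

`archstent` simulates bare-metal stenting of a residually dissected aortic
arch at desk scale: a synthetic dissected-arch anatomy stands in for a
patient CT segmentation, a parametric Z-stent is crimped, steered onto the
true-lumen centerline and released against the wall and the dissection
flap, and the resulting lumen geometries are run through a pulsatile
lattice-Boltzmann flow model. This note records the models, the defaults
and the reasoning behind the genuinely open design choices.

## Synthetic anatomy

The arch is a tube of circular cross-section swept along a planar
centerline (straight ascending segment, semicircular arch, straight
descending segment; `arch_radius = inf` degenerates to a straight tube).
Frames along the centerline are rotation-minimising; on the arch the first
frame vector `e1` points at the arch center (the inner curvature), and the
true lumen sits on that side by default.

Within the dissected extent every cross-section carries a circular-arc
flap chord attached to the wall at `±theta_att` about `e1`, bowing to an
apex positioned so the open true-lumen channel is exactly
`tl_min_diameter` wide at the plateau. The flap pinches onto the wall over
a smooth taper at both axial ends, closing the false lumen. Defaults are
sized to an adult arch: wall inner diameter 30 mm, arch radius 40 mm,
ascending/descending segments 60/120 mm, TL minimum diameter 12 mm, flap
thickness 2 mm (imaging-resolution scale; not reported for this device
class), angular extent 160 deg, axial extent 45–65 % of the centerline
(so the 185 mm device placed 14 mm from the root covers the dissection)
(the ascending segment is undissected, emulating a post-hemiarch state).
Three branch vessels (10/8/8 mm) leave the outer curvature proximal to the
dissection; placing the dissection distal to the ostia avoids modelling
branch malperfusion, which is out of scope.

Region measures run on two independent routes: 2-D cross-section polygons
(areas, centroids, maximum inscribed circles via pole-of-inaccessibility)
integrated along the arc with the exact curved-tube Jacobian
`1 - kappa * x_e1`, and closed lofted triangle meshes whose signed volumes
are evaluated with trimesh. The two routes agree to well under 1 % and are
cross-checked in the tests. The crimp target of the deployment is the
largest inscribed sphere of the TL: the minimum over TL-centerline points
of twice the in-plane distance to the TL boundary.

What the generator does *not* emulate: non-circular wall cross-sections,
re-entry tears (deliberately absent), tapering branch anatomy, wall
motion. Passing tests on this geometry therefore validate the machinery
and the qualitative flap-stiffness physics, not patient-specific
magnitudes.

## Stent model

Each support ring is a sinusoid `z = z_c + a sin(p s)` drawn flat and
wrapped isometrically onto the design cylinder. Defaults: 185 mm total
length, 9 rings, 9 peaks per ring, inter-ring gap 4 mm (amplitude solved
from the layout, 8.5 mm), nominal free diameter 36 mm (typical for this
device class and larger than the 30 mm wall, so the deployed stent stays
compressed). The peak count is chosen so that uniform sampling places
nodes exactly on the sinusoid extrema for both the default (72/ring) and
the fine (900/ring) discretisations; that makes the built axial extent
exactly 185 mm. Sutures join each ring's peaks to the circumferentially
nearest valleys of the next ring as tension-only springs (5 N/mm tensile,
zero compressive — a soft polymer-thread scale).

The wire radius is not reported for this device; it is calibrated once so
the paired-simulation radial force at 30 mm outer diameter is 1.7 N/mm
(the bench anchor for this stent), giving r = 0.4554 mm at the default
discretisation and crimp schedule. All structural results use this calibrated default.

## Structural solver

The wire is a chain of axial springs (EA/L) and hinge bending springs; the
flap shell is a grid of membrane springs (stretch + diagonal shear) and
hinge rows, with membrane stiffness `E_f t` and bending stiffness
`E_f t^3/12` from the scaled small-strain Raghavan–Vorp modulus
`E_f = 6 C10 * ratio`. Bending uses the discrete-rod curvature-binormal
energy `E = (k~/2) |kb - kb0|^2`, `kb = 2 (e1 x e2)/(|e1||e2| + e1.e2)`,
which is smooth in the node positions and penalises concave/convex flips
of a naturally curved wire (a plain unsigned hinge angle admits
zero-energy zigzag modes and spurious equilibria — the pinched-ring oracle
exposed exactly that failure). Rest-curvature directions co-rotate with
the wire between load increments; flap hinges keep fixed references (the
local axial tangent across the chord, `e2` along the axis) so a flap
section flipping through flat is penalised consistently.

Equilibria are found by direct energy minimisation (L-BFGS with analytic
gradients, Jacobi preconditioning including contact penalty stiffness,
restart chunks with a backtracking-descent rescue). This replaces the
originally planned explicit pseudo-time relaxation, which showed false
convergence on these stiff EA/EI networks; the monotone decrease of the
energy over accepted steps is retained and tested. Convergence demands a
projected residual below `2e-3` of the largest member force; oracle tests
run at `1e-4`.

Contacts are node-level penalties (default stiffness `100 * 3EI/l^3` of
the wire) with elastic-slip Coulomb friction, coefficient 0.1 on all
pairs; anchors, force caps and contact normals are frozen per load
increment so the friction energy has an exact gradient. The four pairs
are stent–crimper, stent–wall, stent–flap and flap–wall; the crimper
never contacts the wall. The aortic wall is rigid; the flap deflects
along the local `e1` (push) direction, its attached edges fixed to the
wall. The stent–flap pair works per cross-section against the flap
polyline as a graph `x(y)`; the barrier extends to the wall attachments so
wire nodes cannot slip around the flap edge into the false lumen.

Deployment phases: (1) radial crimp by a kinematic cylindrical crimper
(radius ramped in ~16 increments; proximal-ring extrema held axially;
per-ring mean-position regularisation removes rigid sliding modes), down
to the TL inscribed-sphere diameter with no extra margin; (2) kinematic
point-by-point alignment of the crimper centerline onto the TL
centerline — every cross-section moves rigidly (translation to the target
point plus the minimal rotation between old and new tangents, with the
deterministic anti-parallel tie-break), which preserves crimper
circularity to machine precision; the stent is placed 14 mm from the
aortic root; (3) crimper radius growth in ~24 increments, stent–crimper
contact dropped once the crimper clears the largest lumen radius, damped
equilibration against wall and flap, with the first-ring peaks confined to
the plane normal to the local centerline tangent. A weak tangent-hold
spring (0.05 N/mm per node) stands in for the axial grip of friction.

Radial force uses the paired-simulation subtraction: total radial crimper
reaction with the stent minus the empty-crimper reaction (identically zero
for a kinematic tool), normalised by the 185 mm stent length. Before each
recorded diameter the friction anchors are refreshed and the state
re-equilibrated (a friction-neutral hold), which makes the measurement
independent of the crimp schedule to better than 1 %; without the hold the
reading carries the tangential stick history of the loading increments.

Beam stress is the outer-fiber Euler–Bernoulli surrogate
`sigma = E (|eps_axial| + |dkappa| r_wire)` with `|dkappa|` the full
curvature-vector change (zero-twist assumption; torsion is not modelled,
so bending-plane rotation is charged as bending — a conservative upper
bound). The narrowest-TL metric after deployment is taken over the
stented axial extent (14–199 mm), matching the notion of the treated
segment's narrowest point; the flap distal to the stent rocks slightly
into the TL, which is physical but not part of that metric.

Known limitation: with the default 12 mm synthetic TL and the calibrated
wire, the deployed crown curvature reaches ~0.05/mm and the peak fiber stress
1300–1950 MPa — above the 1000 MPa nitinol ultimate surrogate. The bound
is geometry-bound: a 36 mm device held at ~12–21 mm sustains ~1.8 % fiber
strain, beyond the linear-elastic envelope. The stress *ordering* across
flap stiffness (stiffer flap, higher stress) does hold.

## Hemodynamics

D3Q19 single-relaxation-time BGK on a uniform voxel lattice, half-way
bounce-back walls, Zou-He (non-equilibrium bounce-back) velocity inlet at
the aortic root, equilibrium pressure outlets at the celiac level and the
three branch tips. The inlet follows the printed five-harmonic velocity
series (mean 0.4248 m/s, base angular frequency 14.77/2 rad/s); outlets
are either constant 100 mmHg or the printed oscillating 120/80 mmHg
series, applied jointly to all outlets. Three cardiac cycles are run and
the third analysed; cycle-2 vs cycle-3 slice means differ by < 1 % at the
default settings.

Unit mapping: dt follows from the lattice Mach scale (`u_lat_peak`,
default 0.05–0.08 at the inlet peak), and the relaxation time tau sets the
lattice viscosity. At desk-scale grids (dx = 1.5–2.5 mm, tau = 0.55–0.8)
the effective kinematic viscosity is orders of magnitude above blood's:
runs are deliberately Reynolds-scaled (effective Re of order 10–100
instead of ~3000), which preserves the laminar pressure-gradient and
velocity-redistribution trends across configurations but inflates viscous
pressure-drop magnitudes; `FlowField.info` reports the scale. Blood is
Newtonian (1060 kg/m^3, 3.5 mPa s — not reported, standard values), walls
rigid, and the stent wires are excluded from the fluid domain (the flow
geometry is the deformed wall + flap surface only).

Voxelization classifies cell centers with the anatomy's analytic regions
(flap-solid cells are walls; TL/FL labels propagate to the postprocess),
flags one-cell inlet/outlet caps inside the cut planes, and removes fluid
pockets not connected to the inlet.

## Postprocess

Aortic profiles use 20 slices of equal arc length between the root and
the celiac plane (the spacing rule is not prescribed; equal arc length is
the natural choice), branch profiles 4 slices per branch; means are
area-weighted over the fluid cells of each slice and region (equal-volume
cells, so cell averaging equals area weighting per slice), with empty
slices flagged missing rather than zero. Systole/diastole are the
argmax/argmin of the inlet waveform within the analysed cycle. The
pressure-gradient metric is the TL mean pressure of slices 1–3 minus
slices 18–20 at systole. The remodeling summary tabulates FL volume
(percent change against the non-stented model), narrowest TL diameter,
maximum flap displacement and maximum stent stress per stiffness ratio.

## Problem sizes

Default desk-scale sizes, chosen as the package's working resolution:
72 beam elements per ring (648 wire nodes; the 8100-element mesh of the
convergence-grade discretisation is available via `with_resolution(900)`),
flap shell ~31 x 15 solver nodes (every second anatomy row), ~16 crimp and ~24 release
increments, lattice spacing 2 mm (~27k fluid cells, ~6,300
steps/cycle, 3 cycles). One full study (three deployments plus four flow
solutions) runs in roughly 15 minutes on one CPU core.

## Reproducibility

All geometry is deterministic in the configuration; the single
`random_seed` is threaded through the pipeline (no stage currently draws
random numbers, so re-runs are bit-identical at the table level).
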