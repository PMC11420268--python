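# Methods

## Scope and model

`laaoflow` studies how occluder family (plug vs disc) and position (ostial,
deep, tilted) change surrogate markers of device-related thrombus in a left
atrium under atrial fibrillation. The chain is: parametric anatomy →
geometric virtual implantation → incompressible laminar pulsatile flow →
passive "old blood" tracer → wall and volume markers. Everything is
deterministic: there is no random number source anywhere in the pipeline,
so a fixed configuration reproduces every number bit-identically.

## Synthetic anatomy

The blood pool is an implicit solid: an ellipsoidal atrial body (default
semi-axes 24 × 21 × 19 mm, ≈ 76 mL total pool with appendage and tubes — a
moderately dilated AF atrium), four pulmonary-vein inlet tubes (radius 6 mm,
length 30 mm), one short mitral outlet tube, and a tapered blind appendage
(LAA) attached through a circular 24 mm ostium. The appendage lumen narrows
quickly behind the ostium (neck drop 1.3 mm with a 2 mm e-folding scale)
and then tapers linearly, so that a 24 mm plug seats at the ostium with
11.5% compression and a 21.6 mm plug seats 16 mm deep with 8% compression —
both inside the clinical 8–20% release window. The appendage axis points
antero-laterally between the left upper pulmonary vein (whose rim provides
the LUPV ridge anchor) and the mitral outflow, so the fixed 40 mm ROI
sphere centred on the ostium midpoint overlaps the mitral approach flow.

Two choices deserve emphasis:

- **Outlet size.** The outlet tube is short (10 mm) and mitral-annulus
  sized (26 mm diameter). A 10 mm-diameter outlet cannot pass physiologic
  atrial throughflow at laminar Reynolds numbers; with the annulus-sized
  outlet the peak outlet Reynolds number is ≈ 1900, matching the laminar
  regime the study design assumes.
- **Straight appendage axis.** Clinical "LUPV ridge length" accumulates
  along the curved appendage wall. With a straight axis, ridge length and
  axial depth coincide, so the deep plug scenario seats 16 mm deep: deep by
  the > 10 mm rule, leaving a cul-de-sac, with the device's atrial face
  still inside the 40 mm ROI — the configuration whose hemodynamics the
  deep-implantation comparison is about. A 27 mm axial seat would push the
  device face outside the fixed ROI entirely, which is a property of the
  straightened geometry, not of deep implantation.

The solid is voxelized on a uniform Cartesian grid (cell-centre inside
test, staircase boundaries); tube end planes become inlet/outlet cap ghost
layers. A watertight triangulated surface for STL export is extracted by
marching cubes from the same implicit function. An `ImplicitSolid`/trimesh
adapter allows externally supplied surfaces to replace the generator.

## Virtual implantation

Devices are analytic solids in the placement frame. The plug (non-pacifier)
is a capped cylinder (deployed diameters 24.0/21.6 mm for labelled sizes
27/24, body length 20/18 mm) with a rounded atrial shoulder (radius 2.5 mm)
and a central cylindrical cove — the threaded-insert recess — of radius
4 mm, depth 3 mm. The disc (pacifier) is a 3.5 mm thick disc (32/28 mm for
labelled 25/22) with a 4 mm-radius insert protruding 3 mm into the atrium;
the distal lobe is sealed off from the blood pool and omitted. Cove,
shoulder and insert dimensions are package constants chosen to be plausible
for the device classes; manufacturers do not publish them.

Deployment is geometric: cells inside the device become device cells, and
wall cells within a 4 mm radial accommodation band may be displaced
(penalty-free dilation) so the device seats with contact. Fluid pockets
that lose face-connectivity to the outlet (the appendage distal to a seated
device) are frozen as stagnant: their pressure problem is singular and
their physical state is exactly stagnation, so they are excluded from the
momentum solve and hold tracer concentration 1.

The compression rate is evaluated from the analytic lumen profile at the
landing zone (5 mm behind the atrial face for the plug, mid-disc for the
disc), not from the voxelization, so it is resolution-independent; values
outside 8–20% raise a non-fatal release-criterion warning. For the
oversized discs pressed into the neck this warning is expected — clinically
the criterion applies to the (unmodelled) lobe.

Position metrics mimic the transesophageal measurement plane (the plane
containing the appendage axis and the LUPV anchor): LUPV ridge length is
the chord from the anchor to the device's atrial rim on the ridge side
(rim radius clamped to the accommodated lumen when buried), deep
implantation is ridge length > 10 mm, implant depth toward the MV is the
proximal rim protrusion past the ostium plane, and the device–ridge angle α
is measured against the in-plane ridge line taken parallel to the appendage
axis, so an untilted device reads 180° and the tilted scenario reads
166.4°.

The scenario suite comprises pre-occlusion plus eight occluded cases:
plug clinical (2 mm proud), ostial, tilted and deep; disc ostial and deep
for both sizes (deep disc seats at 10.1 and 15.5 mm). The tilted plug is
rotated 13.6° toward the mitral valve and displaced 8 mm into the
ridge-side accommodation band: an oversized plug in a convergent neck seals
at any pure tilt, so the lateral displacement is what leaves the
peri-device crescent channel on the mitral side — the leak morphology the
tilted configuration is meant to produce. Ostial discs are recessed 1 mm
into the ostium so the rim lands on the rim annulus; at voxel resolution
the two disc sizes then expose identical fluid-side geometry and differ
only in compression, which matches the near-identical ostial behaviour of
the two sizes.

## Flow solver

Incompressible Newtonian blood (ρ = 1060 kg/m³, μ = 3.5 mPa·s), laminar,
rigid no-slip walls. Discretization: uniform staggered (MAC) Cartesian
grid; fractional-step projection with explicit first-order upwind advection
and explicit diffusion (tangential wall neighbours enter by reflection, so
the discrete Poiseuille profile is exact); the pressure Poisson system
(Neumann at walls/inlets, Dirichlet 0 ghost at the outlet) is factorized
once per domain with sparse LU, driving the per-cell divergence to
round-off each step. Time step 0.005 s with CFL-triggered sub-stepping
(cap 0.7). Domains with a single cell in z run in plane-flow mode (used by
the channel benchmarks). Wall shear uses the one-sided gradient
τ_w = μ u_t/(h/2) from the first fluid-cell tangential velocity, exact for
linear shear.

Pulmonary-vein inflow is a parametric AF waveform: baseline 0.08 m/s plus
raised-cosine S and D waves (amplitudes 0.15 and 0.20 m/s, peaks at 21% and
62% of the 1.01 s cycle, widths 30%/34%), no atrial-contraction wave,
identical on all four veins. Published AF recordings motivate the shape;
the amplitudes were calibrated once so the ROI volume-averaged velocity
falls in the 0.04–0.07 m/s range of patient-scale studies while the peak
outlet Reynolds number stays ≈ 1900 (laminar). The mitral outlet is a
permanently open zero-gauge pressure outlet with zero-normal-gradient
velocity.

The reference protocol is 10 warm-up plus 6 evaluation cycles (202 steps
per cycle). Resolution tiers scale the study: `test` (2.0 mm, 2 + 2 cycles,
every 2nd step recorded; ≈ 10⁴ fluid cells, ≈ 40 s per scenario), the
package's default desk regime; `standard` (1.25 mm, 10 + 6) and `fine`
(1.0 mm) for longer runs. Evaluation-cycle counts and grid spacing are the
dominant cost knobs; all reported test-tier numbers state this scaled-down
regime.

## Tracer and markers

The "old blood" tracer starts at 1 everywhere at the beginning of the
evaluation cycles; inlets inject 0. Advection is conservative finite-volume
upwind with MUSCL/minmod limiting (monotone, globally conservative to
round-off; no molecular diffusion — numerical diffusion is bounded by the
limiter). φ is the concentration-weighted volume fraction (no binary
threshold; thresholding at 0.5 is available for visualization). The
washout half-time is the first linear-interpolated crossing of φ = 0.5,
censored if not reached inside the evaluation window and flagged on
re-crossing.

TAWSS/OSI/ECAP are integrated over the last stored cycle (trapezoidal;
integrating over all evaluation cycles is an option). The ROI surface is
the set of wall and device faces whose centroid lies in the ROI sphere and
outside the excluded distal appendage; averages are area-weighted, and both
tissue and device faces are included (separable via the `is_device` flag).
Faces whose TAWSS is at the numerical noise floor (≤ 10⁻⁶ Pa) are excluded
from ECAP statistics as 0/0 ratios. Vorticity is reported both as the ROI
volume average (1/s) and as the volume integral (m³/s), since both
conventions appear in the literature. Flux "into the appendage" is the
time-integrated positive volume flux across the plane one cell distal of
the device's closure surface (the ostium plane pre-occlusion); for a fully
seated device this is exactly zero because the distal compartment is
frozen.

## Verification

- Plane-Poiseuille wall shear within 5% (observed ≈ 1%) and Womersley
  oscillatory channel L2 velocity error < 5% (observed ≈ 2%) at test
  resolution.
- Marker kernels against closed forms (OSI limits, TAWSS of a sinusoid =
  2A/π, ECAP identity) and hand-worked area averages.
- Washout: single well-mixed compartment recovers t½ = ln 2 · V/Q within
  2%; a coarsely sampled two-compartment exchange curve matches the dense
  ODE solution; whole-domain φ is non-increasing in every scenario.
- Conservation: per-step global mass balance at solver round-off; closed-box
  tracer total conserved to 10⁻¹².
- Geometry: marching-cubes surfaces watertight; voxel volumes converge
  first-order to analytic solids; ROI masks equal brute-force sphere tests
  exactly.

What passing these tests does *not* show: agreement with patient-specific
anatomy. The generator has a convex smooth chamber, straight tubes, a
straight conical appendage and rigid walls; trabeculae, appendage lobes and
curvature, wall motion and mitral valve dynamics are absent. Marker
magnitudes at 2 mm resolution are therefore not clinical values — wall
shear is under-resolved (area fractions below the 0.36 Pa adhesion
threshold saturate near 1, and ECAP magnitudes are inflated by low TAWSS) —
but the *ordering* across device positions and families, which is the
study's object, is reproduced and is the tested claim.

## Known limitations

- Staircase walls: first-order boundary accuracy; wall-shear maps are
  trend-level only at the test tier.
- The tilted-plug leak morphology is constructed (tilt + lateral
  displacement), parameterized to the reported off-axis angle; a straight
  conical neck cannot produce a leak from tilt alone.
- Two evaluation cycles (test tier) leave φ far from its 6-cycle
  asymptote; half-times near the window edge may be censored.
- The disc's lobe, device anchors, fabric permeability and device motion
  are not modelled; the plug is impermeable from deployment onward.
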