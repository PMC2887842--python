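# Methods

`iesim` models intraurethral electrical stimulation (IES) of pudendal
afferent fibers in the male cat: a quasi-static volume-conductor solve of
the potential field produced by catheter-mounted electrode contacts, an
activating-function analysis along the two sensory pudendal branches (the
dorsal nerve of the penis, DNP, and the cranial sensory nerve, CSN), and
the selectivity experiments that compare electrode configurations and
stimulation sites.

## Volume conductor

The steady-state conduction problem is ∇·(σ∇V) = −s with isotropic,
piecewise-constant tissue conductivity σ and regulated current s on the
electrode contacts.  It is discretized by finite volumes on a graded
rectilinear grid: 0.5 mm cells throughout the tissue core, growing
geometrically (ratio 1.6, capped at 48 mm) toward the outer boundary.  The
face between two cells carries the series ("harmonic-mean") conductance of
the two half-cells, so current continuity holds across every tissue
interface and faces into the practically insulating catheter
(10⁻¹⁰ S/m) carry no current.  Exterior boundary faces are grounded
(V = 0) through a half-cell conductance, except the distal wall at the
meatus/prepuce end, which is insulated.  The resulting system is symmetric
positive definite and solved by Jacobi-preconditioned conjugate gradients
to a relative residual of 10⁻⁶ (argument-tunable; this is four orders of
magnitude below the 5% physical accuracy contract below).  Models and
sources that are mirror-symmetric about the midsagittal plane — all twelve
catalogue configurations at dorsal or ventral orientation — are solved on
the y ≥ 0 half-domain with an insulated symmetry plane and reflected.

A monopolar configuration returns its current through the grounded outer
boundary.  That return resistance converges slowly (~1/R) in the ground
distance, so the default bounding box is large (lateral half-width 350 mm,
proximal margin 250 mm, reached by a handful of coarse cells): with it,
doubling the box changes the maximum nerve-point potentials by < 4%,
satisfying the adopted model-adequacy contract (< 5% change under mesh
refinement near the electrode and under box doubling).
`AnatomyParams.desk_scale()` (120/80 mm) is provided for the sweep and
Monte-Carlo experiments; ratios, orderings and selectivity counts agree
with the far-ground model to three significant digits, and every
experiment records which scale it ran at.

Current injection: a metal contact flush on the insulating catheter
surface is represented by distributing the regulated current over the
tissue voxels immediately adjacent to the contact's patch of catheter
surface, weighted by exposed face area; multi-contact cathodes share the
current equally.  An equipotential (metal-conductivity) contact model was
tested and changes the reported quantities negligibly, because the
catalogue's multi-contact arrays are symmetric.

## Anatomy

The model spans the urethra from the external meatus (x = 0, mm,
increasing proximally) to 5 mm proximal of the prostate (x = 80).  The
source anatomy literature gives no printed dimensions, so all extents and
radii are explicit, overridable defaults chosen for an adult male cat:
a 2 mm urethral lumen filled by a flush catheter, inner and outer
urethral muscle layers to r = 2.2 mm, corpus spongiosum to 3.4 mm, the
paired corpus cavernosum as a dorsal wedge (±45°, to r = 5.2 mm, x < 48),
the prepuce as a distal sheath, ventral bulbospongiosus and
ischiocavernosus muscle at the penile bulb, a periurethral sphincter
sleeve (to r = 5 mm) along the membranous urethra, bulbocavernosus glands,
and the prostate.  Everything else is connective-tissue bath (0.05 S/m)
inside the grounded box.  Conductivities: muscle 0.291, erectile tissue
0.6, glands 0.4, connective tissue/bath 0.05, catheter 10⁻¹⁰, urine
1.55 S/m (all isotropic).

The catheter is flush with the lumen by default (the baseline contact
model assumes contacts sit on the urethral wall); the shrunk-catheter
study halves its diameter, and the freed annulus is then labeled urine.
A catheter thinner than the lumen always gets a urine annulus, which is
the only situation in which that compartment appears.

Electrode catalogue (twelve entries): 1 and 2 mm monopolar rings, short
(1 mm) and long (4 mm) half-shell sectors, narrow/wide bipolar sector
pairs, 1 and 2 mm bipolar ring pairs, and 3/5-contact and 3/5-ring arrays
at 3.5 mm centre-to-centre pitch.  Sector contacts are 180° half-shells:
the printed figures do not dimension the arcs, and at 0.5 mm voxels the
catheter surface carries only ~8 angular positions, so a 90° pad would
collapse to two voxels and exaggerate focality.  Sectors face dorsally
(toward the nerves) unless rotated.

## Nerve trajectories

Nerves are not part of the conduction domain; the solved field is sampled
along parameterized bilateral trajectories.  All trajectories run in the
dorsal periurethral fascial plane — the connective-tissue space outside
the tunica of the erectile bodies and outside the sphincter sleeve — as
the pudendal branches do anatomically.  This choice is also numerically
load-bearing: where a sampled path crosses a conductivity interface
non-tangentially, the axial field component jumps by the conductivity
ratio and the discrete second difference acquires an interface spike
~|∇V|/ℓ that can exceed the genuine far-field activating function by
orders of magnitude.  Confining each path to a single compartment removes
those spikes entirely rather than hiding them.

* DNP: from its distal terminal near the meatus (x = 2 mm, 6.4 mm from
  the lumen axis) dorsally along the penile body, rising gently to 7.0 mm
  at the bulb, truncated at x = 46.5 where the trunk leaves the model.
* CSN: from its terminal near the prostate (x = 78) along the membranous
  urethra at 6.2 mm from the axis, climbing over the bulb into the same
  dorsal corridor as the DNP and truncated at x = 34.
* The two trunks share the corridor over the penile bulb (x ≈ 34-46.5).
  This encodes their common neurovascular course there and is what makes
  stimulation at ~4 cm activate both branches at nearly identical
  strength — the anatomical reading of the observation that no
  configuration is selective at the penile bulb.
* Five lateral DNP branches leave the trunk at 14-26 mm (3 mm apart),
  wrap ventrolaterally around the penile body with a ~7 mm oblique axial
  run, dive past the edge of the erectile wedge between 45° and 75° from
  dorsal, and terminate ventrolaterally at 4.8 mm from the axis.  In the
  Monte-Carlo experiment each branch's axial position is jittered
  uniformly within ±10 mm (clamped to the penile segment, 3-37 mm) per
  trial; uniform is the least-informative bounded choice.

Waypoint polylines are resampled densely and Gaussian-smoothed (σ = 2 mm)
so that no bend is sharp on the internodal scale; a kink would otherwise
contribute a spurious curvature drive ~|∇V|·Δθ/ℓ.

## Sampling and the activating function

Potentials are sampled every 0.1 mm of arclength.  Sampling uses a
tricubic spline over the uniformly spaced fine core of the grid (where all
nerves live); trilinear interpolation is available, but its derivative
kinks at every cell face put a noise floor of ~|∇V|/ℓ under the second
difference, which matters wherever the true AF is small.  Tricubic
interpolation is C², exact on affine fields, and leaves the acceptance
oracle comparisons unchanged.

The activating function at interior nodes is the second central
difference of the extracellular potential at the internodal length
ℓ = 0.5 mm (5 μm myelinated fibers): AF_n = (V(s−ℓ) − 2V(s) + V(s+ℓ))/ℓ².
Depolarization is positive under cathodic stimulation, and "maximum AF"
is the maximum of the signed AF over nodes.  At the distal fiber terminal
the drive is the first difference (V₁ − V₀)/ℓ; when terminals compete
with interior nodes for the maximum, the terminal enters as the
sealed-end one-sided second difference (V₁ − V₀)/ℓ², which has interior
units and is the discrete cable end-node drive.  This is the single most
consequential convention in the package: the lateral branches owe much of
their advantage over the through-running trunk to terminal drive, which
is physically why terminated fibers near a field have low thresholds.
`terminal_mode="exclude"` is provided.  Truncated ends (where a trunk
leaves the model) get no terminal value — which also means the DNP's
maximum AF can be small or negative for stimulation far proximal of its
course, where only its hyperpolarized tail is in the field; the
selectivity quotient treats a nowhere-depolarized off-target as
infinitely selectable against.

Node placement repeats for five positions of the most distal node
(offsets 0-0.4 mm in ℓ/5 steps, commensurate with the sampling), and
maxima pool bilaterally: 10 ensemble members for a trunk pair, 5 for a
branch.  The ensemble SD uses ddof = 1.

Selectivity of target 1 over target 2 is S = (μ₁ − σ₁)/(μ₂ + σ₂) with
AFR = μ₁/μ₂; a configuration is deemed selective only when S > 1 and
AFR > 1.5.  Relative activation thresholds are inverse mean maximum AFs,
normalized so the lowest threshold is 1.

## Experiments

* Sweep: one solve per configuration (8) and site (1-7 cm); DNP, CSN and
  combined (per-cell maximum of the two) statistics, combined normalized
  by the global maximum.
* Selectivity map: DNP-vs-CSN over 1-5 cm and CSN-vs-DNP over 3-7 cm;
  the implication "S > 1 ⇒ AFR > 1.5" is recorded per cell, not assumed.
* Branch Monte-Carlo: 50 jittered placements (fixed seed; the same
  placements for every configuration), branch maxima rank-ordered per
  trial, rank-averaged across trials, and two counts of branches
  activatable before the trunk: a paired one-sided t-test at p < 0.001 of
  rank values against the trunk mean, and the S/AFR rule.  A count of k
  branches corresponds to (k − 1) × 3 mm of urethral length.
* Perturbations: the short sector rotated 180° to face ventrally at 2 cm,
  and the half-diameter catheter with urine-filled lumen at 2 and 7 cm.
* Convergence study: percent change of the maximum nerve-point potentials
  under local mesh refinement (half spacing near the electrode) and under
  bounding-box doubling, on the default model.

## What the synthetic world does and does not establish

All inputs are generated: the anatomy is parametric, its dimensions are
package defaults rather than measured geometry, and the nerve courses are
templates.  A green ordering or ratio therefore establishes that the
physics of the model — current spread in the layered conductor, proximity
of each nerve segment to each stimulation site, terminal drive of
terminated branches — produces the reported relationships; it does not
validate the absolute AF magnitudes (V/m²), which depend directly on the
unprinted dimensions.  Quantities that are ratios of the same nerve's
response under two configurations (threshold ratios, perturbation drops)
are robust to the dimension choices; quantities comparing different
nerves depend on the relative trunk offsets, which were chosen once and
documented above.  The known shortfall of the stated world is the
orientation study: with a 2 mm catheter flush in the lumen and the trunk
6.5 mm away, facing the sector away from the nerve costs ~50% of the
maximum AF rather than the ~30% reported for the original (thinner
catheter, different nerve clearance) geometry; the discrepancy scales
with the catheter-radius-to-nerve-distance ratio and is left visible
rather than absorbed into a dimension retune.

## Numerical choices

* CG relative residual 10⁻⁶, iteration cap 20 000; raises on
  non-convergence rather than returning a stale field.
* Discrete maximum principle: a purely cathodic source yields V ≤ 0 up to
  solver tolerance (asserted in tests).
* Volume fractions of every compartment change < 10% when the voxel edge
  is halved; catheter volume scales with diameter² within discretization
  error.
* Degenerate inputs rejected: all-insulated boundary with a monopolar
  source (singular), catheter wider than the lumen, voxels too coarse to
  resolve the catheter (> r/2), contacts past the catheter tip, profiles
  shorter than two internodal lengths.
* Ties and edges: branch jitter clamped to the penile segment; the five
  terminal offsets are exactly commensurate with the 0.1 mm sampling so
  no extra interpolation occurs at node positions.

## Known limitations

* Tissue is purely resistive and isotropic; no capacitive or interface
  impedance, no frequency dependence.
* The AF approximates relative thresholds only; no cable-model
  verification of activation.
* The pudendal trunks are truncated at the model edge, so their response
  to stimulation beyond their course is underestimated; branch urethral
  offshoots and the CSN's lateral branch are not modeled.
* A tensor-product grid cannot coarsen anisotropically around the tissue
  core; the resulting high-aspect outer cells are harmless for accuracy
  here but hurt CG conditioning, which is why the default far-ground
  model solves ~3× slower than the desk-scale variant.
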