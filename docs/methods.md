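# Methods

## Problem setting

The package estimates strain and stress of the superficial (luminal) layer
of a coronary artery wall from its observed motion across one cardiac
cycle. The input is a sequence of lumen geometries — an ordered 3D
centerline with one radius per centerline point and a cardiac-phase label
per frame — of which exactly one frame is diastasis (mid-diastole). Because
the ventricle is quiescent at diastasis, that frame is taken as the
zero-strain, zero-stress reference configuration; all cumulative quantities
are measured against it. Cross-sections are modelled as circles. This is a
deliberate idealization: it makes synthetic ground truth exact and matches
the diameter-based stenosis vocabulary of quantitative coronary
angiography, at the cost of ignoring lumen eccentricity.

## Geometry and meshing

Centerlines are resampled to L points equally spaced in arclength
(piecewise-linear interpolation, endpoints preserved). Ring orientation
uses rotation-minimizing frames computed by exact minimal-rotation parallel
transport of the normal pair along the tangent sequence; a Frenet frame
would spin about the tangent on helical segments and contaminate the
circumferential strain with spurious twist. Tangents are central
differences with third-order one-sided stencils at the ends. Node (i, j)
sits at c(sᵢ) + rᵢ(cos θⱼ n₁ᵢ + sin θⱼ n₂ᵢ), θⱼ = 2πj/C. Every mesh in a
sequence shares (L, C), so a node index is a candidate material label. The
default density for a 50 mm vessel is L = 101, C = 32 (≈0.5 mm axial
spacing, 0.3 mm circumferential at a 3 mm lumen), comparable to the spatial
resolution of angiographic reconstruction; both are configurable. A tube
whose radius exceeds the local radius of curvature self-intersects; this is
flagged with a warning rather than an error because the downstream algebra
remains well defined on the grid.

### Stenosis profiling

Percent diameter stenosis per ring is (1 − d/d_ref)·100, clipped at 0,
against a reference diameter interpolated linearly between the proximal and
distal healthy shoulders. Shoulders are detected as the nearest rings on
each side of the global minimum where the diameter recovers to ≥90% of that
side's segmental median, extended outward along the recovery slope to the
local diameter plateau; if the minimum sits at a vessel border the missing
shoulder degenerates to the minimum ring, which makes a gradual border
taper its own reference (0% DS) rather than a false lesion. Rings with
%DS > 20 are labelled stenotic. The threshold and the 90% recovery fraction
are configuration, not physics.

## Displacement mapping

With identical node dimensions, correspondence between consecutive frames
reduces to a re-parameterization of the tube surface: a global axial shift
δ (mm) plus a circumferential twist φ. The energy of a candidate matching is

- a deformation term: Mooney–Rivlin membrane energy density of each quad
  element under the matched correspondence, integrated over reference
  areas and normalized by (C₁+C₂)·(total area) to make it dimensionless —
  zero exactly when the matching is an isometry of the element edges;
- a kinetic-proxy term: mean squared *centered* displacement over nodes,
  normalized by the nominal diameter squared, weight α_k = 0.1. The mean is
  removed because bulk translation between frames is cardiac motion of the
  whole vessel and carries no correspondence information; penalizing it
  would pull the optimum away from zero-deformation matchings. What the
  term penalizes is motion heterogeneity, selecting the physically smallest
  motion among near-isometric matches.

Minimization is a coarse grid over all C twists × axial offsets within ±2
ring spacings (ties broken toward the smaller axial magnitude, then the
smaller twist index), followed by Nelder–Mead refinement of (δ, φ). A
refined point is accepted only if it improves the energy beyond a 1e-10
relative tolerance: along flat symmetry directions (twist of an
axisymmetric tube, axial shift of a uniform cylinder) the simplex would
otherwise drift on floating-point noise, and the tie-broken coarse point is
the correct answer. An exactly-zero coarse optimum short-circuits
refinement.

Two resampling details matter numerically. Circumferential linear
interpolation at fraction w of a node spacing contracts a circular ring by
|(1−w) + w·e^{i2π/C}|; uncorrected, an inflating vessel would reward
spurious half-node twists that partially cancel the inflation. The
resampled ring is therefore rescaled about its centroid by the inverse
factor (exact for circular sections). Axially, linear interpolation
low-passes the deformed surface and systematically lowers the apparent
deformation energy at fractional shifts; Catmull–Rom (cubic) interpolation
keeps that bias at fourth order, and linear extrapolation continues the
tube beyond its end rings.

Correspondence is propagated from diastasis pair-by-pair on the previously
matched configuration, making it transitive around the cycle. The cycle
closure residual — how far the composed motion misses the diastasis nodes —
is measured and reported, never corrected; on the synthetic conditions it
is at the 1e-8 mm level.

Known identifiability limits, inherent to any correspondence-from-geometry
method on a tube: a twist about the axis of a rotationally symmetric
vessel, and an axial translation along a featureless straight segment, are
unobservable; the kinetic term resolves them toward the smallest motion.
Similarly, rigid motions are recovered exactly only when the matching
family contains them exactly (e.g. twists by integer node spacings);
otherwise the piecewise interpolation caps accuracy at the chord-sampling
error (~1e-2 mm at C = 32). Nonuniform axial stretch cannot be represented
by a global axial offset at all — see the generator notes below.

### Held-out frame prediction

To predict frame k without using its geometry, the meshes adjacent to k are
matched directly and node positions are interpolated piecewise-linearly at
k's time fraction (frames are treated as equally spaced; the cycle wraps to
diastasis one step after the last frame). The predicted centerline is the
ring-centroid curve of the interpolated grid. Diastasis, being the
reference, cannot be held out.

## Strain and stress

Each quad element's in-plane deformation gradient F (2×2) is the
least-squares linear map sending the element's four reference edge vectors,
expressed in an element-anchored tangent basis, to the deformed edges; the
basis co-rotates under rigid motion, so strains are frame-indifferent to
machine precision. Principal stretches are the singular values of F
(closed form; λ₂ taken as det F/λ₁ so λ₁λ₂λ₃ = 1 holds to 1e-15). The
stretch-ratio construction means one step's strain is literally the element
length at the next time point divided by that at the previous one;
cumulative strain relative to diastasis (the default for reported maxima)
composes multiplicatively — two 6% inflation steps give 12.36%, not 12%.

Stress assumes an incompressible, homogeneous, isotropic Mooney–Rivlin
membrane in plane stress; eliminating the incompressibility multiplier
gives σ_k = 2C₁(λ_k² − λ₃²) − 2C₂(λ_k⁻² − λ₃⁻²), σ₃ = 0, and the von Mises
stress reduces to √(σ₁² − σ₁σ₂ + σ₂²). Stenotic element rows receive the
lesion composition's constants (an element row is stenotic if either
bounding ring is — shoulder elements belong to the plaque). Shipped
constants (kPa): normal C₁ = 18.9, C₂ = 2.75; fibrous 2×, calcified 10×,
lipid-rich 0.5× those values. These are placeholders in the physiological
range: published coronary constants vary by an order of magnitude across
protocols, so every conclusion the package draws from stress depends only
on ratios and orderings, never on absolute kPa. Through-thickness gradients,
anisotropy, residual stress and viscoelasticity are out of scope — the
"superficial wall" is exactly the membrane idealization of the luminal
layer.

Pulse stress is the per-element |σ_vm(end-systole) − σ_vm(end-diastole)|,
reported with the arclength of its maximum from the ostial (proximal) end.
Cycle summaries average over the non-reference frames and classify the
cycle-peak element against the lesion geometry: throat = minimum-diameter
ring ±1, shoulders = remaining stenotic rings on each side.

## Synthetic in-silico models

`make_stenosis_model` builds the idealized bench vessel: straight, 50 mm,
3 mm lumen, with a 10 mm concentric raised-cosine lesion reaching 50%
diameter stenosis at mid-vessel, and a 0.5 mm normal wall (EEM diameter
4 mm; the wall thickness is a modelling default, not a measured value).
Plaque burden — (EEM − lumen)/EEM volume over the lesion, by frustum
integration — is met exactly by solving a signed raised-cosine EEM offset;
remodeling applies a multiplicative trend to the reference EEM (0.95
negative, 1.00 none, 1.05 positive). With circular sections, a fixed lumen
and fixed wall thickness, burden and remodeling are geometrically coupled:
at a prescribed burden the offset absorbs the trend, so the pure remodeling
geometry is exposed through `solve_burden=False`, in which regime lesion
EEM equals / undercuts / exceeds the reference exactly as the remodeling
type says. Infeasible demands (wall thinner than a 0.1 mm floor) raise an
error naming the bound.

`generate_cardiac_sequence` imposes kinematic motion with per-phase weights
(0 at diastasis, raised toward end-systole: 0, 0.35, 0.8, 1.0, 0.45 across
the five standard phases — a smooth cycle shape chosen once, since no
waveform is prescribed by the physiology at this level of idealization):

- radial pulsation: peak fractional diameter change, default drawn from
  10–15%, the physiological range of coronary diameter variation under
  pressure pulsation;
- lesion attenuation of that pulsation: stiffer plaque pulsates less.
  Defaults per composition — calcified 0.02, fibrous 0.18, lipid-rich
  0.85 — scaled linearly with burden (normalized at 0.691), encoding the
  observation that softer plaque and larger burden show more lumen
  variation and, through the assigned material stiffness, higher
  superficial stress. The compliance mask edges are smoothed over 2.5 mm
  (several mesh rings, so the transition cannot alias under resampling)
  and saturate just outside the %DS > 20 boundary, so plaque material and
  plaque compliance cover the same rings;
- axial stretch about the proximal end and transverse Gaussian bending
  (peak added curvature = amplitude), both applied uniformly: the
  longitudinal stretch of an epicardial segment is imposed by myocardial
  tethering, not modulated by local wall stiffness — and, consistently, a
  global matching family could not represent a nonuniformly stretched
  correspondence anyway;
- rigid translation and rotation.

Ground truth is the material node grid per frame (torsion-free,
ring-following motion), so inter-frame true displacements telescope to zero
around the cycle by construction. Motion that would self-intersect the
surface raises an error naming the first offending frame. The validation
cohort draws plaque specs stratified over the 3×3×3
composition × burden × remodeling design and motion from the documented
ranges, all from one explicit seed; `bend_site="proximal_shoulder"`
concentrates a stronger, narrower bend on the proximal shoulder band for
peak-localization experiments.

What the generator does *not* emulate: eccentric lumina, non-circular
sections, bifurcations, reconstruction noise, frame-timing jitter, and any
fluid dynamics. Passing the synthetic suites therefore demonstrates that
the inverse machinery is correct and self-consistent under the stated
kinematics — not that it is robust to the imaging artifacts of real
angiography.

## Force-based comparator

The conventional direction is represented by a quasi-static axisymmetric
membrane: per ring, P·r_def = σ_θ·t_def with t_def = t/(λ_θλ_z), λ_z fixed
(default 1, tethered artery), solved by bracketed root-finding on λ_θ
(Brent, 1e-14 tolerance); a limit-point (no root below λ_θ = 3) raises an
error naming the ring and pressure. The reference configuration is the
diastasis geometry and the waveform is transmural pressure *increments*
above diastasis, matching the inverse method's zero-strain convention —
absolute transmural pressure and the unloaded configuration are
unknowable here and deliberately not modelled. Pressure can be calibrated
so the normal segment pulsates a requested fraction. In the thin-wall,
small-stretch limit the solver reproduces Laplace's law σ_θ = Pr/t within
2%, and an independent variational solve (strain energy minus pressure
work) reproduces the equilibrium stretch to 1e-8 — both are test oracles.
The closed loop (forward pressurized sequence → inverse pipeline) recovers
the normal-segment hoop stress to machine precision on straight vessels,
because the mapping's optimum is exactly the identity there; the 5%
acceptance margin covers less symmetric conditions.

## Procrustes scoring

Predicted and true centerlines (index-corresponded by construction) are
compared by full Procrustes superimposition: center both, standardize to
unit centroid size, rotate optimally (SVD; reflections excluded — anatomy
is chirality-preserving), scale optimally. Scaling = Σ adjusted singular
values (1 for congruent shapes, ≤1 always); dissimilarity = standardized
residual = 1 − scaling², bounded in [0, 1]. This convention is adopted
because it is bounded and matches the magnitude on which centerline
agreement is conventionally reported; near-collinear configurations get a
rank-deficiency warning but still solve. The cohort experiment draws one
random non-diastasis frame per sequence (seeded), predicts, scores, and
reports per-sequence values plus mean ± sd, with failed sequences listed
rather than dropped.

## Numerical defaults

| quantity | default | notes |
|---|---|---|
| mesh density | L=101, C=32 | ≈0.5 mm axial spacing on 50 mm |
| energy weights | α_d=1, α_k=0.1 | kinetic term centered |
| coarse axial search | ±2 rings, step 1 | plus all C twists |
| refinement | Nelder–Mead, ≤200 iter | xatol 1e-9, fatol 1e-16 |
| stenosis threshold | 20% DS | labels, material assignment |
| wall thickness | 0.5 mm | EEM 4 mm for 3 mm lumen |
| min wall floor | 0.1 mm | burden feasibility bound |
| pressure units | kPa internal | 1 mmHg = 0.13332 kPa at the CLI |

## Limitations

Beyond the scope exclusions above: strain accuracy is bounded by the
surface interpolation (chord error ~(2π/C)²r/8) and by the identifiability
limits of global matching; stress magnitudes inherit the placeholder
material constants and the membrane idealization; the peak-location
classifier presumes a single focal lesion; and the time axis is ordinal
(frames equally spaced), so no strain-rate quantities are offered.
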