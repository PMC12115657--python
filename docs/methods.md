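# Methods

## The measurement problem

Three 1.6 mm Kirschner wires are driven from the lateral cortex of the
proximal femur, up the neck, into the capital epiphysis.  Two quantities
matter: the *purchase* of each wire (axial length seated inside the
epiphysis) and whether any tip breaches the subchondral bone into the
joint.  The package compares a linear arrangement (wires stacked
proximal-to-distal) with a triangular one (wires clustered around the
thickest part of the epiphysis) on the same femur, specimen by specimen, as
a paired design.

## Synthetic anatomy

Real cohorts of immature canine CT scans are not distributable, so the
generator builds stylized femora with exact ground truth in a canonical
left-femur frame (+x cranial, +y medial, +z proximal; right femora are
mirror images, produced from the same random draws).

- **Capital epiphysis** — a spherical cap: an icosphere (subdivision 4,
  ~5000 faces) of radius `cap_radius` cut by the physeal plane so the cap
  height equals `cap_height`.  The flat cut is refilled by a centroid fan
  and labeled *physeal*; the dome is *subchondral*.  With zero surface
  noise, the inward-normal chord from the dome pole to the physeal plane
  has length exactly `cap_height`, and every other inward-normal chord is
  shorter (for an at-most-hemispherical cap, the chord from polar cosine
  `c` is `r − (r−h)/c`, increasing in `c`).  That makes `cap_height` the
  analytic ground truth for the thickness stage.
- **Distal margin trim** — an optional second cut (`distal_trim_offset`,
  default 0.75 mm in cohorts, off in the plain `FemurParams`) removes the
  cap beyond a plane parallel to the cap axis, offset distally along the
  physis.  Real epiphyses are thickest dorsocentrally and fall away
  quickly toward the distal physeal margin; a rotationally symmetric cap
  cannot express that, and without it the distal and proximal wires of the
  linear pattern would gain or lose purchase symmetrically.  The trim
  leaves the pole chord (and therefore the ground-truth maximum) intact;
  its cut face is part of the articular margin and is labeled subchondral.
  0.5–1.0 mm behaves equivalently; beyond ~1.2 mm the margin no longer
  reaches the distal linear wire and the arrangement difference washes out.
- **Femur remainder** — neck and shaft capsules plus a third-trochanter
  sphere, evaluated as an analytic signed distance field on a 0.7 mm grid
  and surfaced by marching cubes at level 0; the physeal-gap plane enters
  the SDF as an exact linear field, so the remainder stays a configurable
  0.01–0.1 mm (default 0.05 mm) clear of the epiphysis.  Defaults (neck
  radius 5 mm, shaft radius 7 mm, neck-shaft angle 135°, anteversion 15°,
  physis tilt 25°) are plausible for 10–50 kg immature dogs but are
  synthetic conventions, not validated morphometry.
- **Cohort sampling** — `cap_height ~ Normal(11.8, 2.0)` truncated to
  `(2 mm, 2·cap_radius − 0.5 mm)`, n = 16 by default; the other parameters
  get uniform jitter.  `cap_radius` is floored at `cap_height + 0.5 mm`:
  beyond a hemisphere, near-rim inward normals run almost parallel to the
  physis and their chords exceed the cap height, which would decouple the
  measured maximum from the generator's distribution.  All draws come from
  one `numpy` generator seeded by the cohort seed; per-specimen seeds are
  spawned below 2^31.
- **Voxelizer** — voxel centers inside any watertight surface receive
  1000 HU, the rest −1000 HU, via an even-odd ray-parity rule along grid
  columns (the grid is offset half a voxel so centers straddle axis-aligned
  faces).  This provides CT-like input for the segmentation stage without
  any scanner model: no noise, no partial-volume effect, no slice overlap.

## Segmentation

The bone window (226–3071 HU, both bounds inclusive) thresholds the volume;
26-connected components of at least `min_component` voxels (default 50) are
surfaced by marching cubes at the 0.5 level of the binary field, scaled to
millimetres.  The raw 0.5-level surface is the faithful boundary of a hard
threshold and is the default; optional Taubin smoothing
(`smooth_iterations`, default 15 in the volume-ingest pipeline) is applied
before thickness mapping because staircase face normals otherwise mislead
normal-based rays (see below).  The epiphysis/remainder split takes the
component containing a user seed point; bridged physes are out of scope —
supplying separately segmented masks is the supported fallback.

## Thickness mapping

Rays start at the barycenters of subchondral faces (largest faces first, up
to `n_samples`, default 800), offset 0.01 mm inside, and travel along the
exact inward face normal until the first mesh exit.  Two discard rules keep
the field honest:

- exits through a *subchondral* face are grazing chords that never reach
  the physeal side;
- exits at grazing incidence (`|d·n_exit| < 0.25`) skim the solid nearly
  parallel to the exit face; the chord length `height / descent` is
  hyper-sensitive to normal error in that regime, and on rough surfaces
  the exit label alone cannot reject such chords.

Vertex-normal smoothing of the ray directions was evaluated and rejected:
averaging across the sharp trimmed-margin crease (or the cap rim) tilts
directions off the articular tangent and launches multi-millimetre spurious
chords even on noise-free meshes.  Face normals are exact for the analytic
geometry; for marching-cubes surfaces the Taubin pre-smoothing restores
well-behaved normals.  On rough meshes the maximum is positively biased
(the max over many noisy chords); at the default zero-noise study
conditions it recovers the ground truth to ~0.01 mm.

Reported thickness is ray length plus the 0.01 mm inset.  The maximum is a
point estimate at a sample; exact ties are broken toward the area-weighted
centroid of the top-1% samples.  The number of rays and all thresholds are
configuration, not physiology: clinical thickness measurement is a manual
procedure with no canonical sampling rule to reconstruct.

## Wire planning

The central trajectory runs from the third-trochanter landmark through the
measured thickest point; a warning (not an error) is logged if it is not
simultaneously cranial, medial and proximal.  Offsets live in the plane
perpendicular to the trajectory, spanned by the projected proximal axis `u`
and the projected (orthonormalized) cranial axis `c`:

- linear: `+s·u, 0, −s·u` for wires 1–3 (proximal to distal);
- triangular: an equilateral triangle of *side* `s` centered on the axis,
  wire 1 proximal at circumradius `s/√3`, wires 2/3 at ∓120° toward ±c
  (craniodistal/caudodistal).

`s = 2 mm` is read as axis-to-axis distance: 2 mm centers with 1.6 mm wires
leave 0.4 mm of clearance, consistent with near-touching cylinders, and the
side-length convention makes triangular neighbor distances equal the linear
ones.  Each wire tip sits `tip_setback` (2 mm) short of the *last*
subchondral crossing of its line, measured along the wire axis — the
"last crossing" rule seats wires that traverse the physeal gap correctly
beneath the dome, and the axis-aligned setback matches how a surgeon backs
a wire out along its own track.  The entry is the first crossing of the
femur remainder (lateral cortex).  A line that misses the subchondral
surface marks the wire off-target and fails the pattern with the offending
indices; the pipeline flags such specimens and excludes them from the
paired statistics rather than aborting the cohort.

By construction the setback makes articular penetration impossible;
`detect_penetration` still measures tip overshoot past the subchondral
margin (boundary contact is not penetration, tolerance 1e-9 mm) as an
independent safety check.  In thin distal bone the intra-epiphyseal chord
can be shorter than the setback, leaving a wire with zero purchase — the
in-model analogue of the clinical failure mode that motivates the
triangular pattern.

## Purchase and statistics

Purchase sums the inside intervals of the entry→tip segment against the
watertight epiphysis (sorted line–mesh crossings plus a containment test at
the segment start); multiple intervals are summed although simple geometry
yields one.  Values are kept at full precision internally and rounded to
0.01 mm in reports.  The engagement ratio divides purchase by the maximal
epiphyseal thickness; oblique chords may exceed 1 and are logged.

Differences `d_i = p_i^tri − p_i^lin` are summarized per wire location and
cumulatively with medians and linear-interpolation quartiles.  The test
against zero is the exact one-sample Wilcoxon signed-rank: zeros dropped,
midranks for ties, two-sided p as the probability mass of `|W⁺ − m(m+1)/4|`
at least as extreme under all `2^m` sign assignments.  The null
distribution is computed by subset-sum dynamic programming over doubled
midranks — integer-exact and identical to full enumeration — with a
continuity-corrected normal approximation (flagged in the output) above
m = 25.  A two-sample rank-sum mode is provided for users who prefer the
literal reading of that test's name; both modes label themselves in the
output.  The cumulative report row averages purchase per wire but tests
the per-specimen cumulative differences.  No multiplicity correction is
applied.

## What the synthetic cohort does and does not show

Passing tests demonstrate that the geometry pipeline is correct against
closed forms and that, under anatomy with a thin distal epiphyseal margin,
the triangular arrangement gains most of its purchase advantage at the
distal wire — the qualitative mechanism of the in-silico comparison.  The
synthetic femora are stylized: no trabecular texture, no physeal curvature,
no cartilage, no scanner noise.  Absolute purchase magnitudes depend on
real anatomy, so no numeric agreement with clinical cohorts is claimed.
Problem sizes (16-specimen cohorts, 800 thickness rays, 0.5 mm voxel
round-trips) are the package's default study conditions and keep a full
cohort run around ten seconds on one core.

## Numerical choices

- Ray–triangle intersection: vectorized Möller–Trumbore in float64,
  barycentric tolerance 1e-9, duplicate hits within 1e-7 mm merged
  (shared-edge crossings are reported by both adjacent faces).
- Containment: even-odd rule along a fixed incommensurate direction.
- Determinism: identical config and seed reproduce every CSV/JSON artifact
  byte-for-byte (the run manifest, which records wall-clock time, is the
  one exception); STL export is deterministic.
- Degenerate inputs raise typed errors (`ParameterError`, `GeometryError`,
  `PlacementError` with the missed wire indices, `ConfigError` with an
  itemized problem list) rather than propagating NaNs.

## Known limitations

- The seed-point component split assumes the physis separates epiphysis and
  remainder at voxel resolution; the generator's sub-voxel gap does not, so
  the synthetic pipeline runs on meshes directly and the volume path is for
  ingested data with separable components (or separate masks).
- Thickness on unsmoothed marching-cubes surfaces is unreliable (staircase
  normals); the pipeline smooths by default, but the bias-variance tradeoff
  of smoothing iterations on real scans is not calibrated here.
- Wires are infinitely stiff line segments; bending, drill wander, and
  soft-tissue constraints are out of scope, as is any biomechanical
  strength claim.
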