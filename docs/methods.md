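# Methods

## Polymer model and units

Chromatin fibres are closed bead-spring chains in reduced units: the bead
diameter σ (= 10 nm, 400 bp of chromatin) is the length unit, kBT the
energy unit, τ = σ√(m/kBT) the time unit with bead mass m = 1. The force
field is the conventional non-crossing combination:

* **FENE bonds** along each ring, k = 30 kBT/σ², maximum extension
  R₀ = 1.5 σ, with the WCA term between the bonded pair (equilibrium bond
  length ≈ 0.97 σ). The bond diverges before two beads can slip past each
  other, so with excluded volume on the chain cannot cross itself — the
  premise all topology results rest on, and verified directly by the
  knot-conservation tests.
* **WCA (purely repulsive 12-6) excluded volume**, ε = 1 kBT, cutoff
  2^{1/6} σ, between non-bonded pairs. A pair is skipped when either bead
  carries the *phantom* flag: phantom segments model Top2B-mediated strand
  passage by simply letting other segments pass through.
* **Bending stiffness** is a harmonic-cosine term, default κ = 0 (fully
  flexible). The unknotting/decatenation mechanism does not depend on
  persistence length, so the flexible default is used throughout; κ is a
  config knob.
* **Confining wall**: harmonic inward restoring force beyond the sphere
  radius, k = 100 kBT/σ². Bead centres penetrate the wall by ≲ 0.15 σ at
  thermal energies; geometric analyses pad the container radius by 0.5 σ.

Integration is BAOAB-split velocity Langevin dynamics, dt = 0.01 τ,
γ = 1 τ⁻¹, T = 1 kBT. Long-run mean kinetic energy per degree of freedom
is within 2% of kBT/2. Thermal noise is generated per block from a
counter-derived PCG64 stream, so a run is bit-for-bit reproducible from
(system, parameters, seed) on one platform.

Two numerical safeguards matter for the active (extrusion) forces:

* **Velocity cap** (6 σ/τ): a freshly re-formed walk spring at its 2 σ
  formation length would otherwise drive beads at terminal velocity
  ~F/γ ≈ 50 σ/τ, outrunning both the neighbour-list skin and the WCA
  contact within one timestep. Thermal speeds are ~1.7 σ/τ, so the cap
  touches equilibrium dynamics with probability ~e^{-18}; it acts purely
  as a motor-jolt limiter. Equipartition and Einstein-diffusion tests pass
  with the cap active.
* **Displacement-triggered neighbour-list rebuild**: the pair list is
  rebuilt whenever any bead has moved half the skin (0.35 σ) since the
  last build, rather than on a fixed interval.

Overlapping beads (separation < 10⁻⁶ σ) produce a capped force and a
logged clash count, never a crash; the force-capped mode (cap 50 kBT/σ)
is also the soft push-off used whenever excluded volume is switched on
over an overlapping configuration.

## Extrusion mechanisms

**Cohesin handcuff** (single-TAD and three-TAD experiments). Two 7-bead
rings (FENE ring bonds; circumradius 1.152 σ for unit side) are built in
the planes normal to the fibre tangent at two adjacent chromatin beads, so
each is pierced exactly once, and are joined by two harmonic bonds between
neighbouring beads of each ring. Threading is verified geometrically after
a capped relaxation: |Lk(cohesin ring, chromatin ring)| must be 1 for
both rings (placement retries with rotated phase otherwise). Each ring
walks by three springs (K = 20 kBT/σ², rest length 1 σ) from its beads
{0, 2, 4} to the chromatin bead one position ahead of the embraced bead;
when all three have shrunk to 1.1 σ they are re-formed one bead
further (formation length ≤ 2 σ), and the anchor advances. The threshold
is geometrically attainable: the minimal simultaneous distance from beads
{0,2,4} to an embraced bead near their plane is ≈ 1.04 σ for a 7-ring of
circumradius 1.152 σ, so bonds "shrunk to about rest length" do occur.
A ring whose next bead carries the CTCF flag halts permanently; the other
ring keeps walking. The ring aperture (≈ 0.65 σ) passes one fibre strand
only, so entanglements cannot enter the extruded loop — this is tested as
an invariant (the virtually closed extruded arc stays unknotted).

**Migrating bond** (melt experiment). One strong spring
(K = 100 kBT/σ², rest length 1 σ) joins the loop anchors; whenever they
are within 1.2 σ, the bond moves to the next outward pair (per non-stalled
side) provided that pair is within 2.5 σ. Anchors stop at CTCF beads and
at the edge of phantom segments, and when they meet. This mechanism does
not physically seal the loop, so entanglement exclusion is statistical
here, not an invariant — the melt acceptance checks are correspondingly
statistical over seeds.

## Knot and link analysis

Knot identification follows the standard trajectory-analysis pipeline:

1. **KMT simplification**: vertices are removed in random order whenever
   the triangle spanned with their neighbours is pierced by no other
   segment (exact segment-triangle tests; coplanar and grazing contacts
   are treated conservatively), iterated to a fixed point. This preserves
   the knot type; the suite checks Alexander-polynomial invariance on 100
   random closed walks.
2. **Projection** along a generic direction (perturbed on degeneracy) into
   an oriented Gauss code with over/under from depth and right-handed
   crossing signs, then **Reidemeister I/II reduction** to a fixed point.
   Candidate directions are the curve's three principal axes plus seeded
   random units (10 total): symmetric knots — torus knots in particular —
   project near-minimally along their symmetry axis, so the principal axes
   make the minimal diagram reproducible. The minimal reduced diagram over
   all directions supplies the crossing estimate (an upper bound on the
   crossing number).
3. **Alexander polynomial** from the Wirtinger crossing matrix: the
   (n−1)-minor determinant over ℤ[t] is evaluated exactly at integer
   points (fraction-free Bareiss) and interpolated, then normalised to
   lowest degree 0 and positive leading coefficient. The knot determinant
   is |Δ(−1)|. For diagrams above 16 crossings only the determinant is
   computed (a single integer determinant); such knots are unclassifiable
   anyway.
4. **Naming**: (polynomial, determinant) lookup in a bundled prime-knot
   table (all primes through 8 crossings plus the torus knots 8_19, 9_1,
   10_124); composite candidates by exact polynomial factorisation into
   table entries, flagged as heuristic. Hypotheses requiring more
   crossings than the crossing estimate are excluded — this is how the
   granny knot (3_1#3_1, 6 crossings) is separated from 8_20, which shares
   its Alexander polynomial. Ambiguous matches return a candidate list;
   diagrams still above 12 crossings are "unclassified" with invariants
   recorded. Alexander invariants are achiral, so mirror knots are never
   distinguished.

Catenation uses the exact Gauss linking number for polygonal curves
(signed solid angle of the endpoint quadrilateral, summed over segment
pairs — no simplification needed), cross-checked in the tests against an
independent projection crossing-count oracle. Two rings are catenated when
|Lk| > 0; Whitehead-style links with Lk = 0 are not counted, which is the
standard (slightly conservative) convention.

## Voronoi demixing measure

The confining sphere is tessellated around every bead. The spherical wall
is realised with ghost points: each bead within 3 σ of the wall is
reflected radially across the sphere surface, and 2000 quasi-uniform
(Fibonacci) tangent points each contribute the reflection of the locally
nearest bead across the tangent plane. Every boundary cell is then clipped
by planes tangent to the sphere, so the union of cells is a polyhedron
circumscribing the sphere; summed cell volumes match the sphere volume to
~3/K ≈ 0.15–0.2%, and the 0.5% volume-conservation invariant is asserted
on every analysed frame. Cell volumes come from facet-pyramid
decomposition around each generator. The inter-chain interfacial area
sums facets whose beads belong to different rings (each once, wall facets
excluded); per-ring envelope areas are accumulated in the same pass, so
Σ envelopes = 2 × total holds exactly. Beads are points (standard, not
radical, Voronoi) — correct for monodisperse beads. The wall
discretisation is fixed in space, so a plain rigid rotation reproduces
areas to ~10⁻⁵ relative; co-rotating the wall directions (exposed as a
parameter) gives exact equivariance, and both are tested.

## Synthetic configurations

* **Torus-knot rings**: arc-length-resampled (p,q) torus curves, rescaled
  to bond length 0.97 σ. (2,3) is the trefoil input; (3,7) the
  14-crossing complex knot; (1,q) the unknotted control. gcd(p,q) ≠ 1 is
  rejected (it would be a link).
* **Single TAD**: 133-bead knotted ring; border at bead 0 with a 5-bead
  phantom segment flanked by 2 CTCF beads on each side; the extruder loads
  at bead 66, equidistant from both borders along the contour.
* **Three TADs**: 400-bead ring laid out as one large trefoil, three
  equally spaced borders (same 5+2×2 layout), extruders mid-TAD. The
  construct is deliberately unequilibrated before extrusion so the
  delocalised knot spans all three TADs.
* **Confined melt**: 8 rings × 300 beads (desk scale; bead count is a
  config knob, 4000 at paper scale) in a sphere sized by
  R = (n/(8φ))^{1/3} for volume fraction φ = 0.30. Phase 1 marks every
  bead phantom and runs 160 000 steps (1600 τ) of Langevin dynamics,
  extended in windows while a chi-square comparison of the per-ring
  knot-determinant spectrum between successive windows still detects
  drift. Phase 2 restores excluded volume via capped push-off. The
  equilibrated melt is returned with a topology report (knot name per
  ring, linking matrix). At φ = 0.30 an unstretched 300-bead circle cannot
  fit the sphere, so the construction starts from radially compressed
  circles whose bonds relax in phase 1; the construction-topology control
  (phase 1 skipped ⇒ everything trivial) is exercised in the dilute
  regime where unit-bond circles fit and push-off provably does nothing.

## Experiments and problem sizes

The three drivers alternate MD chunks with extruder updates (walk attempts
every 40 steps / migrations every 25 steps — several spring relaxation
times apart) and sample knot type, extruder state and (for the melt) the
Voronoi area every 20 000 steps. Step budgets are 4×10⁵ (single TAD),
6×10⁵ (three TADs) and 4×10⁵ (melt extrusion) — runs typically finish
well within them and stop early once extrusion is complete and the ring
is unknotted. The melt analysis runs at 8 × 300 beads; this keeps every
statistical acceptance check (10-seed single-TAD and three-TAD unknotting
rates, 5-seed melt decatenation/demixing) reproducible on a single CPU.
The desk scale preserves the volume fraction, border layout and mechanism
but shortens ring length ~13-fold, so the melt starts less deeply
entangled than at paper scale (≈10 linked pairs rather than every ring
catenated with ≥3 others); the claims tested at this scale are the strict
decreases in linked pairs and interfacial area, not complete decatenation.

## Parameter choices at paper gaps

| parameter | value | rationale |
|---|---|---|
| bond style | FENE 30 kBT/σ², R₀ 1.5 σ | conventional non-crossing combination |
| bending κ | 0 | results persistence-length independent |
| dt, γ, T | 0.01 τ, 1 τ⁻¹, 1 kBT | standard stable choice |
| walk replace threshold | 1.1 σ | "about rest length"; attainable since the 7-ring geometry allows ≈ 1.04 σ |
| migration proximity | 1.2 σ | "brought close together" |
| phantom segment | 5 beads | short section, ≳ one passage site |
| CTCF flank | 2 beads each side | minimal robust stop |
| walk attach beads | {0,2,4} of 7 | three nonconsecutive ring beads |
| melt equilibration | 160 000 steps + stationarity windows | knot-spectrum chi-square across windows |

## What the synthetic data does and does not show

All inputs are generated: parametric knots, layout-flagged rings, and a
phantom-equilibrated melt. They emulate the *topological* content of the
study systems — knot type, catenation, crowding at 30% volume fraction,
TAD borders as stop/passage elements — but not sequence-specific CTCF
orientation, cohesin loading/unloading kinetics, nucleosome-scale
structure, or Hi-C-derived conformations. Passing tests therefore show
that the extrusion mechanism unknots/decatenates/demixes *this class of
coarse-grained models*, with statistics quoted per seed count at desk
scale; they do not calibrate rates or time scales for real chromatin.

## Known limitations

* Knot names are limited to the bundled table (≤ 8 crossings + three
  torus knots); denser equilibrated rings report "unclassified" with
  invariants, as knot tables themselves do beyond 12 crossings.
* Composite detection by polynomial factorisation is a flagged heuristic;
  Alexander-equivalent pairs are returned as candidate lists.
* The crossing estimate is an upper bound from simplification, not a
  certified minimal crossing number.
* The migrating-bond extruder can transiently admit entanglements into
  its loop (see above); only the handcuff guarantees exclusion.
* Linking-number-0 links (e.g. Whitehead) count as uncatenated.
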