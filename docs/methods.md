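# Methods

## Physical model

The esophageal wall is modelled as a straight, axisymmetric tube of two
concentric isotropic tissue shells around a non-conducting lumen, embedded in
an unbounded homogeneous surround:

| compartment | thickness (mm) | σ (S/m) | note |
|---|---|---|---|
| mucosa | 0.85 | 0.05 | equivalent conductivity of mucous membrane + muscularis mucosae |
| muscle | 2.72 | 0.53 | circular + longitudinal muscle treated as one shell |
| surround | ∞ (truncated) | 0.27 | serosa and lung, one equivalent medium |

The stimulus is a train of five 1 ms constant-current pulses at 200 Hz.  The
tissue conductivities are flat below ~100 kHz, so each pulse is treated as a
DC problem: capacitive and dispersive effects are neglected and the potential
obeys ∇·(σ∇V) = 0 with current entering the tissue only through the
electrode contacts (quasistatic volume conduction).  Sensory afferents are
assumed recruited wherever |E| = |∇V| exceeds a threshold, 20 V/m by default
(the action-potential threshold of a nonspecific nerve fibre); 3 and 100 V/m
are provided as alternates to bracket the sensitivity of the recruited-volume
picture to that choice.  Only the field magnitude is thresholded; fibre
orientation is not modelled.

No psychophysical model is fitted: the sensation (ST) and pain (PDT)
calibration currents bundled with the six scenarios are simply tabulated
against the computed field volumes.

## Electrode model

Contacts are ideal-metal equipotential surfaces (stainless-steel electrodes
are effectively perfect conductors at tissue impedances): all contact nodes
are condensed onto a single floating potential carrying a prescribed total
current ±I.  This is materially different from a uniform-current-density
patch — the true current density diverges like 1/√d at the contact edge —
and it is the physically faithful contract for metal electrodes.  No
electrode–electrolyte interface impedance is modelled.

Contact footprints live on the inner (mucosal) surface and are defined in the
developed coordinates of that cylinder (the cylinder is developable, so
planar areas are preserved):

* **ring, circular apposition**: disc of radius 1.5 mm (round lumen
  cross-section).  The catheter radius is likewise 1.5 mm, inferred from this
  footprint.
* **ring, elliptical apposition**: ellipse with semi-axes 0.7 mm (axial) ×
  7.5 mm (circumferential), the footprint seen when the catheter lies in a
  collapsed slit-like lumen.  On the 1.5 mm catheter the 7.5 mm semi-axis
  exceeds the half-circumference (4.71 mm), so the footprint wraps into a
  closed band of axially varying width — the limiting "full ring contact"
  case.  The bundled 2 mm-spacing scenario uses this footprint: two 1.5 mm
  discs cannot sit 2 mm apart centre-to-centre.
* **patch**: square of side √π·1.5 ≈ 2.66 mm, chosen so its area equals the
  circular ring contact (only area equality between the designs is known);
  the side length is exposed in the configuration.

## Bag model and distension

The inflation bag is non-conducting; its wall is insulated except at the two
patches.  The bag is modelled as a cylinder of fixed length
L = 6 mL / (π·14²) ≈ 9.74 mm, so that full 6 mL inflation reproduces the
28 mm maximum diameter; at partial filling the radius is R(v) = 14·√(v/6) mm
(8.08 / 11.43 / 12.78 mm at 2/4/5 mL).  A capsule (cylinder with
hemispherical caps) was considered and rejected: a capsule of radius 14 mm
holds at least 11.5 mL, so no cap-ended shape of the stated maximum diameter
can hold only 6 mL.

Inflation presses the wall out to the bag radius.  The wall is treated as
incompressible under circumferential stretch (plane strain): each tissue
layer conserves its annular cross-sectional area from the resting state, so
distension thins the layers (at 2 mL the mucosa thins from 0.85 to
≈ 0.20 mm).  This choice matters: with the resting thickness kept, computed
patch impedances come out *above* the ring ones and *increase* with filling —
both opposite to the published computed values and to the in-vivo
measurements.  The incompressible-stretch model restores both orderings for
a physical reason.  The alternative reference — treating distension as pure
unfolding of mucosal folds from a large natural circumference — piles wall
tissue into a thicker effective annulus and inverts the ordering again, and
was rejected.  Fold geometry itself is out of scope.

## Meshing

A deterministic structured curvilinear grid (radius × angle × axial
position, periodic in the angle) is subdivided into tetrahedra with the
Kuhn 6-tet split; identical splitting in index space makes the mesh
conforming everywhere, including the periodic seam.  Node lines coincide
exactly with the tissue interfaces.

* **Radial**: every tissue layer receives at least five element layers
  (the transmural resolution rule), more if the target edge length h demands
  it; the surround coarsens geometrically (ratio 1.4) to the truncation
  radius.
* **Angular**: spacing ~h over the contact arc plus one footprint diameter,
  geometric coarsening on the far side; uniform when the footprint wraps.
* **Axial**: spacing h/2 over each contact and one footprint diameter beyond
  its edges (`refine=2`, exposed), spacing h between/around the contacts,
  geometric coarsening (capped at 8 mm) to the domain ends.  A refinement
  factor of 4 was considered and rejected: in a product grid it multiplies
  the global axial plane count ~4×, and the measured impedance change does
  not justify it (see convergence below).

The default target edge length is h = 0.17 mm (= resting mucosa / 5), giving
meshes of roughly 150k–430k nodes (0.8–2.5 M tets) per scenario; these are
the problem sizes used throughout the tests and the acceptance run.  The
coarseness gate `h ≤ thinnest layer / 5` is anchored to the *resting*
anatomy; distension-thinned layers still receive five radial divisions
through the grading, without forcing h ≈ 0.04 mm globally.

Boundary facets are tagged per structured quad face (both triangles of a
face inherit its tag, decided at the quad centroid).  This keeps the source
and sink facet sets exact mirror images; tagging at triangle centroids
breaks the mirror symmetry through the face diagonals and was observed to
induce a multi-percent asymmetry in the solved potential.

**Truncation of the "infinite" surround.**  Far radius 50 mm, axial length
120 mm, homogeneous Dirichlet V = 0 on the truncation boundary (consistent
with the r⁻² decay of the bipolar far field under the antisymmetric gauge).
Doubling the far radius (and extending the axial length accordingly) moves
the computed impedance by well under 1%, which bounds the truncation error.

## Solver numerics

The condensed system (contact nodes collapsed, far-field nodes eliminated)
is symmetric positive definite and is solved with Jacobi-preconditioned
conjugate gradients, relative tolerance 1e-10, with a sparse direct
factorization as fallback; everything is deterministic — two runs of the
same configuration are bitwise identical.  When no far-field boundary exists
(two-electrode fixtures), the sink potential is pinned to remove the
constant nullspace and the pair potentials are re-gauged afterwards.  The
reported potential is gauge-fixed so that V_source = −V_sink.

Electrode currents are evaluated with the variationally consistent
(reaction) flux, the standard discrete realization of ∮ J·n dA; it
reproduces the injected current to ~1e-12 relative.  Raw facet integration
of the piecewise-constant gradient is also provided for smooth surfaces
(e.g. the far boundary, where the net leak at default resolution is < 1%),
but it is meaningless on the contact itself, whose edge current density is
singular: there it misses by tens of percent at any practical resolution.

## Post-processing

E = −∇V is piecewise constant per element; |E| is evaluated at the element
centroid with no smoothing, and superlevel ("activation") volumes count
elements all-or-nothing.  This rule is reproducible and exactly monotone in
threshold and current, and makes the scaling identity
vol(t, k·I) = vol(t/k, I) exact per element; elements straddling the
threshold contribute whole, with the error bounded by the mesh-convergence
tests.  Volumes are reported per anatomical region (mucosa, muscle,
surround) only.  Impedance is Z = (V_source − V_sink)/I in kΩ.

Convergence at the default resolution, measured on the 2 mm ring scenario:
the impedance changes by ~1.2% from h = 0.17 to h = 0.085 (the equipotential
contact makes Z converge slowly from above — the edge singularity is
progressively better resolved), and meshed region volumes match the analytic
annular volumes to ~0.2%.

## Validation oracles

Closed-form resistances validate the full mesher + solver + post-processing
chain: concentric spherical shells (R = Σ (1/4πσᵢ)(1/rᵢ − 1/rᵢ₊₁)) and the
coaxial cylinder (R = ln(b/a)/(2πσL)).  The spherical fixture truncates the
sphere with insulated polar caps — the exact radial solution also solves the
truncated sector, whose resistance is the full-sphere value scaled by
4π/solid-angle — avoiding the polar coordinate singularity of a full
structured sphere.  All cases agree within 2% at the default resolution with
monotonically decreasing error under refinement.  A homogeneous slab with
plate electrodes, whose linear solution lies exactly in the element space,
pins down units and the impedance/field formulas to solver tolerance.

## What the scenarios do and do not show

The bundled scenarios use printed anatomical and electrical parameters plus
contact footprints; the *axial width of the physical ring electrodes and the
true dimensions of the patches were never published*, and only the contact
footprints above are defensible.  Consequences, measured at default
resolution:

* All published *ordering* properties are reproduced: ring impedance rises
  with spacing, patch impedance falls with filling, muscle activation volume
  exceeds mucosa at 20 V/m everywhere and falls monotonically across the
  3 → 20 → 100 V/m sweep, and activation volumes obey the exact
  current-threshold scaling identity.
* The *absolute* computed impedances (1.35 / 2.61 / 2.64 kΩ for the rings,
  1.50 / 1.33 / 1.28 kΩ for the patches) sit 1.4–2.5× above the published
  model values (0.94 / 1.05 / 1.08 and 0.86 / 0.81 / 0.79 kΩ), and the
  activation volumes correspondingly below, consistent with the published
  model having used a substantially larger effective electrode area than the
  contact footprints imply.  Notably, the ring values land inside the
  published *in-vivo* impedance range (2.41–2.95 kΩ).  The cross-family
  ordering (all patch impedances below all ring impedances) holds in the
  published table but is marginally violated here (ring2 1.35 < patch2ml
  1.50 kΩ) for the same reason.

The comparison table (`esofield table1`) therefore always reports the
published values side by side with relative deviations rather than claiming
reproduction.

## Known limitations

* Isotropic conductivities; muscle-fibre anisotropy is not modelled.
* No electrode–electrolyte interface impedance, saliva film, or luminal
  contents — the main reasons in-vivo impedances exceed any bare volume-
  conductor prediction.
* Straight rigid tube; no peristalsis, folds, or time-varying geometry.
* Plain |E| threshold; no activating-function or fibre-cable recruitment
  model, no refractory dynamics across the pulse train.
* The distension model is a plane-strain incompressibility idealization;
  real wall mechanics (folding, axial tethering) are richer.
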