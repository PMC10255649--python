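# Methods

This note documents the model implemented by `toothmc`, the choices made
where the design was genuinely open, the problem sizes the shipped tests use,
and what the passing tests do and do not establish.

## Transport model

Photon packets carry a statistical weight *w*, launched at 1. Propagation is
the standard weighted (implicit-capture) random walk for turbid media:

* **Free paths.** The engine samples a dimensionless optical depth
  τ = −ln(δ) and consumes it across voxels as Σ chord·µ_t(voxel). In a
  homogeneous region this reduces exactly to the textbook step
  s = −ln(δ)/µ_t, which is also exposed (and tested) as its own function.
  Voxels are traversed by exact face-to-face ray stepping, so the chord in
  every voxel is the exact ray segment — no fixed-substep pathlength bias.
* **Interactions.** At an interaction site the packet deposits w·µ_a/µ_t
  into the fluence map, survives with w·µ_s/µ_t, and deflects by a
  Henyey–Greenstein angle sampled by inverse CDF. The printed HG inverse CDF
  degenerates at g = 0; the analytic isotropic limit cos θ = 2δ − 1 is used
  there (the convention of the classic multilayer codes). Azimuth is uniform
  on [0, 2π): the phase function is azimuthally symmetric and nothing in the
  problem breaks that symmetry.
* **Boundaries (WSR / W-OSR).** With surface reflection enabled (WSR),
  unpolarized Fresnel coefficients (mean of s and p power reflectances,
  R = 1 past the critical angle) decide stochastically between specular
  reflection and Snell refraction at every voxel face where the refractive
  index changes — tissue–tissue and tissue–exterior alike — plus the
  deterministic specular weight loss at launch. With W-OSR the packet
  crosses every face undeflected at full weight. The Fresnel random draw is
  made only when the indices actually differ, so matched-index WSR and
  W-OSR runs are bit-identical (tested).
  Face normals are axis-aligned because the geometry is voxelized, not
  meshed; see "Known limitations".
* **Source and detection.** The source is a Gaussian beam (1/e² radius
  0.1 mm, truncated at twice that radius) entering normally through the flat
  occlusal face. A packet is detected when it transmits out of tissue
  through a face lying on a detector disc (center, radius, face axis); no
  numerical-aperture cut is applied. Default probes: reflectance discs of
  0.1 mm radius at SDS 0.25 / 0.75 / 1.5 mm on the source face;
  a transmittance disc on the opposite face at 7 mm center-to-center
  separation (placed laterally at √(7² − thickness²)).
* **Time gating and termination.** Elapsed time advances by chord·n/c per
  voxel; packets are tracked to 1 ns in ten 0.1 ns gates. A chord that would
  cross t_end is truncated there and the remaining weight is booked as
  in-flight residual. Russian roulette below w = 10⁻⁴ keeps packets with
  probability 0.1 (weight ×10) — standard multilayer-code values, unbiased
  by construction. The energy ledger
  launched = absorbed + escaped + residual (with the net roulette balance
  folded into "absorbed") closes to 1e-6 relative on every run (tested at
  machine precision).
* **Random numbers and replay.** Every packet owns a counter-based
  splitmix64 stream keyed by (run seed, photon index). Replaying a detected
  packet re-runs the identical code path on the identical stream, so replay
  reproduces exit weight, time, and per-tissue pathlengths bit-for-bit;
  the replay accumulates voxelwise chord and scattering-event sums weighted
  by the detected weight W_j. Memory is O(detected packets), not O(steps).

## Sensitivity quantities

MPP, MTP, and the absorption/scattering Jacobians follow the
perturbation-Monte-Carlo definitions given in the README. Two conventions
worth stating:

* The MPP denominator is the detected weight summed over *all* gates while
  the numerator is gate-restricted, so per-gate maps are partial fractions
  of the all-gates map and sum exactly to it (tested to 1e-9).
* "Weighted detected photons" (the spatial-sensitivity map and the
  contribution table) is the unnormalized Σ_j W_j·PP_j(V_i), divided by the
  voxel volume for the voxelwise map. Whether such published maps are
  pathlength-weighted or pure detected-weight maps is ambiguous in the
  source material; both the MPP map and this weighted map are emitted,
  labeled distinctly. Contribution percentages are
  100·(tissue sum)/(all-tissue sum) and always total 100.

The Jacobian definition is validated against an independent oracle: bumping
one tissue's µ_a by δ ≤ 0.02 mm⁻¹ and re-running with common random numbers
must change ln(detected weight) by −δ·MPP_tissue within 3 combined Monte
Carlo standard errors (tested).

## Synthetic geometry

No segmented molar mesh is distributed, so the generator builds a smooth
stand-in with the same compartment topology: an outer enamel superellipsoid
(lateral semi-axis 5 mm for a 6 mm crown, axial exponent 4) truncated flat at
the occlusal and root-side faces; a nested dentin body capped by a 1.2 mm
occlusal enamel layer and a ≥0.2 mm lateral enamel margin, exposed only at
the root-side face; an ellipsoidal pulp chamber plus a root-canal stem,
restricted to the 6-connected erosion of the dentin body so pulp never
touches enamel or the exterior. Two surface scales are calibrated by
bisection against voxel counts: the dentin body to enamel+dentin+pulp
partition and the pulp chamber to its fraction, each to |error| < 0.005
(achieved ≈ 0.001 at default pitch). Defaults: crown thickness 6 mm, volume
fractions 0.44/0.52/0.04, pitch 0.05 mm (≈3.7 million tissue voxels; the
pitch is a free parameter — only the total voxel count is constrained from
outside). Regeneration with identical parameters is bit-identical; a
`shape_seed` drives an optional surface perturbation that defaults to off.

The bounding medium (µ_a = µ_s = 10 mm⁻¹, g = 0.9, n = 1.0) is a
computational absorber: "high absorption and scattering" is not quantified
anywhere, so the values were chosen such that less than 1 % of weight
entering the padding survives a 1 mm round trip (e⁻²⁰ for 2 mm). Its n = 1.0
makes the tissue–padding interface optically identical to a tissue–air
interface, which is what the WSR flag is meant to exercise.

## What the generator emulates — and what it does not

The stand-in reproduces the compartment topology, volume fractions, crown
thickness, flat probe faces, and the optical-property contrast of a molar
crown. It does **not** reproduce the curved occlusal anatomy, enamel-rod
microstructure, root geometry, or the smooth (mesh) surface normals of a
real segmented tooth. Consequently, passing tests establish the correctness
of the transport physics and the internal consistency of the
pathlength/Jacobian machinery on *a* realistic three-compartment crown; they
do not certify numeric pathlengths or sensitivities for any particular real
tooth, which depend strongly on the individual geometry.

## Problem sizes used by the shipped tests

Full-scale runs of this kind use 5×10⁸–6×10⁸ photons (convergence rate
1/√N ≈ 4×10⁻⁵). The package's own test suite is sized for a single CPU:

* Oracle tests run on slab phantoms (2 mm, 0.05 mm pitch) at 10⁵–10⁶
  photons, where Beer–Lambert closed forms make 3-standard-error bands
  meaningful.
* Direction-of-effect tests run the calibrated crown at 0.15 mm pitch
  (≈1.4×10⁵ tissue voxels) with 10⁶ photons per run, using enlarged
  collection discs (0.2 mm reflectance, 1 mm transmittance radii) to cut
  detection variance; enlarging a disc rescales detected counts without
  changing any of the tested orderings. Effects asserted (dentin dominates
  scattering events; MTP and pulp contribution grow with SDS; transmittance
  sees pulp better than reflectance at every SDS) hold with wide margins at
  this scale.
* The geometry acceptance check generates the full default-pitch
  (0.05 mm) model.

## Numerical choices

* Positions are stored together with integer voxel indices; a face crossing
  sets the position exactly onto the face plane, so traversal cannot stall
  on accumulated round-off and no epsilon nudging is needed.
* Detected-photon records round-trip through TSV bit-exactly
  (17-significant-digit floats; round-trip float parsing on read).
* Depth profiles use half-open bins measured from the source face; argmax
  ties break toward the smaller depth.
* Degenerate requests fail loudly: zero/negative compartment fractions,
  non-integer gate counts, vacuum media (µ_t ≤ 0), pad thickness < 1 voxel,
  detectors closer than the crown is thick (transmittance), unknown config
  keys.
* The fraction calibration uses bracketing bisection (the bracket halves
  every iteration; the final |achieved − target| < 0.005 is asserted, and
  unreachable targets raise an error naming the offending compartment).

## Known limitations

* **Boundary-reflection gain.** Published full-scale results on a segmented
  molar mesh report *higher* detected signal with surface reflection (WSR)
  than without. On this voxelized stand-in the gain appears only in the
  633 nm transmittance channel (lateral enamel trapping guides light to the
  far detector, detected-weight ratio ≈ 1.35); in the other channels
  enabling Fresnel boundaries *lowers* the total detected weight, which is
  the classical behavior of absorbing turbid media (internally reflected
  light is partly absorbed before it can escape). Both effects are real
  physics; which one wins depends on the surface geometry. Axis-aligned
  voxel-face normals under-represent the light-guiding of smooth curved
  enamel, so the WSR-gain direction should be considered
  geometry-dependent, and the corresponding acceptance check is expected to
  fail on this stand-in for those channels. The per-channel comparison is
  reported by `analysis.compare_wsr` (both detected weight and
  weight×pathlength sensitivity).
* Polarization, coherence, fluorescence, and wavelength interpolation
  between 633 and 1310 nm are out of scope; the pulp refractive index is
  treated as wavelength-independent, as tabulated.
* Hypothesis-based property tests and Monte Carlo moment checks are seeded/
  derandomized; stochastic assertions use 3-standard-error bands estimated
  from the runs themselves (batch coefficient of variation), never fixed
  magic tolerances.
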