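# Methods

## Measurement model

All coordinates are world millimetres in the LPS patient frame (+x
patient-left, +y posterior, +z superior). A reference plane is built from an
ordered landmark triplet (anterior anchor, EAC_R, EAC_L): the normal is the
normalised cross product of the two edge vectors, sign-fixed so its
z-component is non-negative ("superior"), ties broken by the first nonzero
component positive. Angle computations use the absolute dot product, so the
sign convention can never change a result. Triplets with triangle area
≤ 1e-9 mm² are rejected outright rather than fit approximately.

Per ear, length is the 3D Euclidean chord between the pharyngeal and
tympanic orifices and angle is `arcsin(|n̂·d̂|)` in [0°, 90°]. Two choices the
measurement protocol leaves open are resolved as follows:

- **3D chord, not in-slice distance.** A clinician measures on the oblique
  reformat containing both orifices; the chord lies in that plane, so the 3D
  chord equals the in-image distance. Length is therefore plane-independent
  by construction.
- **One right-anchored plane for both ears.** The left ear is measured
  against the same (right-anchored) plane rather than a mirrored
  left-anchored one, matching how the plane-transfer workflow reuses the
  adjusted plane for both sides.

Angles and lengths are kept at full double precision everywhere; the
1-decimal table style appears only in console display.

## Synthetic cohorts

The generator inverts the measurement: per ear it draws a true angle
θ* ~ N(μθ, σθ) truncated to (0°, 90°) and a true length L* ~ N(μL, σL)
truncated to > 5 mm (rejection sampling, ≤ 100 attempts — no point mass at
the bounds), places the tympanic orifice at its template position, and puts
the pharyngeal orifice at distance L* along a direction making angle θ* with
the template's KC plane, pointing inferiorly, with in-plane azimuth uniform
on the forward-medial quadrant. With zero landmark jitter, measuring the
subject returns (θ*, L*) to machine precision — the round-trip the test
suite checks at 1e-6. Truth is defined once, against the KC plane of the
noise-free template; Reid's-plane behaviour follows from the tilt parameter
below, avoiding double bookkeeping.

Rater disagreement is modelled as i.i.d. isotropic Gaussian jitter on every
landmark coordinate (raters disagree on landmark placement, not on the
arithmetic that follows); the shipped presets set jitter to 0.

**Template.** EAC margins at x = ±60 mm, mandibular fossae ~8 mm anterior to
the EACs, infraorbital margins ~55 mm anterior, tympanic orifices just
antero-superior to the EACs, and all plane-defining anchors coplanar at
z = 0 when the tilt is zero — so the three reference planes then coincide
exactly. These coordinates are plausibility-only plumbing with no
anthropometric claim, and are overridable.

**KC-plane tilt.** Both the KC and Reid's planes contain the interaural
(EAC–EAC) axis, so the only way they can differ is by a rotation about that
axis; `mfp_tilt_deg` is that dihedral angle, applied by rotating the
mandibular fossae. For a chord at angle θ to the KC plane with azimuth φ,
the Reid's-plane angle is θ + t·sin φ to first order; with φ uniform on
(0, π/2) the cohort-mean offset is (2/π)·t. The `normal_sinus` preset ships
t = −1.7·(π/2) ≈ −2.670°, so its mean Reid's-plane angle reads 1.7° below
its KC angle (33.0° vs 34.7°), reproducing the published plane-equivalence
comparison; the π/2 factor is the analytic azimuth-averaging correction, not
a fitted constant.

**Presets.**

| preset | KC angle (SD) | length (SD) | age (SD) | % female | tilt |
|---|---|---|---|---|---|
| `normal_sinus` | 34.7° (5.2) | 31.3 mm (3.7) | 46 (14) yr | 46.7 | −2.670° |
| `normal_ci` | 33.0° (6.1) | 31.9 mm (2.4) | 63.9 (21.3) yr | 46.7 | 0 |
| `cholesteatoma` | 27.8° (5.1) | 25.9 mm (5.1) | 42.5 (14.3) yr | 33.3 | 0 |

The published summaries pair the two normal cohorts' lengths inconsistently
across comparisons (31.3 (3.7) vs 31.9 (2.4) mm appear swapped in one
table); the presets follow the cohort-comparison pairing for `normal_ci` and
the plane-equivalence pairing for `normal_sinus`, as noted in each preset's
`provenance` field. The sinus cohort's age SD is unreported and set to
14 yr from its 18–71 yr range. Ages are truncated to [18, 100] yr (adult
cohorts). Demographics exist only to exercise the comparison statistics; no
dependence between demographics and ET geometry is modelled, left and right
ears are independent, and no left–right correlation is imposed.

**What the synthetic cohorts do not emulate:** real CT intensities (bone/air
HU, noise, beam hardening), anatomical covariance between landmarks,
age/sex effects on geometry, within-subject ear correlation, or the
plane-dependent length differences a human measuring on 2D reformats can
produce. Passing tests therefore validate the measurement logic and the
statistics under the stated distributional conditions — not landmark
identification on clinical images.

Cohorts are reproducible from (preset, n, seed): each subject consumes its
own spawned child stream, so subject k is identical regardless of cohort
size, and serialized cohorts round-trip losslessly through JSON.

## MPR engine

Volumes are scalar grids with per-axis spacing and an origin at the center
of voxel (0,0,0); world = origin + index·spacing, and only
identity-direction NIfTI affines are accepted (the affine is authoritative
on read). Oblique slices sample a square grid on the plane, centered at the
projection of the volume center, with u the normalised projection of world
+x onto the plane (+y fallback within 1e-6 of the normal) and v = n × u.
Interpolation is trilinear with a configurable out-of-volume fill (default
0): phantom markers are piecewise-constant, so higher-order schemes add
ringing without benefit. Phantom rasterization renders each landmark as a
ball of a distinct integer label (declaration-order labels, 1–10), refusing
configurations where balls would touch; marker recovery takes the
intensity-weighted centroid of each label's voxels, merging any equal-label
components. At 0.3 mm spacing and 0.9 mm marker radius the full
rasterize → detect → measure loop agrees with coordinate-based measurement
within 0.5° and 0.5 mm.

## Statistics

Student's pooled-variance t-test is the primary two-sample test (the
era-typical default for "unpaired t test"), with Welch always co-reported;
raw-sample input reduces to summaries, so both paths agree to 1e-12.
Degenerate zero-variance pairs: equal means give p = 1 by convention,
unequal means p = 0 with a warning. Fisher's exact two-sided p sums
hypergeometric probabilities ≤ the observed table's (relative slack 1e-12);
it matches exhaustive enumeration on all small-margin tables. The
sample-size formula is the two-sided normal approximation; at
sd = 4.8°, δ = 3.9°, α = 0.05, power 0.8 it gives 23.8 → 24 ears per group.
The approximation ignores the t critical value, so the exact noncentral-t
power at n = 24 is ≈ 0.787, a hair under nominal — the test suite asserts
agreement with the exact power rather than ≥ 0.80. No multiple-testing
correction is applied (none is applied in the study design this mirrors);
reports running more than three tests carry an explicit note. Ears are the
unit of analysis throughout; subject-level clustering is deliberately not
modelled.

Plane-equivalence and left-vs-right comparisons on the same ears are
naturally paired, but only unpaired tests are implemented (matching the
stated protocol); recomputing those comparisons from summary statistics can
therefore differ in the second decimal from published p-values, and no
equality is asserted for them.

## Problem sizes and seeds

Simulation-based tests use the study-design size of 30 subjects (60 ears)
per cohort; calibration checks run at a fixed seed (20220331) with
2·SD/√n tolerances, coverage checks use 100 replicate seeds, the type-I
calibration uses 1000 null cohort pairs, and Monte-Carlo moment checks use
10⁴ ears. All random tests are seeded; `scripts/acceptance.py` derives every
stream from its `--seed` argument.

## Known limitations

- Landmarks are inputs: no automatic landmark detection or segmentation.
- No DICOM ingestion; NIfTI only, identity-direction affines only.
- Length is plane-independent by construction, so the model cannot
  reproduce protocol-induced length differences between reference planes.
- The normal-approximation sample size slightly understates the exact-t
  requirement (24 vs ~25 ears for a true 80%).
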