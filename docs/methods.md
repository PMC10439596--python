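# Methods

## Measurement model

The quantity of interest is the signed in-plane deviation of three
simulated femoral-component rotational alignments from the surgical
transepicondylar axis (sTEA), measured in the transverse plane of the
femoral mechanical axis.

**Axes from landmarks.** Seven bony landmarks define four reference axes:
sTEA (lateral epicondylar prominence ↔ medial epicondylar sulcus), aTEA
(lateral ↔ medial epicondylar prominences), the Whiteside/AP line
(deepest point of the trochlear groove ↔ deepest point of the posterior
intercondylar notch) and the posterior condylar line, PCL (lowest points of
the medial and lateral posterior condyles). Axes are undirected lines; no
endpoint ordering is assumed anywhere downstream.

**Mechanical axis and plane "o".** Circles are fitted to two cross-section
point clouds — the shaft medullary canal and the section at the
intercondylar-notch apex — and the line through the centers is the
anatomical axis, oriented distal→proximal (notch → canal). The mechanical
axis is obtained by rotating the anatomical axis by the subject's coronal
valgus angle α in the varus sense. The transverse plane "o" is
perpendicular to the mechanical axis.

**Deviation angles.** Each reference axis direction is projected
orthogonally into plane "o" and normalized. The simulated alignments are:
the perpendicular (in-plane 90° rotation) of the projected Whiteside line;
the projected aTEA itself; and the projected PCL externally rotated by 3°.
The three signed angles from the projected sTEA — ∠WS, ∠aTEA, ∠PCL — are
positive for external rotation and normalized to (−90°, 90°]. Deviations of
magnitude strictly greater than 2° are classified as outliers (the boundary
value 2.0° is not an outlier; the threshold is configurable).

## Conventions and geometric choices

* **Canonical frame.** Right-handed; origin at the notch-apex circle
  center; +Z proximal along the true mechanical axis; +Y anterior; +X
  medial for a right femur. Left femurs are handled by a chirality factor
  (equivalently, mirroring across the sagittal plane), so the
  external-rotation-positive semantics are side-independent; mirroring a
  model and flipping its side flag leaves every signed angle unchanged.
* **Sign convention.** The sources define the sign only semantically
  (external = positive). Geometrically we realize it as the
  counterclockwise sense about the distal→proximal plane normal for a right
  femur, mirrored for a left femur.
* **Varus rotation plane.** The α correction is applied as a rotation about
  the anteroposterior direction (orthogonalized against the anatomical
  axis), i.e. within the coronal plane, which matches the coronal long-leg
  view in which α is measured; the rotation plane is not otherwise
  constrained by the procedure's description. The construction guarantees
  angle(mechanical, anatomical) = α exactly.
* **Circle fit.** Algebraic Kåsa least squares (one linear solve) in the
  section plane: exact on exact circular data, deterministic and fast.
  Iterative geometric (orthogonal-distance) refinement exists only as a
  test oracle; at realistic digitization noise (0.1 mm) the two centers
  agree within 0.05 mm.
* **Tolerances.** 1e-9 for exact geometric identities, 1e-6° for noise-free
  end-to-end round trips; section points must be coplanar within 0.1 mm;
  directions within 1e-9 of a plane normal raise a degenerate-projection
  error rather than returning an unstable projection.

## Synthetic cohort generator

The generator inverts the pipeline: it lays out the four in-plane axis
directions so that the noise-free measurement reproduces the specified true
angles (∠PCL truth = 3° − PCA), lifts each landmark out of the transverse
plane by a per-landmark axial offset drawn U(−8, +8) mm — the reference
axes of a real femur do not lie in one CT section, and projection must (and
does, exactly) remove these components — and samples the two cross-sections
exactly on circles centered on the anatomical axis, which is tilted from
+Z by α in the coronal plane.

Default cohort conditions (all configurable):

| parameter | default | basis |
| --- | --- | --- |
| n | 120 | study cohort size |
| ∠WS truth | N(2.54°, 2.30°) | reported cohort distribution |
| ∠aTEA truth | N(4.21°, 1.01°) | reported cohort distribution |
| ∠PCL truth | N(0.50°, 1.06°) | reported cohort distribution |
| valgus α | N(7.9°, 1.5°) truncated to (3°, 12°) | mean from the worked example; spread a plausible clinical range |
| condylar width | 80 mm | plausible adult distal-femur scale |
| Whiteside span | 40 mm | plausible AP trochlear extent |
| posterior condyle offset | 25 mm posterior | plausible |
| shaft section height | 120 mm above the notch | within a knee CT volume |
| observer noise σ | 0.3 mm isotropic per landmark | calibration, see below |

Lengths carry no science here — only angles do — so the length defaults are
round plausible magnitudes, fixed once. The observer-noise default is the
one deliberately *calibrated* quantity: no observer-noise magnitude is
reported by the study, only the resulting ICCs, so σ is chosen such that,
at the default geometry scale, simulated intra- and inter-observer ICCs
land in the "high" band (> 0.75; empirically 0.84–0.94 across seeds, versus
the reported 0.90–0.975). At σ = 0.5 mm the shorter 40 mm Whiteside lever
arm and the ~1° between-subject spread of ∠aTEA/∠PCL pull their ICCs down
to ≈ 0.70; 0.3 mm placement repeatability is realistic for trained readers
on 3D surface models. σ is a per-observer parameter, not a claim about the
study's readers.

What the generator does **not** emulate: bone surface geometry, cartilage
and osteophytes, CT segmentation error, correlated (anatomy-driven)
landmark ambiguity, or any dependence between the three deviation angles
within a knee (they are drawn independently). Passing tests therefore show
that the *measurement procedure* is correct and stable under placement
noise — not that real-patient accuracy would match the simulated numbers.

## Statistics

* **ICC.** Two-way random-effects, absolute-agreement, single-measures
  ICC(2,1), computed from the two-way ANOVA mean squares, with the standard
  F-based 95% confidence interval; a consistency form (ICC(3,1)) is
  available via configuration and the form used is recorded in the output.
  Grading: poor < 0.4 ≤ good ≤ 0.75 < high. Intra-observer reliability
  compares the first observer's two sessions; inter-observer reliability
  compares the two observers' final session. With zero observer noise the
  within-subject differences are exactly zero and the ICC is exactly 1.
* **Bland–Altman.** Bias = mean difference; limits = bias ± 1.96·SD of the
  differences (the normal quantile, not a t quantile); coverage counts
  differences inside the limits *inclusively* and the pass flag requires
  ≥ 95% coverage. Coverage is reported as a number: for Gaussian
  differences ±1.96 SD captures ~95% in expectation, so individual samples
  of n = 120 occasionally fall just below.
* **Axis comparison.** The three angle groups are compared as independent
  samples (as is conventional for this design, although they are paired
  within knees — a documented limitation): Levene's median-centered test at
  α = 0.05 selects classic one-way ANOVA versus Welch's ANOVA; Fisher-LSD
  pairwise t-tests (pooled ANOVA MSE, unadjusted p-values) are always
  reported and carry inferential weight only when the omnibus test is
  significant.

## Reproducibility

All randomness flows from a single integer seed through
`numpy.random.default_rng`; the measurement stage uses a stream derived
from seed + 1 so that generation and observation noise are decoupled.
Outputs contain no timestamps; a fixed configuration and seed reproduce
every file byte-for-byte. The full default run (120 subjects, 2 observers ×
2 sessions, complete analysis) takes a few seconds on one CPU.

## Known limitations

* One shaft cross-section is used for the canal circle (plus the notch-apex
  circle); multi-section canal fitting is out of scope.
* The generator's observer noise is isotropic and independent across
  landmarks; real placement error is anisotropic and anatomy-correlated.
* Valgus α is treated as exact per subject; its own radiographic
  measurement error is not modelled.
* No mesh/surface output; model interchange is landmark + section JSON.
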