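# femrot

Measurement and reliability analysis of femoral rotational reference axes on
3D distal-femur landmark models.

## The problem

In total knee arthroplasty with a measured-resection technique, the rotation
of the femoral component is set from bony reference axes of the distal
femur. The **surgical transepicondylar axis (sTEA)** — the line from the most
prominent point of the lateral epicondyle to the medial epicondylar sulcus —
is the accepted gold standard, but it is hard to palpate intraoperatively.
Surgeons therefore align the component to surrogate axes:

* the perpendicular of the **Whiteside (anteroposterior) line** (trochlear
  groove deepest point ↔ deepest point of the posterior intercondylar
  notch),
* the **anatomical transepicondylar axis (aTEA)** (medial ↔ lateral
  epicondylar prominences), or
* the **posterior condylar line (PCL)** (lowest points of the two posterior
  condyles) with a conventional **3° of external rotation**.

`femrot` implements the 3D measurement procedure that quantifies how far
each surrogate-based alignment deviates from the sTEA, and the statistics
used to judge its accuracy and reproducibility.

## The measurement model

All axes are compared in the **transverse plane "o"** perpendicular to the
femoral mechanical axis, located as follows:

1. Fit least-squares circles to two cross-sections: the femoral-shaft
   medullary canal and the section through the intercondylar-notch apex.
   The line through the two centers is the **anatomical axis**.
2. Rotate the anatomical axis by the subject's **femoral valgus angle α**
   (measured per patient on long-leg coronal radiographs, e.g. α = 7.9°)
   within the coronal plane, in the varus sense, giving the **mechanical
   axis**; plane "o" is perpendicular to it.
3. Project the four reference axes into plane "o" (projections L′₁–L′₄ of
   the Whiteside line, aTEA, sTEA, PCL), and form the simulated component
   alignments: L₆ = perpendicular of L′₁, and L₅ = L′₄ externally rotated
   by 3°.
4. Report three signed deviation angles from L′₃ (the projected sTEA):
   **∠WS** (L₆ vs sTEA), **∠aTEA** (L′₂ vs sTEA) and **∠PCL** (L₅ vs sTEA),
   positive when externally rotated, and flag deviations of magnitude
   strictly greater than 2° as **outliers**.

Reproducibility of repeated measurements (two observers × two sessions) is
assessed with the two-way random-effects absolute-agreement ICC(2,1)
(graded poor < 0.4 ≤ good ≤ 0.75 < high) and Bland–Altman limits of
agreement (bias ± 1.96·SD of differences, with the fraction of differences
inside the limits reported). Accuracy of the three alignments is compared
by one-way ANOVA (Welch's variant when Levene's test rejects variance
homogeneity) with Fisher-LSD pairwise tests.

Because no patient imaging is distributed, the package ships a
**synthetic cohort generator**: parametric femur models with exactly known
ground-truth deviation angles, per-subject valgus angles, non-coplanar axis
endpoints, and Gaussian observer landmark-placement noise, calibrated to
the cohort statistics reported for 120 osteoarthritic knees
(∠WS 2.54 ± 2.30°, ∠aTEA 4.21 ± 1.01°, ∠PCL 0.50 ± 1.06°).

## Worked example

```python
import numpy as np
from femrot import FemurSpec, generate_femur, measure_subject

spec = FemurSpec(
    subject_id="demo", side="right",
    true_ws=2.54, true_atea=4.21, true_pca=2.5, valgus_alpha=7.9,
    axial_offsets={"a": 3.0, "e": -6.0, "g": 2.5},
)
model = generate_femur(spec, np.random.default_rng(0))
dev = measure_subject(model)
print(f"∠WS   = {dev.ws:+.2f}°  outlier={dev.ws_outlier}")
print(f"∠aTEA = {dev.atea:+.2f}°  outlier={dev.atea_outlier}")
print(f"∠PCL  = {dev.pcl:+.2f}°  outlier={dev.pcl_outlier}")
```

prints

```
∠WS   = +2.54°  outlier=True
∠aTEA = +4.21°  outlier=True
∠PCL  = +0.50°  outlier=False
```

i.e. the noise-free pipeline recovers the generator's ground truth: the
Whiteside-perpendicular deviates +2.54° (an outlier, > 2°), the aTEA
+4.21°, and the PCL+3° alignment only +0.50° — ∠PCL = 3° − PCA, with this
subject's posterior condylar angle set to 2.5°.

A full reproducible cohort run (generate 120 femurs, measure under
2 observers × 2 sessions of landmark noise, analyse):

```sh
femrot run-all --n 120 --seed 7 --out demo_run
```

writes model JSONs, a ground-truth table, the angles CSV, study-style
reliability tables, an outlier table, Bland–Altman plot data and a
`summary.json` — e.g. with seed 7 the cohort means are
∠WS 2.54 ± 2.31° (58.3% outliers), ∠aTEA 4.25 ± 0.92° (98.3%),
∠PCL 0.56 ± 1.20° (14.2%), Welch omnibus p < 10⁻⁶⁰, and all intra- and
inter-observer ICCs fall in the high band (0.86–0.94). A fixed seed makes
every output byte-reproducible.

The individual stages are also available as `femrot simulate`,
`femrot measure` and `femrot stats`; see `femrot --help`.

## Layout

| module | contents |
| --- | --- |
| `femrot.geometry` | circle fitting (Kåsa), axes, planes, projections, signed in-plane angles |
| `femrot.models` | landmark sets and femur models |
| `femrot.synthetic` | cohort generator, observer-noise model, coronal valgus axes |
| `femrot.pipeline` | reference-axis construction and the deviation-angle measurement |
| `femrot.stats` | ICC, Bland–Altman, cohort summaries, axis comparison |
| `femrot.run`, `femrot.cli`, `femrot.config` | end-to-end workflow, CLI, configuration |

See `docs/methods.md` for the measurement model, conventions and
limitations in detail.
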