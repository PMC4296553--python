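# cumudose

Cumulative dose assessment for combined radiotherapy of cervical cancer:
whole-pelvis external-beam radiotherapy (EBRT) plus fractionated high-dose-rate
intracavitary brachytherapy (ICBT). The package converts per-component
physical dose grids to biologically equieffective dose in 2-Gy fractions
(EQD2), fuses every component onto the first-brachytherapy CT frame by rigid
and deformable image registration (DIR), reads the cumulative dose-volume
parameters the field reports — HR-CTV D90, rectum and bladder D2cc — and
quantifies registration quality with the Dice similarity coefficient (DSC).

It is written for medical-physics researchers who want to study *when*
registration-based dose accumulation and the conventional GEC-ESTRO practice
of simply adding per-component DVH parameters agree, on fully controlled
synthetic data. A synthetic pelvic phantom generator produces multi-session
courses with known organs, known doses, and known ground-truth deformations,
so every pipeline stage can be validated against closed-form oracles.

## The model

**Fractionation.** Each component delivering total dose D in n equal
fractions is converted voxel-wise with the linear-quadratic model,

    EQD2 = D · (d + α/β) / (2 + α/β),   d = D / n,

with α/β = 10 Gy for tumor and α/β = 3 Gy for late-responding normal tissue.
A 45 Gy / 25-fraction EBRT plan is worth 43.2 Gy_EQD2 to normal tissue; a
6 Gy single-session brachytherapy dose is worth 8.0 Gy_EQD2 to tumor.

**Spatial fusion.** The EBRT plan is aligned to the reference frame rigidly
(least-squares bony-landmark fusion, closed-form Kabsch solution);
brachytherapy sessions 2–4 are aligned rigidly on the applicator and then
deformably with a multi-resolution demons registration (sum-of-squared-
differences forces, Gaussian fluid + diffusion regularization, deterministic).
Externally computed displacement fields can be injected in place of the
demons step — that is how phantom ground truth enters. All warping is
backward (pull-back): the cumulative dose at reference voxel x is the sum of
the component EQD2 doses sampled at the mapped points x + u(x).

**Evaluation.** Cumulative DVH parameters are compared between voxel-wise
accumulation and simple DVH-parameter addition (Σ of per-component D90 /
D2cc). Contour-propagation quality is scored as
DSC = 2|V_DIR ∩ V_initial| / (|V_DIR| + |V_initial|), with a paired t-test
between DIR and rigid-only DSC values.

## Worked example

Simulate a course, accumulate it, and read off the parameters:

```bash
cumudose simulate --seed 1 --out course/
cumudose report --course course/course.yaml --out results/
```

or in Python:

```python
import cumudose as cd

course = cd.generate_course(cd.PhantomSpec(seed=1))
treatment = cd.to_treatment_course(course)
result = cd.accumulate(treatment)          # demons DIR, default settings
params = cd.dvh_parameters(result.tumor, course.reference.organs["HR-CTV"])
print(round(params.d90, 1))                # 76.8
```

The cumulative HR-CTV D90 of 76.8 Gy_EQD2 decomposes into ≈ 44 Gy_EQD2 from
the EBRT plateau plus ≈ 8 Gy_EQD2 per brachytherapy session, matching the
clinical scale of combined-modality prescriptions. On the same course, simple
parameter addition gives D90 = 75.9 Gy_EQD2 (a slight underestimate — summed
cold spots do not coincide) while for the organs at risk it *over*estimates
D2cc (bladder: 60.8 vs 59.0 Gy_EQD2 accumulated).

The bundled published volume/DSC table can be replayed without any images:

```text
$ cumudose reproduce-tables
HR-CTV: DIR 0.77 ± 0.06, rigid 0.46 ± 0.16, paired p = 4.48e-06
rectum: DIR 0.75 ± 0.06, rigid 0.62 ± 0.10, paired p = 6.78e-04
bladder: DIR 0.87 ± 0.08, rigid 0.69 ± 0.14, paired p = 1.60e-04
...
```

Deformable registration overlaps the reference contours significantly better
than bony rigid fusion for every structure (p < 0.05).

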