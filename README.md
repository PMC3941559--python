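# respivol

Photogrammetric thoracoabdominal volumetry and spirometry prediction for
marker-annotated breathing maneuvers.

## What it does and for whom

Spirometry is the standard for measuring lung volumes, but spirometers
are scarce outside large laboratories. `respivol` implements a low-cost
alternative for field settings (schools, basic health units, sports
clubs): a supine subject wears five 13 mm circular adhesive markers over
anatomical landmarks of the trunk — manubrium sterni (MEd), xiphoid
process (AXd), inferior angle of the 10th rib (ACd), umbilicus (COd) and
right anterior superior iliac spine (EId) — and performs a forced vital
capacity maneuver in front of a lateral video camera. From the frames at
maximal expiration and maximal inspiration, the package:

1. detects the markers and calibrates the metric scale from their known
   13 mm diameter (no ruler or checkerboard needed);
2. partitions the sagittal trunk profile into four compartments — upper
   and lower thorax (UT, LT) and upper and lower abdomen (UA, LA) — each
   a trapezoid closed on the bed line, and extrudes the areas through the
   caliper-measured thorax length *L* into volumes:
   `V [l] = A [cm²] × L [cm] / 1000`;
3. computes the **total volumetric mobility**
   `m = V_insp − V_exp` (thoracoabdominal totals), the kinematic
   predictor of the regression equations

       FVC = −8.572 + 5.108·height + 0.138·thorax + 0.120·m
       DI  = −6.373 + 3.751·height + 0.122·thorax + 0.163·m

   (height in m, thorax in cm, m in l; FVC = forced vital capacity,
   DI = deep inspiration, both in litres);
4. validates predictions against measured spirometry with Pearson
   correlations, an OLS refit of the same model form, and Bland-Altman
   agreement (bias ± 1.96·SD limits, one-sample t-test for bias).

Subjects with a Tiffeneau index (FEV1/FVC) strictly below 0.80 are
screened out as showing airflow obstruction before any analysis.

Because no study data are distributable, `respivol.synthetic` generates
complete synthetic studies — subjects with realistic correlated
anthropometrics, ground-truth marker kinematics whose forward volumetry
reproduces a prescribed mobility exactly, and rendered frames — so the
entire chain is testable end to end. See `docs/methods.md` for the model
details and design choices.

## Worked example

Simulate a five-subject study, measure it from the rendered frames, and
predict spirometry:

```bash
respivol simulate --n 5 --seed 42 --out-dir demo
respivol measure --frames-index demo/frames_index.csv \
                 --subjects demo/subjects.csv --out demo/volumes.csv
respivol predict --volumes demo/volumes.csv \
                 --subjects demo/subjects.csv --out demo/predictions.csv
```

`demo/volumes.csv` holds one row per subject and phase (litres), with the
mobility on the inspiration row:

```
subject_id,phase,UT_l,LT_l,TT_l,UA_l,LA_l,TA_l,thoracoabdominal_l,mobility_l
S0001,expiration,4.97,4.01,8.98,1.74,2.42,4.16,13.13,
S0001,inspiration,5.95,5.58,11.54,2.28,2.69,4.97,16.51,3.37
```

Subject S0001's trunk prism expands from 13.13 l to 16.51 l between the
two extremes, a mobility of 3.37 l. `demo/predictions.csv` then applies
the equations:

```
subject_id,height_m,thorax_cm,mobility_l,FVC_pred_l,DI_pred_l
S0001,1.5952,23.26,3.37,3.191,2.998
S0002,1.6974,24.59,3.4,3.9,3.548
```

so S0001 (1.60 m, thorax 23.3 cm, mobility 3.37 l) is predicted an FVC of
3.19 l and a deep inspiration of 3.00 l. With measured spirometry in the
subject table, `respivol validate` additionally writes the correlation
table, Bland-Altman limits and plots, and refit model JSONs, and
`respivol report` summarizes the cohort (mean/SD/min/max per variable).

The same measurement runs from manually digitized coordinates
(`--coords`, a CSV of pixel positions and marker diameters) when frames
are processed in external software.

## Library use

```python
import respivol as rv

subject = rv.sample_subject(7)
truth = rv.make_kinematics(subject, target_mobility=3.75, rng_seed=1)
frame = rv.render_frame(truth, "inspiration", subject)
markers = rv.detect_markers(frame)
cal = rv.calibrate(markers)                      # mm per pixel
ms = rv.assign_landmarks(markers, cal, frame.baseline_row_px)
vol = rv.volumes_from_markers(ms, subject.thorax_length)
print(rv.predict_fvc(subject.height, subject.thorax_length, 3.75))
```

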