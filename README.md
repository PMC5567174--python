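# flexitorque

Elbow-flexion torque modelling from upper-arm circumferential strain.

During voluntary elbow flexion the biceps brachii thickens and the upper-arm
circumference grows. `flexitorque` implements a bio-mechanical pipeline in
which the joint torque is the product of the voluntary circumferential strain
`s` and a combined torque-angle/torque-velocity factor `eta(theta) = T/s`:

1. **synthetic** — a forward simulator of passive, isokinetic and isotonic
   flexion trials (synchronized angle / torque / circumference channels) with
   known ground truth, sensor noise and fabric-sensor baseline drift.
2. **preprocess** — passive-trial calibration of the connatural circumference
   profile, flexion segmentation, drift-cancelling rectification of the
   circumference signal, and strain extraction.
3. **model** — `eta` computation with a strain-threshold mask, least-squares
   fitting of `ln eta = a1*theta + a2` over [50°, 100°], training of an
   averaged `eta_bar` curve, and torque prediction `T = s * eta_bar(theta)`.
4. **stats** — one-way ANOVA (with eta-squared effect sizes) testing the
   velocity independence of the fitted parameters across 60/90/120 °/s, and
   five torque-agreement indicators (C.C, r_ma, r_mr, r_rms, r_m).
5. **cli / pipeline** — an end-to-end study replica: per subject, calibrate,
   train on the 1st isokinetic sets, predict the 2nd sets and all isotonic
   sets, and emit per-subject p-value and error tables.

## Command line

```sh
# simulate a 3-subject cohort of trial CSVs with a manifest
flexitorque simulate --subjects 3 --seed 1 --out cohort/

# calibrate a connatural profile from passive trials
flexitorque calibrate --passive cohort/subject_1/passive_1.csv \
    --passive cohort/subject_1/passive_2.csv --out profile.csv

# extract the 2nd flexion's strain series
flexitorque strain --trial cohort/subject_1/isokinetic_90_set1.csv \
    --profile profile.csv --flexion-index 2 --out strain.csv

# train eta_bar from the three 1st isokinetic sets
flexitorque train --trials cohort/subject_1/isokinetic_60_set1.csv \
    --trials cohort/subject_1/isokinetic_90_set1.csv \
    --trials cohort/subject_1/isokinetic_120_set1.csv \
    --profile profile.csv --out model/

# predict and evaluate a held-out trial
flexitorque predict --trial cohort/subject_1/isokinetic_90_set2.csv \
    --profile profile.csv --model model/ --out pred.csv
flexitorque evaluate --predicted pred.csv --range 50 100

# ANOVA of fitted parameters grouped by velocity
flexitorque anova --fits model/fits.json --param a1

# full 13-subject study replica with both report tables
flexitorque reproduce --subjects 13 --seed 0 --out study/
```

All commands are deterministic for a fixed `--seed`.

## Data formats

* Trial CSV: `time_s, angle_deg, torque_Nm, circumference_mm` (one file per
  trial; metadata lives in the cohort `manifest.json`).
* Profile CSV: `angle_deg, c0_mm` with a `# rom_deg lo hi` header comment.
* Strain CSV: `angle_deg, circumference_rect_mm, strain, valid`.
* Model directory: `eta_bar.csv` (`angle_deg, eta_bar_Nm, valid`) plus a
  `meta.json` sidecar with training provenance.
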