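# fluoroperf

A desk-scale pipeline for fluorescence-augmented lesion classification in
dual-channel (white-light + near-infrared) endoscopy recordings, plus the
accompanying multi-rater clinical-judgement statistics.

The package covers six areas:

- **`fluoroperf.synthetic_data`** — synthetic dual-channel scene renderer
  (gamma-variate ICG inflow/washout kinetics per tissue class, global camera
  jitter, Gaussian sensor noise) with exact ground-truth masks, displacement
  series and generating curves; an item-response rater simulator
  (P(correct) = logistic(skill − difficulty)); and self-describing on-disk
  fixture bundles (multi-page 16-bit TIFF stacks, ROI JSON, CSVs, YAML
  manifest).
- **`fluoroperf.roi_tracking`** — normalized-cross-correlation template
  tracking of ROIs on the white channel (bounded search window, validity
  flags, optional subpixel refinement) and mean-NIR curve extraction over
  the displaced footprint at 30 fps, with interpolation of invalid frames.
- **`fluoroperf.curve_features`** — curve normalization (smoothing,
  baseline subtraction, peak scaling) and the five discriminant milestones:
  time to peak, upslope, downslope, skew and centre of mass, plus
  lesion-minus-normal reference deltas.
- **`fluoroperf.classification`** — seeded hyperparameter search over
  bagged and gradient-boosted tree ensembles scored by patient-grouped
  5-fold CV accuracy, per-ROI probability/call, ROI→patient aggregation
  ("any" / "majority") and confusion/accuracy/sensitivity/specificity
  reporting.
- **`fluoroperf.rater_stats`** — Fleiss multi-rater kappa with large-sample
  95% CI and qualitative bands, Likert frequency tables, per-rater and
  per-group diagnostic accuracy, majority-vote analysis, Spearman rank
  correlation and size-estimation error.
- **`fluoroperf.pipeline` / `fluoroperf.cli`** — config-driven
  orchestration (`simulate → track → features → train → classify →
  raterstats → report`) with deterministic per-stage seed fan-out.

`fluoroperf.data` bundles per-polyp summary tables from a published
32-rater survey of 14 ambiguous rectal lesions (majority answers, Likert
frequency counts, pathology truth, size estimates); cell-level responses
were not published, so vote counts are reconstructed from the majority
percentages.

## CLI

```sh
fluoroperf run --workdir out --seed 7            # full pipeline, report.json
fluoroperf simulate --out bundle --seed 1        # synthetic scene bundle
fluoroperf track --wl bundle/scene_wl.tif --nir bundle/scene_nir.tif \
                 --rois bundle/rois.json --out curves.csv
fluoroperf features --curves curves.csv --reference-label normal --out features.csv
fluoroperf train --features features.csv --folds 5 --seed 17 --out model.joblib
fluoroperf classify --model model.joblib --features features.csv \
                    --aggregate any --out preds.csv
fluoroperf raterstats --answers answers.csv --truth truth.csv --out report/
```

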