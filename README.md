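# wheelvault

Markerless motion analysis of the wheel-gymnastics vault mounting phase
(Unit 2): rule-based key-frame detection from optical-flow and
segmentation-mask signals, a 21-variable pose feature set, Random-Forest
estimation of execution-score (E-score) deductions with importance-based
feature selection and decision-rule extraction, and the associated group
hypothesis tests — exercised end to end on a built-in synthetic vault
simulator, so no video data or neural networks are required.

## Layout

| Module | Role |
| --- | --- |
| `wheelvault.synth` | Synthetic performances with known ground-truth events, knee angle, time on wheel, and regulation-based deductions |
| `wheelvault.ioformats` | BODY_25 pose JSON, Middlebury `.flo` flow, mask PNGs, canonical feature-table CSV |
| `wheelvault.events` | The four key-frame detectors (take-off, pike-mount, contact start, thrust) |
| `wheelvault.features` | The 21 explanatory variables (18 joint angles, 2 level features, time on wheel) |
| `wheelvault.model` | Day-wise sequential split, MSE-criterion forest, importances, rule paths, single-feature baseline |
| `wheelvault.stats` | Threshold-group assignment, Mann-Whitney U (exact enumeration + normal fallback), Dunnett many-to-one test |
| `wheelvault.pipeline` | End-to-end orchestration and a schema-validated, reproducible JSON report |

## CLI

```sh
# synthesize a corpus to disk (masks, .flo flows, pose JSON, ground truth)
wheelvault simulate --seed 0 --days 1 --per-day 2 --out data/

# detect key frames from flow + mask files (synthetic-scale parameters)
wheelvault detect --flows data/perf_000/flows --masks data/perf_000/masks \
    --eps 0.5 --mag-lo 0.6 --mag-hi 4.0 --out events.json

# compute the 21 features for one performance
wheelvault featurize --events events.json --keypoints data/perf_000/keypoints \
    --fps 60 --image-height 120 --out features_one.csv

# model and statistics on a canonical feature table
wheelvault train --features features.csv --out model.joblib
wheelvault rules --model model.joblib
wheelvault stats --features features.csv --cond-a "time_on_wheel<=4.935" \
    --cond-b "knee_pikemount>162.5" --control I --out stats.json

# everything at once, from a config file
wheelvault run-all --config examples/config.yaml --out experiment/
```

Note on detector parameters: the reference defaults (30-frame persistence
window, 10-frame look-back, a 5.5–15 px/frame thrust magnitude band,
1 px/frame moving-pixel threshold) assume full-resolution footage at
60 fps. The synthetic simulator renders at 160×120, so the pipeline's
default `EventParams` rescale the magnitude band and moving-pixel
threshold (`eps=0.5`, band 0.6–4.0); window, look-back, and the 0.5 s
contact rule are unchanged.

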