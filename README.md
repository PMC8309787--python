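# pearcount

Detector-agnostic fruit counting from video detection streams.

Orchard yield is still widely counted by hand. A practical alternative is to
film a tree row, run a per-frame fruit detector, and turn the detections into
a count — but raw detections flicker, double-fire, and vanish under occlusion,
so a counting system needs a tracker between the detector and the tally.
`pearcount` implements everything in that pipeline *after* the detector, for
any detector that can emit per-frame bounding boxes:

* **I/O** for the MOT-challenge `det.txt`/`gt.txt` dialects and per-frame
  YOLO/Darknet annotation files;
* an online **multi-object tracker** in the SORT family: per-track
  constant-velocity Kalman filter on (cx, cy, a, h), association by the
  Hungarian algorithm under motion (1 − IoU) and/or appearance (cosine
  distance to an embedding gallery) costs, chi-square Mahalanobis gating, a
  matching cascade, and the tentative → confirmed → deleted lifecycle;
* two **counting strategies** plus a variant: unique track IDs, first
  crossing of a horizontal ROI line at a configurable fraction of the frame
  height, and unique IDs filtered by detection coverage over the track
  lifespan;
* **evaluation**: Pascal-VOC detection metrics (greedy IoU ≥ 0.5 matching at
  confidence ≥ 0.25, P, R, F1, FNR, FPR, mean IoU, 11-point interpolated AP)
  and CLEAR-MOT-style counting metrics

      R_count = TP/(TP+FN)        P_count = TP/(TP+FP)
      F1_count = 2·P·R/(P+R)      MOTA = 1 − (FN + FP + mismatches)/total_gt

  with mismatches = 0 for static fruits, plus a breakdown of *why* a
  line-crossing counter missed each object;
* a **simulator** of a camera pass along a tree row (static fruits, constant
  vertical image flow) with a detector-failure model — flicker, entry
  occlusion, localization jitter, false positives, confidence noise, and
  per-fruit appearance embeddings — so the whole pipeline is testable without
  any video data;
* **training utilities** for the detector side: a linear-warmup multi-step
  learning-rate schedule, a 70:10:10:10 source-stratified dataset split,
  k-means anchor clustering under the 1 − IoU distance, and a staged
  error-gap (bias / overfit / data-mismatch / validation-overfit) report.

## Worked example

Write a small run configuration:

```yaml
# run.yaml
seed: 11
output_dir: demo
simulator:
  scene: {n_fruits: 20}
  corruption: {p_miss: 0.15}
```

and run the full pipeline:

```text
$ pearcount pipeline -c run.yaml
INFO pearcount: simulate: 960 frames, 20 objects in 0.18s
INFO pearcount: track: 252 tracks over 948 frames in 0.56s (1697.4 frames/s; real-time bar is 24)
INFO pearcount: count[unique_id] = 22
INFO pearcount: count[roi_line] = 18
INFO pearcount: count[unique_id_lifespan] = 19
INFO pearcount: eval[unique_id]: F1_count=95.24% MOTA=90.00%
INFO pearcount: eval[roi_line]: F1_count=94.74% MOTA=90.00%
INFO pearcount: eval[unique_id_lifespan]: F1_count=87.18% MOTA=75.00%
```

The scene contains 20 fruits filmed over 960 frames with 15 % per-frame
detection dropout. The unique-ID counter reports 22 — every fruit plus two
flicker-born track fragments (recall 100 %, precision 90.91 %). The ROI-line
counter at half frame height reports 18 — it filtered both fragments (no
false positives) but missed two fruits that were first picked up too close to
or beyond the line, as the miss breakdown records:

```text
$ cat demo/count_eval.csv
metric,unique_id,roi_line,unique_id_lifespan
MOTA,90.0,90.0,75.0
FN rate,0.0,10.0,15.0
FP rate,10.0,0.0,10.0
Precision_count,90.91,100.0,89.47
Recall_count,100.0,90.0,85.0
F1_count,95.24,94.74,87.18

$ cat demo/fn_breakdown.csv
category,count
never_detected,0
detected_only_after_line,1
detected_near_line,1
detected_other,0
```

This is the characteristic trade-off the toolkit is built to measure: unique
IDs are sensitive but over-count under flicker; the ROI line is precise but
under-counts whatever the detector acquires late.

The same stages run individually (`pearcount simulate|track|count|eval-count
-c run.yaml`), and `pearcount track` works equally on a `det.txt` produced by
a real detector instead of the simulator. The library surface mirrors the
CLI; see `pearcount.run_tracker`, `pearcount.count_roi_line`,
`pearcount.evaluate_detections`, and friends.

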