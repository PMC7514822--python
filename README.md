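# xraypipe

Entropy-based segmentation and fracture detection for long-bone (forearm)
radiographs, plus a synthetic phantom generator with exact ground truth.

The pipeline chains five stages:

1. **align** — pad the frame, binarise, morphologically close, estimate the
   collimation-box axis by PCA over white-pixel coordinates, rotate upright
   with Lanczos resampling over an 8×8 neighbourhood.
2. **entropy_seg** — per-pixel sliding-window Shannon entropy weighted by the
   window standard deviation (window 9×9, log base 2, mirrored borders);
   row-wise peak detection (plateau merge + 20% of row maximum threshold)
   produces a binary line-edge image. Tile-entropy scores (image entropy,
   segmentation entropy, combined global entropy) measure residual noise, and
   Canny/Laplacian/Sobel baselines are wired in for comparison.
3. **roi** — top boundary from the jump in row-peak counts (searched in the
   central 50% of rows, peaks ≥ 95% of the band maximum, deepest row wins);
   lateral boundaries from the per-row four highest peaks, averaged and
   expanded by 20%.
4. **bone_graph** — every bottom-row white pixel roots a tree grown upward by
   nearest-white-pixel search (5 rows up, ±5 columns, Euclidean ties kept);
   root-to-leaf paths spanning > 60% of the image height survive, and
   contours within 15 px are merged row-wise into at most four bone lines.
5. **fracture** — per bone line: crop the top 20% curvature at the fitted
   quadratic vertex, fit a 3rd-order "ideal healthy" polynomial, and track
   residual runs beyond a 3 px tolerance; qualifying deviation areas flag the
   image and are localised with a circle.

`evalmetrics` provides confusion-matrix bookkeeping and the nine derived
rates (sensitivity, specificity, precision, NPV, FPR, FDR, FNR, accuracy,
F1), and `phantom` renders seeded, bit-reproducible test images with known
box angle, bone-edge coordinates and fracture location.

## CLI

```bash
# generate 10 phantoms (30% fractured) with ground-truth sidecars
xraypipe phantom --n 10 --seed 1 --fracture-rate 0.3 --out-dir scratch/phantoms

# full pipeline on one image
xraypipe run scratch/phantoms/phantom_0000.png --out report.json

# individual stages
xraypipe align   input.png --out aligned.png
xraypipe segment input.png --out edges.png --score-out score.json
xraypipe roi     input.png --out roi.png --box-out box.json
xraypipe trace   roi.png   --out lines.csv --overlay overlay.png
xraypipe detect  lines.csv --out report.json
xraypipe evaluate --pred-dir preds/ --truth-dir truths/ --out metrics.json
```

All hyperparameters live in a YAML config (`PipelineConfig`); pass
`--config cfg.yaml` to any stage-aware subcommand.

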