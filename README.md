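# nucleidict

Detection of individual cell nuclei in single-channel fluorescence
micrographs, using a convex active-contour segmentation coupled to a
sparse dictionary of disk-shaped atoms. The package is aimed at
quantitative microscopy workflows (e.g. counting DAPI-stained nuclei of
peripheral blood mononuclear cells) where nuclei are blurred, unevenly
illuminated, clustered into touching groups, and surrounded by clutter
such as apoptotic debris — conditions under which plain thresholding or
edge-based detectors either merge touching nuclei or hallucinate
detections.

## The model

An image `f` (normalized to [0, 1]) is segmented by a relaxed labeling
`u : Ω → [0, 1]` that minimizes, jointly with per-radius atom-coefficient
maps `t_r : Ω → [0, 1]`, the convex energy

```
E(u, t) = TV(u) + μ ⟨u, s⟩ + λ Σ_{r,x} |t_r(x)| + (α/2) ‖u − D t‖₂²
s(x)    = (c₁ − f(x))² − (c₂ − f(x))²
```

where

* `TV(u)` is the isotropic total variation (the active-contour perimeter
  term),
* `s` is the active-contour-without-edges data term with expected
  foreground/background intensities `c₁ > c₂` (estimated per image from
  an Otsu split),
* `D` is the *dictionary synthesis operator*: `D t = Σ_r k_r * t_r`, the
  superposition of binary disk atoms `k_r` over a discretized interval of
  nucleus radii — a shape prior that represents any legal segmentation as
  a sum of disks and penalizes overlapping nuclei,
* the `ℓ₁` penalty (weight `λ`) is the convex surrogate for the nucleus
  count, keeping the decomposition sparse,
* the quadratic term (weight `α`) relaxes the hard constraint `u = D t`,
  so nuclei may deviate slightly from the disk model.

The energy is minimized by alternating a primal-dual update of `u` with
clipped proximal (soft-threshold) sweeps of `t`; both fields stay in
[0, 1] exactly and the energy trace is non-increasing by construction.
Detections are then read off the coefficients: per-pixel dominant radius
and summed coefficient image `T`, Otsu binarization of `T`, morphological
closing, masking by an opening-based clutter filter, 8-connected
components scored by mean preprocessed intensity, and greedy non-maximum
suppression within each accepted candidate's dominant radius.

Validation uses the field's standard point-matching metrics — precision,
recall and F-measure under a 3.2 µm match radius with one-to-one
closest-pair matching — plus the per-image nucleus-count RMSE and the
whole-image Dice coefficient of the binarized segmentation.

## Worked example

The built-in generator produces benchmark-style micrographs with exact
ground truth (touching nuclei, illumination gradient, an oversized
clutter blob, blur and noise):

```python
import numpy as np
import nucleidict as nd

# one synthetic micrograph: 30 nuclei of radius 10 px, 30% touching,
# blur, illumination gradient, one clutter blob, Gaussian noise
sample = nd.generate(nd.FixtureConfig(seed=0))

detections, preprocessed, seg = nd.detect_image(sample.image, nd.RunConfig())
print(f"{len(detections)} nuclei detected / {len(sample.truth_centroids)} true")
print("first detection:", detections[0])

report = nd.evaluate(
    [np.array([d.centroid for d in detections])],
    [sample.truth_centroids],
    seg_masks=[nd.threshold_u(seg.u, 0.5)],
    truth_masks=[sample.truth_mask],
)
print(report.as_text())
```

prints

```
30 nuclei detected / 30 true
first detection: Detection(centroid=(207.22222222222223, 26.444444444444443), dominant_radius=10.0, score=0.785033920083359)
count RMSE : 0.0000
precision  : 1.0000
recall     : 1.0000
F-measure  : 1.0000
TP/FP/FN   : 30/0/0
Dice       : 0.8514
```

All 30 nuclei — including the touching pairs — are found with no false
positives, each assigned the correct dictionary radius (10 px); the
clutter blob is rejected by the opening-based mask. The Dice value
compares the raw binarized segmentation against the pre-blur union of
true disks, so it reflects the blurred object boundaries and the clutter
blob that segmentation (correctly) labels as bright foreground.

The same pipeline is available from the shell:

```sh
nucleidict fixtures --n-images 2 --out fixtures/
nucleidict detect fixtures/fixture_000.tif --r-min 10 --r-max 10 --out results/
nucleidict evaluate --detections results/fixture_000_detections.csv \
                    --truths fixtures/fixture_000_truth.csv --out results/
```

`detect` writes one CSV per image (`x_px, y_px, radius_px, score`) and
the effective YAML configuration next to the outputs; radii may also be
given in micrometres (`DictionarySpec(units="um")` plus
`--pixel-size-um`).

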