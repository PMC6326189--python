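# vertseg

Semi-automatic segmentation of vertebral bodies in sagittal lumbar-spine MR
images — from **one** user-drawn ROI.

Quantitative spine MRI (volumes, shape biomarkers, morphometry) needs each
vertebral body delineated, but fully manual outlining is slow and most
classical pipelines still demand a seed or ROI *per body* plus algorithm
parameters. `vertseg` reduces the user's role to a single rectangle around
any one vertebral body:

1. **Detection** — the user box is matched across the image by zero-mean
   normalised cross-correlation (ZNCC),

   `r(p) = Σ (T − T̄)(I_p − Ī_p) / √(Σ(T − T̄)² Σ(I_p − Ī_p)²)`,

   and the remaining bodies are found by iterative peak search with
   neighbourhood suppression, guided by the reference distance `d` between
   the first two peaks. Intervertebral-disc correlation then corrects
   horizontal positions (bodies deviating from the disc line by more than
   `0.1·ly` are snapped to it).
2. **ROI refinement** — Canny edges + Hough transform estimate each body's
   rotation (the angle whose projection extent is minimal) and the ROI is
   counter-rotated; edge-projection profiles `Px`, `Py` detect clipped
   sides and grow the ROI until the body fits.
3. **Segmentation** — edge projections give approximate vertices
   `(bL, bU), (bR, bU), (bL, bD), (bR, bD)`; the surrounding band is split
   into four side bands and eight corner triangles. Superior/inferior
   boundaries come from a minimum-cost monotone path (dark cortical rim =
   cheapest traversal); lateral boundaries come from per-line rules on a
   10-level k-means clustering of the ROI; corner triangles are padded to
   parallelograms and handled likewise. A cubic fit per side removes
   outliers and the closed contour is rasterised into one mask per body.
4. **Evaluation** — Dice similarity coefficient
   `DSC = 2|A∩B| / (|A|+|B|)`, voxel counts, physical volumes
   (`0.39 mm` pixel spacing, `3 mm` slice thickness by default), and mean
   center detection error.

A synthetic spine-phantom generator (`vertseg.phantom`) provides stacked
rounded-rectangle bodies with dark rims, discs, noise, bias fields and
exact ground truth, so every stage is testable without MR data.

## Worked example

```python
from vertseg import PhantomSpec, RoiBox, generate_phantom, run_pipeline

# a 5-body phantom with mild noise, and the single user ROI on body 3
image, truth = generate_phantom(PhantomSpec(n_bodies=5, seed=3, noise_sigma=0.02))
roi = RoiBox(center=truth.centers[2], lx=72, ly=52)

result = run_pipeline(image, roi, reference_masks=truth.masks,
                      true_centers=truth.centers)
print(f"bodies found : {len(result.masks)}")
print(f"mean DSC     : {result.report.dsc_mean:.3f}")
print(f"center error : {result.report.detection_error_px:.2f} px")
```

prints

```
bodies found : 5
mean DSC     : 0.943
center error : 1.05 px
```

i.e. all five vertebral bodies were recovered from the one ROI, each mask
overlaps its ground truth at DSC ≈ 0.94 (the truth includes the full
cortical rim while the boundary tracks the mid-rim line, which caps the
attainable score near 0.95 — see `docs/methods.md`), and detected centers
sit within a pixel of the true ones.

The same pipeline is available from the shell:

```bash
vertseg phantom --seed 3 --out spine.png --truth-dir truth/
vertseg run-all --image spine.png --roi 176,80,72,52 --ref-dir truth/ --out-dir out/
vertseg detect --image spine.png --roi 176,80,72,52        # centers as JSON
vertseg evaluate --pred out/mask_1.png --ref truth/truth_1.png
```

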