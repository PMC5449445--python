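# vicar — visual-cues adaptive registration for time-lapse microfluidics imagery

Time-lapse phase-contrast series from microfluidics chambers drift: thermal
gradients and vibrations slowly translate and rotate the whole visual field
while the imaged bacterial colony doubles in size every generation. Classical
registration fails here — the foreground changes too fast for
intensity-matching methods, and there are no reusable landmarks across
experiments. What *is* stable are the chamber's structural **spacers**:
square-like elements fixed relative to the chamber and visible in every frame.

`vicar` registers a series of `T` frames `I_1 … I_T` to its first frame by:

1. **Preprocessing** each frame into a binary mask (bilateral denoising with
   σ_spatial = σ_range = 75 over a 10 px neighborhood, CLAHE with 10×10 px
   tiles and contrast limit 2, adaptive mean thresholding over 11×11 px
   blocks minus a constant 2, 3×3 dilation, border clearing, and a central
   circular mask of diameter 0.6 r).
2. **Polygon finding**: border following extracts each connected component's
   closed outer boundary `P_j`, scored by the perimeter-to-area ratio
   `r_j = S_j / A_j`. Polygons with `r_j < 5·10⁻²` are the **visual cues**
   (spacers are large and simple; cells and noise are small or ragged). If
   nothing passes, all polygons are retained as a fallback.
3. **Control points**: depending on the number of cues J, three control
   points per frame come from the oriented bounding box of a single cue
   (J = 1), the OBB corners of two cues (J = 2), or cue centers (J ≥ 3).
   The series is partitioned into maximal runs of constant J; runs are
   registered independently and bridged through matched cue subsets.
4. **Affine solve**: three point correspondences determine the 2×3 affine
   matrix exactly; pairwise transforms are chained to the reference frame
   and each frame is re-solved against the reference cue set, then warped
   (bilinear, RGB channel-wise).

Registration quality is reported as the root mean square distance (rmsd, px)
of cue positions relative to frame 1 and the **image closeness**
`Φ = 100 − rmsd·100/r` (percent, `r` = image rows). A probabilistic Hough
transform (PHT) baseline — Canny edges, PHT segments, a best-fitted
four-point subset, rigid least squares — is included for comparison; it
requires straight structural edges and raises a documented failure on scenes
without them.

A synthetic scene generator emulates the real data (1004×1002 px frames,
drifting chamber with dark square spacers, a colony doubling every 10 frames,
background gradient, Gaussian sensor noise) with exact ground-truth
transforms, so the entire pipeline is testable without any download.

## Worked example

```python
from vicar import (PreprocessConfig, SceneConfig, SeriesRegistration,
                   make_scene, render_series)
from vicar.evaluation import evaluate_registration, ground_truth_rmsd

scene = make_scene(
    SceneConfig(rows=512, cols=512, n_frames=4, spacer_ring_radius=105,
                spacer_side_min=115, spacer_side_max=125, max_step_px=1.5),
    seed=7,
)
series, truth = render_series(scene)

model = SeriesRegistration(
    series, preprocess_config=PreprocessConfig(mask_diameter_fraction=0.9)
)
result = model.fit()
print(result.summary())

report = evaluate_registration(result, model)
print(f"mean rmsd = {report.mean_rmsd:.3f} px   closeness = {report.closeness:.2f} %")
print(f"ground-truth transform error = {ground_truth_rmsd(result, truth):.3f} px")
```

prints

```
ViCAR series registration
==================================
frames:              4
registered:          4/4
constant-J runs:     [1..4] J=4
mean elapsed/frame:  0.176 s

 t       a       b      tx       c       d      ty scenario  J     status
 1  1.0000  0.0000  0.0000  0.0000  1.0000  0.0000        -  4  reference
 2  1.0006  0.0067 -2.7260 -0.0062  0.9982  1.7824        c  4 registered
 3  0.9992  0.0111 -2.7372 -0.0111  1.0023  3.0345        c  4 registered
 4  1.0000  0.0112 -1.5941 -0.0099  1.0021  4.0865        c  4 registered

mean rmsd = 0.328 px   closeness = 99.94 %
ground-truth transform error = 0.227 px
```

All four spacers were found in every frame (J = 4, scenario c), each frame's
2×3 affine matrix `[[a, b, tx], [c, d, ty]]` undoes the simulated drift
(translations of a few px, rotations ≲ 0.01 rad), cues re-detected in the
warped frames land within a third of a pixel of the reference cues
(Φ ≈ 99.9 %), and the fitted transforms agree with the generator's hidden
ground truth to 0.23 px.

The same pipeline is scriptable from a shell:

```sh
vicar simulate --out run/sim --seed 7 --config run.yaml
vicar register --input 'run/sim/frames/*.tif' --out run/reg --config run.yaml
vicar evaluate --input 'run/sim/frames/*.tif' --out run/eval --method vicar --method pht
```

`register` writes the warped TIFF series plus a per-frame transforms CSV;
`evaluate` writes a benchmark table (method × Δt_c / rmsd / Φ, with failures
recorded as `failed`, never as zeros).

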