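# tracequant

Quantitative analysis of fluorescence tract-tracing micrographs: from raw
retrograde (labeled somata, e.g. fluorogold) or anterograde (labeled axonal
fibers, e.g. BDA) images to a regional connectivity table and exact
between-cohort statistics.

Neuroanatomical tracing studies summarize where a tracer injection labels
the brain: retrograde label marks areas *projecting to* the injection site,
anterograde label marks areas *receiving from* it. `tracequant` implements
the whole quantitative chain for such studies and validates every stage on
seeded synthetic micrographs with known ground truth, so the pipeline can
be tested without access to the original imaging data.

## Method

For each micrograph, with polygon ROIs supplied per anatomical area:

1. **Preparation** — grayscale conversion (unweighted channel mean),
   Gaussian-convoluted background subtraction (σ = 20 px), Gaussian
   smoothing (σ = 3.5 px) to suppress acquisition artifacts.
2. **Adaptive thresholding** — over a user-chosen *background* ROI (a
   patch with no labeled cells or fibers) compute the luminance mean and
   population variance and threshold at

   `L_thresh = L_mean(ROI) + L_σ²(ROI)`

   (0–255 luminance scale; strict `>` comparison). Pixels above threshold
   form the binary label mask; injection-site extent is documented by
   tracing closed contours around the mask's connected components.
3. **Quantification** — retrograde: 8-connected component counting with
   size filters and local-maximum-seeded watershed splitting of touching
   somata, each detection attributed to the ROI holding the majority of
   its pixels; anterograde: percent of ROI area carrying signal.
4. **Normalization and categorization** — retrograde counts are expressed
   per animal as percent of all labeled cells in that animal
   (percent-of-total, summing to 100), averaged across the cohort, and
   summarized on the five-symbol scale
   `−` (0%), `+` (< 2.5%), `++` (< 5%), `+++` (5–7.5%), `++++` (> 7.5%).
5. **Statistics** — preference between two complementary regions a, b is
   the per-case modulation index

   `MI = (Q_a − Q_b) / (Q_a + Q_b)  ∈ [−1, 1]`

   with Q the quantified tracer amount (count or percent area); injection
   groups are compared with an **exact** two-sided Mann–Whitney U test
   (α = 0.05), computed from the full permutation null distribution — the
   cohorts are far too small for the normal approximation.

A `synthgen` module generates the validation data: retrograde scenes
(truncated-Gaussian somata on a textured, noisy background with bright
debris specks), anterograde scenes (dilated random-walk fiber strokes with
a controllable on-pixel fraction and exact truth mask), and cohort count
tables with a tunable group-preference effect (default cohort sizes 5 vs 4
injections).

## Worked example

```python
import numpy as np
import tracequant as tq

# a synthetic retrograde micrograph with 6 somata and a label-free patch
rng = np.random.default_rng(0)
cells = tq.random_cell_truth(6, (256, 256), radius=3.5, peak=150.0,
                             min_separation=16.0, rng=rng, exclude=(0, 0, 64, 64))
scene = tq.SyntheticScene(cells=cells, seed=0, artifact_count=3,
                          clear_patch=(0, 0, 64, 64))
m, truth = tq.make_retrograde_scene(scene)

# prepare, threshold against the background ROI, count
subtracted = tq.subtract_background(m, sigma=20.0)
smoothed = tq.smooth(subtracted, sigma=3.5)
bg = tq.RoiSpec("bg", "ipsi", ((4, 4), (58, 4), (58, 58), (4, 58)), "background")
stats = tq.threshold_stats(subtracted, bg)
print(f"L_mean = {stats.l_mean:.2f}, L_var = {stats.l_var:.2f}, "
      f"L_thresh = {stats.l_thresh:.2f}")

mask = tq.binarize(smoothed, stats)
roi = tq.RoiSpec("M2", "ipsi", ((0, 0), (255, 0), (255, 255), (0, 255)), "measurement")
detections = tq.count_cells(mask, roi, image=smoothed)
print(f"true somata: {len(truth)}, detected: {len(detections)}")

# exact group comparison of modulation indices (5 vs 4 cases)
mi_scm = [0.85, 0.71, 0.64, 0.92, 0.55]
mi_scl = [-0.48, -0.70, -0.35, -0.61]
res = tq.mannwhitney_exact(mi_scm, mi_scl)
print(f"U = {res.u_stat:g}, p = {tq.format_p(res.p_value)}, "
      f"significant at alpha {res.alpha}: {res.significant}")
```

prints

```
L_mean = 4.95, L_var = 38.55, L_thresh = 43.51
true somata: 6, detected: 6
U = 0, p = .016, significant at alpha 0.05: True
```

The threshold sits well above the background (mean ≈ 5) thanks to the
variance term; all six ground-truth somata are recovered. The two MI
groups are completely separated, so the exact two-sided p reaches its
minimum for cohorts of 5 and 4, `2/126 = 0.0159`, displayed as `.016`.

A full cohort is driven either through the library
(`tracequant.report.run_pipeline`) or the CLI:

```
tracequant simulate --config scene.yaml --out scene.tif
tracequant run --config pipeline.yaml --manifest cohort.yaml --out results/
```

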