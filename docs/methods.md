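# Methods

This note documents the models, conventions and numerical choices behind
`tracequant`, in the order the pipeline runs.

## Luminance scale and image preparation

All computation is defined on the 0–255 (8-bit-style) luminance scale.
This matters because the adaptive threshold `L_thresh = L_mean + L_var` is
dimensionally inhomogeneous — a variance is added to a mean — so its
behaviour depends on the scale: on a [0, 1] scale the variance term is
negligible, on 0–255 it supplies the noise margin that makes the formula
work. 16-bit input is therefore linearly rescaled to 0–255 on load, and
`Micrograph` rejects out-of-range rasters.

Preparation order is grayscale → background subtraction → smoothing →
threshold. Grayscale conversion of multichannel input uses the unweighted
channel mean (tracer fluorescence has no reason to follow photometric RGB
weights). Background subtraction removes a Gaussian blur of the image from
itself (default σ = 20 px, the retrograde workflow value) and clamps at
zero; smoothing is a Gaussian low-pass (default σ = 3.5 px). Both use
reflective padding: it conserves total intensity to floating-point
tolerance and avoids dark rims at the frame edge that would bias
background estimates.

Two deliberate deviations from a naive single pass:

* **Threshold statistics are computed on the subtracted-but-unsmoothed
  image**, while the binary mask is cut from the smoothed one. Smoothing
  suppresses exactly the pixel-noise variance that gives `L_mean + L_var`
  its margin; computed after smoothing, the threshold collapses onto the
  background mean and fluctuates with the (heavily correlated, hence
  poorly sampled) residual texture variance, producing large spurious
  foreground. The pre-smoothing ROI still contains the full noise
  variance, giving a stable threshold several noise standard deviations
  above the background.
* **Anterograde images are not smoothed by default** (`smooth_anterograde`
  flag). Labeled fibers are 1–3 px wide; a σ = 3.5 px blur spreads each
  stroke's above-threshold footprint to many times its true width and
  destroys the percent-area estimate. Somata (≈ 7 px across) survive
  smoothing with their area roughly intact, so the retrograde path keeps
  it.

## Thresholding conventions

* `L_var` is the **population** variance (divide by N): deterministic on
  tiny ROIs and the plain reading of "variance of the luminance" with no
  stated correction.
* Binarization uses strict `>`: a flat ROI (zero variance) then yields an
  empty mask rather than all-foreground.
* A pixel belongs to a polygon ROI iff its **center** lies inside the
  polygon (vertices in x-right/y-down pixel coordinates, 0-based). Only
  simple polygons are accepted, for which the even-odd and winding fill
  rules coincide.
* Background ROIs must be placed on regions free of labeled structures —
  a labeled cell inside the background ROI inflates `L_var`
  quadratically and can push the threshold above the signal.

## Contours

Injection-site extent is documented by tracing one closed contour per
8-connected foreground component (marching squares at the half-pixel
level on the padded component mask; holes ignored). Components below a
configurable minimum area (default 5 px) are treated as speckle. Contours
are ordered by descending component area, and re-rasterizing a contour
reproduces the component's filled mask exactly under the pixel-center
rule, so overlap of two injection cases can be computed as mask
intersection.

## Cell detection

Foreground components are 8-connected. Each component is examined for
multiple strong intensity maxima (`peak_local_max`, minimum peak distance
7 px, secondary peaks below half the component maximum ignored as texture
ripple) and split by watershed on the negated intensity when more than one
is found; the distance transform substitutes when no intensity image is
available. Splitting is attempted on *every* component, not only oversized
ones: two somata joined by a dim bridge of supra-threshold background need
not exceed the maximum cell area, and splitting a component with a single
maximum is a no-op. Pieces are then filtered to the configured size window
(defaults 10–400 px at the synthetic scale; the original workflow's
filters are not published) and attributed to the ROI containing a strict
majority of their pixels, so a border-straddling soma counts in exactly
one area (an exact 50/50 split counts in neither).

## Normalization, categorization, statistics

Percent-of-total divides each area's count by the animal's total labeled
cells (×100). Ipsi- and contralateral areas are distinct entries and both
enter the denominator, since cohort tables report both hemispheres on one
scale; this is a convention — whether the original normalization included
contralateral counts is not stated. Animals with zero labeled cells
cannot be normalized and are excluded with an error.

The five-level category is assigned to the **across-animal mean**
percentage, not per animal. The published legend's edges are ambiguous
("high < 7.5%" in the legend vs "high 5–7.5%" in the text); the resolution
here is: `−` iff exactly 0, `+` on (0, 2.5), `++` on [2.5, 5), `+++` on
[5, 7.5], `++++` above 7.5. The anterograde five-level score was a visual
judgement in the original workflow; `anterograde_level` provides a
quantitative surrogate (half-open binning of percent area on four
configurable cut points, defaulting to the retrograde breakpoints) and is
labeled as a surrogate in output metadata.

The modulation index `MI = (Q_a − Q_b)/(Q_a + Q_b)` is undefined when
both quantities are zero; such cases are excluded, not imputed. Group
comparisons use an exact two-sided Mann–Whitney U test: U = min(U₁, U₂),
and p is twice the probability, over all C(n₁+n₂, n₁) equally likely
assignments of the pooled values to groups, of a U₁ at or beyond the
observed one (capped at 1). Doubling the one-sided exact tail is the
standard small-sample convention and yields the familiar minimum
p = 2/126 ≈ .016 for completely separated cohorts of 5 and 4. Pooled-
distinct data use a dynamic-programming recursion for the null counts of
U; any ties are handled with midranks and full enumeration over
assignments of the observed multiset (a tie-corrected normal
approximation is used only beyond ~5·10⁵ assignments, far larger than the
cohorts this pipeline targets). No multiple-testing correction is applied,
matching the original analysis. Displayed p-values use three decimals with
leading-zero suppression (".016"); machine outputs keep full precision.

## Synthetic data

The generators emulate the statistical structure the analysis assumes:

* **Retrograde scenes** — somata are isotropic 2-D Gaussian intensity
  profiles (default radius 3.5 px, peak 150 above background) truncated
  at 3 radii, on a background of base level 20, an optional linear
  gradient, correlated "tissue mottle" texture (Gaussian field, σ = 2 px,
  amplitude s.d. 11) emulating structured autofluorescence, additive
  Gaussian pixel noise (s.d. 3) clipped to 0–255, and a few near-
  saturating 1–4 px debris specks. A warning is recorded when more than
  20% of soma pairs sit closer than 4 radii (counting validation assumes
  separable blobs).
* **Anterograde scenes** — fibers are random-walk polylines dilated to
  1–3 px, accumulated until the on-pixel fraction reaches the target
  (individual strokes are short enough to keep the overshoot within the
  stated tolerance, default 0.02); the exact fiber mask is returned as
  ground truth. Fractions above 0.9 are rejected as unrealistic
  saturation.
* **Cohort tables** — two injection groups (default sizes 5 and 4, the
  study design this pipeline mirrors) with per-area expected proportions
  summing to 1. A signed per-area effect in [−1, 1] shifts that area's
  share toward one group; magnitude 1 removes it entirely from the other
  group, guaranteeing complete modulation-index separation. Per-animal
  proportions receive log-normal jitter (s.d. = `dispersion`; 0 means
  exact) and are realized as integer counts by largest-remainder
  rounding, so each animal's counts sum exactly to `cells_per_animal`
  (default 1000).

Scenes reserve an optional `clear_patch` rectangle kept free of label,
where validation places the background ROI — the synthetic counterpart of
choosing a non-labeled region on a real section.

What the generators do **not** model: optics (PSF), nuclear counterstain
channels, section-to-section registration, uneven staining, or realistic
soma morphology. Passing the recovery tests therefore shows the
*algorithmic* chain is correct under the stated statistical assumptions,
not that the parameters are optimal for any particular real dataset.

## Problem sizes used in validation

Recovery tests use 256×256 rasters: 50 retrograde scenes with 3–11 somata
separated by > 4.5 radii (≥ 95% of scenes must yield the exact truth
count; centroid error stays below 2 px) and 50 anterograde scenes with
target fractions 0.05–0.5 (percent area within 3 percentage points of
target). The exact-test implementation is checked against brute-force
enumeration on 1000 random datasets with n₁+n₂ ≤ 10 (agreement to 10⁻¹²)
and against an independent library implementation on tie-free data. These
sizes make the whole suite run in well under a minute while exercising
every failure mode the larger-scale analysis would meet.

## Known limitations

* The mean-plus-variance threshold is scale-dependent by construction;
  images must be on (or rescaled to) 0–255.
* Watershed splitting resolves touching somata only when their intensity
  peaks are ≥ 7 px apart and comparable in height; dense clusters are
  undercounted.
* The exact test's tie handling enumerates group assignments and is
  limited to small cohorts (the intended regime).
* ROIs are consumed as given; no atlas registration, 3-D reconstruction
  or illumination flat-fielding beyond the stated background subtraction.
* Confidence intervals on percent-of-total are not computed (the original
  figures' interval construction is unspecified); only the exact U test
  is offered inferentially.
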