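# Methods

This note documents the models and procedures implemented in `bollmark`,
the parameter defaults and why they were chosen, what the synthetic data
emulate (and what they do not), and the numerical decisions taken where
the published description of this kind of pipeline leaves the design open.

## Imaging model

The raw input is a 16-bit RGB TIFF carrying 12-bit camera data of a cotton
boll against a non-fluorescent black backdrop, illuminated with blue LEDs
behind a longpass emission filter. Intact tissue emits red (chlorophyll);
wound-response tissue emits green. The pipeline is a fixed chain:

1. **Center-weighted median filter** (window 3, center weight 3,
   edge-replicated borders): impulse-noise suppression that respects fine
   structure better than a plain median. Both the window and weight are
   configurable; weight 1 reduces to the ordinary median filter.
2. **2×2 binning** (block mean): halves the resolution. Raw frames at
   36 px/mm become analysis frames at 18 px/mm, the scale at which all
   pixel-denominated constants below are expressed.
3. **Boll mask**: one channel (default red — the chlorophyll emission is
   the reliable "this is boll" signal; configurable to green) is blurred
   with a second-order Butterworth low-pass and thresholded; the largest
   connected component is kept, specks under 100 px dropped. The
   Butterworth cutoff is a spatial wavelength of 10 px, i.e.
   f_c = 0.1 cycles/px — a cutoff *frequency* of 10 px⁻¹ would exceed the
   Nyquist limit (0.5 px⁻¹) twentyfold and is physically meaningless. The
   filter applies the standard −3 dB amplitude response
   |H(f)| = (1 + (f/f_c)^(2n))^(−1/2), so a sinusoid exactly at the
   cutoff is attenuated by 1/√2 and the mean (DC) is preserved.
4. **Ratiometric image**: green / max(red, ε) with ε = one 12-bit count,
   multiplied by the mask, so the background is exactly zero and the
   division can never blow up.

Two guards protect the ratio against mask-boundary artifacts. The
automatic threshold is 5% of the blurred channel's maximum — the black
backdrop makes the mask insensitive over a wide threshold range (tested:
< 10% area change between 5% and 50%) — but never below an absolute floor
of 100 counts, so a frame with no boll yields an empty mask rather than an
all-ones mask. The final mask is then eroded by 4 px (configurable):
the blurred-threshold boundary overhangs the true boll edge by a few
pixels, and in that halo the red channel is at backdrop level, so the
green/red quotient spikes meaninglessly.

## Detection and segmentation

**Candidate peaks.** The ratio image is mapped to 12-bit counts with a
*fixed* scale (ratio 4.0 → 4095 counts; green emission four times the red
is a generous upper bound for boll fluorescence). A pixel is a candidate
when it is a 3×3 local maximum inside the boll and exceeds the mean of the
surrounding 15-px-radius disk (restricted to the boll) by at least 10
counts; accepted peaks are at least 15 px apart, higher values win, ties
break in row-major order. The fixed count scale is deliberate: scaling by
the per-image maximum would make the 10-count threshold adaptive, and on a
mark-free boll pure sensor noise would fill the full scale and flood the
detector. Peaks closer than 8 px to the mask boundary are dropped — at
the silhouette the ratio mixes boll and backdrop pixels and the mask rim
itself presents a spurious intensity step. A per-image candidate cap
(default 50, strongest first) bounds the segmentation workload; genuine
marks are always the strongest peaks.

**Greedy snake.** Each candidate seeds a closed 32-vertex polygon,
initialised as a circle larger than the mark: its center is the centroid
of the half-prominence blob under the peak (robust when the peak sits on a
donut ring rather than at the mark center) and its radius is 1.5× the
mark extent read off the azimuthal-mean radial profile (last radius above
local mean + ¼ prominence, so the attenuated donut core is skipped),
clipped to [4, 40] px. The energy is

    E = α·Σᵢ |vᵢ₊₁ − vᵢ|            (stretching)
      + β·Σᵢ |vᵢ₊₁ − 2vᵢ + vᵢ₋₁|    (bending, second differences)
      − γ·Σᵢ g(vᵢ)                  (gradient attraction)

with cyclic indices, bilinear sampling of the Sobel gradient magnitude g,
and defaults α = 1, β = 0.5, γ = 2. Second differences are used for the
bending term because first differences would duplicate the stretching term
and collapse the three-term sum to two. The gradient image is normalised
by the Sobel response of a unit ratio step (4.0), not by its per-image
maximum, for the same robustness reason as above: on a low-contrast boll,
noise gradients must stay near zero rather than being inflated to full
scale.

Each iteration runs a sequential greedy sweep — every vertex moves to the
position in its 3×3 neighborhood that lowers the local energy terms it
appears in, ties favoring staying put, moves creating self-intersections
rejected — followed by a trial *uniform shrink* of the polygon toward its
centroid (by the 1-px search radius), kept only when it lowers the total
energy. The shrink step deserves a note: with raw-length stretching, the
inward sagitta of a smooth 32-gon (~0.02·r px) is far below the 1-px move
granularity, so no single-vertex move can shorten a smooth contour and
pure per-vertex greedy descent is frozen on flat terrain. The uniform
shrink is exactly the "regular, circular contraction" a gradient-seeking
contour should show: internal energy scales linearly with radius, so the
shrink is always accepted on flat ground and always rejected once the
contour sits on a gradient ridge strong enough that leaving it costs more
than the internal saving. Total energy is non-increasing by construction.
Evolution converges when both the sweep (< 5% of vertices moved) and the
shrink make no progress, or gives up at 200 iterations with a warning.

On noise-only candidates there is no ridge to lock onto, so the snake
contracts to a point and the resulting degenerate/tiny region is removed
by the area filter — this is the mechanism behind the clean negative
control (0 retained marks across 30 mark-free scenes). On step-edge disks
of radius 5–20 px the recovered equivalent radius is within 0.5 px of
truth across 50 random placements.

The converged polygon is rasterized to the pixels whose centers fall
inside it (`skimage.draw.polygon`); an empty raster flags the mark
degenerate.

## Mark features and filters

* `area_mm2 = area_px / resolution²` (28 px at 18 px/mm ≈ 0.09 mm²).
* `integrated_intensity = Σ ratio over region / area_mm2` (mm⁻²) — the
  only dimensionalisation of a "per-area intensity" that yields mm⁻² from
  a dimensionless ratio.
* `aspect_ratio` = major/minor axis of the region's second-moment
  ellipse; collinear regions get ∞.
* `convexity` = region pixel count / pixel count of its convex hull,
  where the hull polygon of the pixel centers is rasterized with the same
  centers-inside rule as the region. This definition is exact (1.0) for
  convex digital shapes — disks, blocks, rectangles — at every size,
  strictly ≤ 1, and discriminates concave shapes well (an L of two 10×4
  arms scores 0.78). The common alternative, `area / rasterized hull
  image` (regionprops solidity), scores ideal digital disks as low as
  0.86 and would mis-calibrate the 0.9 threshold.

A mark is kept iff `area_px ≥ 28` AND `integrated_intensity ≥ 0.04` AND
`aspect_ratio ≤ 2` AND `convexity ≥ 0.9`; boundary semantics are exact
("below 28" excluded so 28 is kept; "greater than 2" excluded so 2.0 is
kept), and each rejected mark records the first rule it failed. Convexity
is an *inclusion* criterion: puncture marks are compact and round, while
ragged or elongated regions indicate abrasion.

**I1/I2.** The snake outline is converted to the equal-area circle at the
region centroid (r = √(area/π); equal-area rather than equal-perimeter
because area is the downstream classifier feature). I2 averages the ratio
image over pixels with centers inside that circle, I1 over the concentric
circle of radius 4 px; both circle memberships use the same ≤-boundary
rule, and I2 = 0 flags the mark invalid. The statistic requires
r > 4 px (the equivalent radius must exceed the inner circle), so very
small kept marks can carry an undefined ratio; they are never classified
positive. The 4-px inner radius at 18 px/mm corresponds to ≈ 0.155 mm².

## Classification and ROC

A mark is positive iff `A < 0.6 mm²` and `I1/I2 < 1.2`, strict
inequalities (marks exactly on a real-valued boundary have probability
zero). Contingency tables report counts and two percentage conventions:
pooled (denominator = both groups together, so cells of a criterion pair
sum to 100 across groups) and per-group. The ROC sweep evaluates the six
standard corner points (1.5, 1.4) … (0.4, 0.98) of the rectangle
diagonal; sensitivity = fraction of infested-labeled marks classified
positive, specificity = fraction of control-labeled marks classified
negative (1 − FPR). By the monotonicity of the rectangle rule,
sensitivity is non-increasing and specificity non-decreasing along the
shrinking sweep — asserted as an invariant.

## Statistics

All group comparisons are rank-based (the features are skewed).
Kruskal–Wallis uses the tie-corrected H with a χ²(k−1) p-value by
default; an exact mode (total n ≤ 13) enumerates every assignment of the
pooled values to the group sizes. Dunn's post test computes pairwise
z-scores from pooled mean ranks with the tie-corrected variance
S² = N(N+1)/12 − Σ(t³−t)/(12(N−1)); family-wise adjustment is Bonferroni
over the pairs (classic Dunn) with Holm as an option. The Wilcoxon
signed-rank test is two-sided, drops zero differences, uses the exact
null distribution for n ≤ 25 when the absolute differences are untied and
the tie-corrected normal approximation otherwise; it reports V⁺ (sum of
positive-difference ranks). Under null simulation (2000 replicates), each
test's type-I error at α = 0.05 lies in [0.03, 0.07].

## Synthetic data: what it emulates, and what it does not

The generator produces raw-scale scenes (default 384×384 px at 36 px/mm,
12-bit) containing: a black backdrop (30 counts), an elliptical boll with
red intensity 2200 counts, a green baseline at 0.55× the red level
(baseline ratio ≈ 0.55), and planted marks added to the green channel:

* **true positives** — sharp-edged disks with the central core (40% of
  the outer radius) attenuated by 50–70%, the donut profile of a puncture
  ("dark center where the wall was pierced");
* **needle punctures** — the same geometry, smaller and with stronger
  (75–85%) attenuation;
* **false positives** — center-bright irregular blobs: a sharp-rimmed
  filled disk plus a dominant central Gaussian and 1–3 offset lobes. The
  rim is a modeling choice: real fluorescent smudges have finite extent,
  and a pure Gaussian with no boundary is not lockable by any
  gradient-seeking contour.

Additive Gaussian noise (sd = 1% of the boll red intensity) goes on both
channels; all randomness flows from a single seed, and mark geometry is
seed-stable while noise varies. Planted marks are at least 30 raw px
(15 binned px) apart so the peak-spacing rule cannot merge them. Each
mark's ground truth (planted area = π·R² at the binned scale, planted
I1/I2) is computed from the *noiseless* rendered scene binned 2×2, using
the same equal-area-circle I1/I2 definition as the measurement path.

Feature tables are drawn directly from per-class log-normals — the right
family for positive, right-skewed size data — with medians at the study
group values (area 0.35 / 0.60 / 0.27 mm², ratio 0.96 / 1.20 / 0.86 for
infested / control / needle) and log-dispersions 0.25 (0.40 for the more
variable control class).

What the generator does **not** emulate: boll surface texture and lint,
specular structure, vignetting and illumination gradients, spatially
correlated noise, irregular boll silhouettes, marks at the silhouette
edge, and any within-boll correlation between mark size and intensity.
Passing tests therefore demonstrate the pipeline's correctness and its
noise robustness under this model, not field performance on real bolls —
the real-data detection rates depend on photographs this package cannot
ship.

## Problem sizes and determinism

The end-to-end suites use 50 generated scenes of 384×384 raw px with ~3–4
marks each and 50 step-edge disks on 128×128 frames — sizes chosen so the
whole test suite runs in about a minute on one CPU while every stage is
exercised at realistic mark scales. All pipeline stages are deterministic
given the input image; reruns produce bitwise-identical mark tables, and
every run report records the package version and a hash of the full
configuration.

## Known limitations

* The greedy snake settles slightly inside smooth (Gaussian-edged)
  boundaries, where the gradient ridge is broad; recovered areas of the
  synthetic false-positive class are accordingly biased low by ~20%.
  Sharp-edged marks (the puncture class) are recovered within a few
  percent.
* The integrated-intensity threshold (0.04 mm⁻²) is far below the values
  any plausible ratio-image mark produces under this dimensionalisation;
  in practice the area, aspect and convexity rules do the filtering.
* Marks whose equivalent radius is ≤ 4 px carry no I1/I2 and can never be
  classified positive; at 18 px/mm this puts a floor of ≈ 0.155 mm² on
  classifiable mark area, slightly above the 0.09 mm² retention floor.
* The classifier thresholds are fixed, not learned; a clustering- or
  ellipse-based boundary is out of scope.
* Four-view rotation imaging is supported only as independent per-image
  processing with an any-view-positive boll flag; there is no cross-view
  mark deduplication.
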