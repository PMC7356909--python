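# Methods

## The measurement model

A niacin flush-test measurement is a photograph of the inner forearm with
two manually marked regions: the patch treated with methyl nicotinate
solution (area 1) and an adjacent untreated patch (area 2). Manual
marking is deliberate — it accommodates natural skin-color variation and
the no-reaction case, where no automatic segmentation target exists. The
control region sits beside the irritated one along the forearm axis so
that both see similar illumination on the curved arm surface; all
downstream inference therefore runs on *differences* between the two
areas, which cancel the subject's baseline skin tone and the shared
lighting to first order.

A ruler visible in the frame is annotated as two pixel coordinates with a
known physical distance; the Euclidean pixel distance gives the scale
(mm/pixel), and the flush surface is the pixel count of area 1 times the
squared scale. The surface uses the *full* annotated region: the marking
itself defines the flush extent, while the chrominance filter below
guards only the color statistics.

## Color model

Pixels are 8-bit RGB. Three derived spaces are computed:

- **HSV** via the polar (arccos) hue formula on channels normalised to
  [0, 1]: θ = arccos(½[(R−G)+(R−B)] / √((R−G)² + (R−B)(G−B))), H = θ for
  B ≤ G and 360° − θ otherwise; S = 1 − 3·min(R,G,B)/(R+G+B);
  V = max(R,G,B). Achromatic pixels (R = G = B, where θ is 0/0) return
  H = 0, S = 0 by convention, and S = 0 is also used for pure black.
  The polar hue differs from the familiar hexcone (max/min) hue by at
  most ≈ 1.12°, coinciding at multiples of 60°; the test suite checks
  agreement at 1.2°.
- **YUV / YCbCr** via the BT.601 studio-range transform with offset
  (16, 128, 128). The U/V and Cb/Cr pairs are numerically identical in
  this digital form. The chrominance rows must sum to zero — otherwise
  neutral grays would not map to Cb = Cr = 128 — which fixes the Cb
  coefficient on R to −0.148. The implementation evaluates the rows in
  channel-difference form (e.g. Cb = −0.148(R−B) − 0.291(G−B) + 128),
  algebraically identical but *exactly* neutral on achromatic input in
  floating point. Luminance is the 0.257/0.504/0.098 row plus 16.

Conversions are kept in floating point; outputs are clipped to [0, 255]
at the end, and rounding to the 8-bit grid happens only where a statistic
requires it (the mode).

### Skin-plausibility filter

Color statistics are computed only over pixels whose (Cr, Cb) fall inside
a configurable window, which removes pen marks, plaster, shadows and
other non-skin content from hand-drawn regions. The stock window —
Cr ∈ [140, 165], Cb ∈ [140, 195] — is a calibration to the acquisition
setup the method was developed with (fixed camera, constant artificial
light) and is **not** a physical constant: under neutral illumination
typical skin sits near Cb ≈ 105–115, below the stock lower bound, and a
strong flush can push Cr above 165 on a Cr ≈ 150 base. Both bounds are
plain configuration values; the synthetic-data workflows and examples run
with the window opened (`SkinThresholds.permissive()`), and an optional
hue band on H/360 (default 0.01–0.1, disabled) is available as an extra
guard. Treat the defaults as a starting point to re-calibrate per camera
and lighting.

## The 97-variable feature vector

Each area is summarised by six statistics — mean, median, mode, range,
minimum, maximum — of eight components (R, G, B, H, S, V, Cr, Cb):
6 × 8 × 2 = 96 color variables plus the area-1 surface in mm², named
`area{1,2}_{component}_{statistic}` and `area1_surface_mm2`. Conventions:

- **median**: midpoint of the two central order statistics for even
  counts;
- **mode**: computed after quantizing the component to 256 levels over
  its native scale (H over [0, 360], S/V over [0, 1], others already
  8-bit), ties broken toward the smallest value, reported back on the
  native scale — the mode is ill-defined on continuous data, and the
  8-bit grid is the natural resolution of the source;
- **hue statistics are arithmetic, not circular**. Skin and flush hues
  sit at ≈ 5–25°, far from the 0/360 wrap, so the bias is negligible
  there; the package is *not* suitable for hue statistics of regions
  whose hues straddle the wrap point.

The delta vector (`delta_{component}_{statistic}`, 48 values + surface)
is area 1 − area 2 per statistic.

## Response call

A measurement is flagged *no difference* when |Δ mean Cr| < τ **and**
|Δ mean R| < τ. The judgement this proxies is traditionally made by human
raters inspecting the photo pairs; no instrument-free definition of a
"visible" difference exists, so τ is an explicit, configurable parameter.
The default τ = 2 (8-bit units) is a conservative just-noticeable color
difference: ≈ 1% of the channel range, comfortably above the area-mean
noise floor of a multi-thousand-pixel region yet well below the 5–20 unit
shifts of a clear flush. Manually recorded rater flags can be supplied
instead of the proxy. A subject's response is **absent** when at least 4
of the 12 (concentration × time) measurements are flagged; incomplete
sessions are never classified silently — the 33% rule is defined on
exactly 12 cells.

## Group statistics

Each variable is analysed with a univariate mixed-design (split-plot)
ANOVA: group as the between-subject factor, the four time points as the
within-subject factor, run separately per concentration. Reported per
effect (group, time, group × time): F, p and partial eta squared
η²ₚ = SS_effect/(SS_effect + SS_error), where the group effect is tested
against the between-subject error and the within effects against the
within-subject error. Sphericity corrections are not applied; with four
within levels, mild violations inflate within-factor p-values modestly,
and the headline contrast (group) is unaffected. A constant dependent
variable short-circuits to F = 0, p = 1, η²ₚ = 0 (every sum of squares is
zero); with a single time point the model degenerates to one-way
between-group ANOVA. The evaluation itself is delegated to
`pingouin.mixed_anova`; an independent sums-of-squares oracle in the test
suite pins the decomposition.

The canonical screen examines 9 variables — the flush surface plus the
mean delta of each color component — at 3 concentrations, i.e. a family
of 27 group tests; the Bonferroni threshold is α/m with m defaulting to
the number of tests actually run.

ROC analysis scores subjects by a delta variable at one (concentration,
time) cell, orients the score so patients (the positive class) score
higher, and reports the trapezoidal AUC (equal to the Mann–Whitney pair
statistic with ½ for ties) plus an operating point: the Youden maximum
J = sensitivity + specificity − 1, ties broken toward higher sensitivity,
or optionally a fixed threshold. Spearman correlations use mid-ranks on
ties (scipy).

## Synthetic data generator

The generator emulates the study's design space, not its optics: a
uniform skin-toned background (default RGB (205, 160, 130), Cr ≈ 150)
with i.i.d. Gaussian pixel noise (default sd 2), an elliptical flush
region, a congruent control ellipse shifted along the forearm axis, and a
dark ruler strip with ticks at known spacing. The flush raises Cr by
δ = attenuation · δ_max · f(concentration) · g(time) with saturating
dose response f(0.001) = 0.3 < f(0.01) = 0.65 < f(0.1) = 1 and a time
course g rising to a plateau at 10 min — qualitative shapes of a typical
flush reaction, chosen as generator conventions. Because pixels are 8-bit
integers, δ is rendered by the best integer (ΔR, −ΔG) pair under
Cr = 0.439 ΔR + 0.368 ΔG; the exactly rendered shift (within ±0.5 of the
request, typically within ±0.02) is recorded in the photograph metadata,
and zero-noise recovery through the full pipeline reproduces it exactly.
Cohorts draw a per-subject attenuation from a clipped normal per group
(with an optional hard non-responder fraction); all randomness flows from
one seed.

What the generator does *not* model — and therefore what passing tests do
not demonstrate about clinical data: realistic skin texture and vignette,
uneven illumination, edema and 3-D arm geometry, camera sensor noise and
white balance, and rater behaviour. The defaults (400 × 300 px at
0.1 mm/px; tests use 200 × 150 px frames with proportionally smaller
ellipses) keep a three-group cohort generation in seconds while leaving
thousands of pixels per region, so area-mean noise stays well below τ.

## Numerical choices and edge cases

- Polygon annotations rasterize by testing pixel centers against the
  polygon (even-odd rule; annotations are assumed simple polygons).
- Inclusive threshold intervals; achromatic hue/saturation conventions as
  above; mode ties toward the smallest value; Youden ties toward
  sensitivity.
- Validation is fail-fast with typed errors: non-8-bit images,
  overlapping or empty areas, degenerate rulers, duplicate or off-grid
  session cells, incomplete sessions, single-class ROC input, constant
  vectors in correlation.
- CLI exit codes: 0 ok, 1 validation error, 2 runtime error.

## Known limitations

No color calibration across cameras (the acquisition protocol controls
lighting experimentally); no automatic flush segmentation or ruler
detection; arithmetic hue averaging; no sphericity correction or
covariate-adjusted models; clinical sensitivity/specificity values can
only be demonstrated on synthetic cohorts, since no patient imagery is
publicly available.
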