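# Methods

## The measurement model

A microdynamic flow test disperses a small powder dose (<200 mg) through an
orifice onto an illuminated measuring cuvette and photographs the resulting
flow pattern. Two area-fraction statistics summarise the image:

* **Flow Index** `FI = 100 · |P| / |R|`, where `R` is the region of interest
  (the illuminated background area) and `P ⊆ R` the set of pixels occupied
  by powder. A free-flowing powder disperses into many small deposits and
  covers a large area; a cohesive powder exits as lumps and covers little.
* **Agglomeration Ratio** `AG = |A| / |P|`, where `A ⊆ P` is the set of
  distinctly darker pixels within the pattern. Under transmitted backlight
  an agglomerate several particles deep attenuates far more light than a
  monolayer of dispersed particles, so darkness is a proxy for local
  optical thickness and hence cohesive lumping. `AG` is normalised by the
  pattern area, not the ROI, so it is independent of `FI`.

Both segmentations use Otsu's method on a 256-bin histogram: choose the cut
`t` maximising the between-class variance `ω₁ω₂(μ₁−μ₂)²` of the classes
`{≤ t}` and `{> t}`; ties go to the lowest `t` for determinism. Under
backlight the powder is the dark ROI class; under frontlight the bright
one. Because any threshold depends only on the rank order of intensities,
`FI` and `AG` are invariant under strictly increasing, non-clipping
intensity remaps, and inverting the image while flipping the polarity flag
leaves the powder mask unchanged — both properties are tested.

### Bimodality gate

Otsu's split is only meaningful when the histogram is reasonably bimodal.
Before accepting the within-pattern split, Ashman's D

    D = |μ₁ − μ₂| / sqrt((σ₁² + σ₂²)/2)

is computed between the two Otsu classes; `D > 2.0` (the conventional
clean-separation value) declares the pattern bimodal, otherwise `AG = 0`
with `bimodality_flag = False`. Two zero-width spikes give `D = ∞`.
Limitation: for the Otsu split of a *single Gaussian*, the class statistics
give `D ≈ 2.65`, so a noisy but genuinely unimodal pattern can pass the
gate and report a spurious `AG ≈ 0.5`. On patterns with discrete levels
(noise-free, or separation ≫ noise sd) the gate behaves as intended;
interpreting `AG` on patterns without visible dark lumps should always
consult the flag and the thresholds in the per-image record.

### Polarity

Lighting polarity (backlight: powder dark on bright; frontlight: the
inverse) is a property of the measuring setup and is best passed
explicitly. `auto` mode first compares the mean intensity of the ROI border
band (outer shell, ~5 % of the shorter side) with the interior — a flow
pattern lands centrally, so a clearly brighter border (≥ 5 gray levels)
means backlight. If the contrast is below that margin the majority Otsu
class decides (powder is assumed the minority phase). Auto detection is
undecidable in principle when powder covers ~50 % of a spatially uniform
field; declared polarity is used throughout the validation suite.

### Small-component suppression

Connected powder components below `min_component_px` (default 4 px,
8-neighbourhood not required — 4-connectivity is used) are removed before
any area is counted, as single-pixel sensor noise otherwise inflates `FI`.
At fixture scales (disks of radius ≥ 2 px) the filter is a no-op on real
powder. No other morphology is applied: opening/closing would silently move
`FI`.

### A trimodal pitfall

With three well-populated levels (background, dispersed, agglomerate) a
single Otsu cut on the ROI can land in the agglomerate/dispersed valley
rather than the powder/background valley when the agglomerate level is very
dark and its mass large; the powder mask then collapses onto the
agglomerates. With the default synthetic levels (230/160/77) the
background cut dominates across the tested grid (coverage ≤ 50 %,
agglomerate fraction ≤ 0.4) — verified against the exhaustive-search oracle
— but images with near-black, massive lumps can need an ROI that excludes
empty background or a two-stage segmentation. The implementation keeps the
single-threshold definition and exposes the thresholds for diagnosis.

## Flow classification

`FI` maps to four classes anchored by microcrystalline cellulose reference
grades measured at a fixed flow rate: Excellent (≥ 50), Good ([30, 50)),
Acceptable ([10, 30)), Poor ([0, 10)). The printed band edges leave 10, 30
and 50 ambiguous; left-closed half-open intervals are used so each boundary
belongs to the better class, giving a total partition of [0, 100] (tested
on a 10⁻³ grid). Classification applies to the replicate *mean* FI — one
class per material — and bands are configuration, overridable per run.
Replicate statistics are mean and sample (n−1) standard deviation; a single
replicate reports no sd.

## PSD percentiles and span

Size classes (μm, strictly increasing) with volume fractions are treated as
the upper edges of a cumulative curve starting at 0; the lower edge of the
first class is extrapolated at the geometric spacing of the first two
classes. `Dv(p)` inverts the curve at the first crossing of `p`, with
interpolation linear in log(size) by default (laser-diffraction classes are
log-spaced; linear-in-size is available). `span = (Dv90 − Dv10)/Dv50` — the
universal laser-diffraction width measure; applied to the reported
percentile triples it reproduces both printed spans (3.60 / 3.28) to two
decimals, which is the validation for adopting it. For replicates, the span
is computed per measurement and then averaged, not taken of the averaged
percentiles.

## Synthetic scene generator

The generator provides ground truth the study's unpublished images cannot:

* **Dispersed phase** — Boolean model: disk centres uniform over the frame,
  radii lognormal (median 4 px, shape 0.35).
* **Agglomerates** — Thomas-type clusters: parent centres uniform, member
  count Poisson (mean 12, min 2), member disks displaced from the parent by
  an isotropic Gaussian (sd 6 px), giving compact multi-particle lumps.
* **Placement** — clusters first, until the agglomerate pixel budget
  `coverage · agglomerate_fraction` is met; then free disks until total
  coverage reaches `target_coverage`. Any placement overshooting its budget
  beyond a 1 %-of-frame tolerance is rejected and redrawn; a bounded number
  of consecutive rejections raises a generation error (radii too large for
  the frame). Realized coverage therefore sits well within ±2 percentage
  points of target.
* **Labels** — a pixel is `agglomerate` if any cluster-member disk covers
  it, `dispersed` if only free disks do, else `background`. `truth_fi` and
  `truth_ag` are exact counts over this label map; ground truth derives
  from geometry, never from the rendering that the analysis thresholds.
* **Rendering** — transmitted-light optical thickness:
  `I = background · exp(−κ·T)` with `background = 230`,
  `κ = ln(230/160)` per particle layer, `T = 1` for dispersed pixels
  (particles settle as a monolayer against the cuvette wall) and
  `T = agglomerate_layers = 3` for lumps (a lump is several particles
  deep). Default levels are then 230 / 160 / 77 — mode separation ≥ 60 gray
  levels, the regime the Otsu metrics assume. Gaussian noise (sd 5 by
  default) is added and clipped to 8 bits. Frontlight inverts the rendered
  intensities (`255 − I`). Per-disk layer stacking is deliberately *not*
  used: it would make chance overlaps of dispersed disks as dark as
  agglomerates (≈30 % of covered area has ≥2 layers at 50 % coverage),
  decoupling darkness from the ground-truth labels and making the
  recovery comparison meaningless.
* **Determinism** — one `numpy.random.default_rng(seed)` per scene, no
  global state; identical parameters give byte-identical images, and the
  TIFF writer emits no timestamps, so fixture files regenerate
  byte-identically from the manifest.

What the generator does *not* emulate: spatial inhomogeneity of real
patterns (deposits concentrate under the orifice), illumination gradients,
motion blur, partial-volume edges, and dense single particles whose gray
level mimics agglomerates. Passing recovery tests therefore show the
*metrics* are computed correctly on images satisfying the method's own
assumptions; they do not certify segmentation accuracy on arbitrary real
images.

## Validation problem sizes

The test suite checks FI/AG recovery on noiseless 512×512 scenes over
coverage {5, 15, 30, 50} % × agglomerate fraction {0, 0.2, 0.4} × 20 seeds
(240 scenes; FI within 2 points, AG within 0.05), AG monotonicity over
agglomerate fractions {0.05, 0.20, 0.42} × 10 noisy scenes each, and Otsu
agreement with exhaustive search on hundreds of random histograms. The
acceptance script repeats the sweep at 5 seeds per cell, which bounds the
same worst-case errors in a few seconds.

## Known limitations

* `AG` presumes the dense phase contrasts with the dispersed phase; the
  unimodal gate can mislabel noisy homogeneous patterns (above).
* The single-Otsu powder segmentation can fail on trimodal images with
  extremely dark, massive agglomerates (above).
* Flow classification is valid only at the fixed flow rate at which the
  reference materials were banded; no flow-rate dependence is modelled.
* 16-bit input is thresholded on a 256-bin rescaled histogram; sub-8-bit
  contrast structure is ignored by design.
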