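# Methods

This note documents the models, defaults and numerical choices behind
`nucbarcode`, and what the synthetic-data tests do and do not demonstrate
about real images.

## The measurement model

Each nucleus expresses a two-FP nuclear marker. Under a single 560–590 nm
excitation, the marker's emission is split between two red passbands
(em1: 635–675 nm, em2: 608–648 nm). The demultiplexing statistic is the
per-nucleus ratio of background-corrected summed intensities,
R = Σem1/Σem2. Summed (rather than mean) intensities are used: over the
same pixel mask the two are proportional, so the ratio is identical, and
sums degrade more gracefully when part of a nucleus (e.g. a dim nucleolar
region) falls near the segmentation boundary.

R is invariant to anything that scales both channels together —
expression level, illumination, exposure — but not to additive offsets,
which motivates the background model below.

### Theoretical ratios from spectra

For an FP with emission spectrum S(λ) the expected ratio is

    R = d · ∫ S·T_em1 dλ / ∫ S·T_em2 dλ,

with T the filter transmissions (top-hat presets or tabulated curves) and
d the instrument's relative efficiency at detecting em1 versus em2
emissions (default 0.893, an instrument calibration constant; override
per microscope). Integration is trapezoidal on the provided wavelength
grid with the passband edges inserted by linear interpolation, so the
integral is exact for piecewise-linear spectra wherever the grid samples
fall; the engine is validated against adaptive quadrature on analytic
spectra to 1e-4.

For a fusion of two different FPs N and C, assuming no energy transfer
between them, each constituent with homogeneous ratio Rᵢ and weight
wᵢ = (excitation efficiency) × (brightness) contributes channel parts
wᵢRᵢ/(1+Rᵢ) to em1 and wᵢ/(1+Rᵢ) to em2; the fusion ratio is the ratio
of summed parts. This "weighted mediant" always lies between the two
constituent ratios and moves monotonically toward the more heavily
weighted one. Excitation efficiencies default to 1.0 when excitation
spectra are not supplied; they cancel for homogeneous fusions and only
reweight mixed ones. FRET-corrected prediction is out of scope.

## Background correction

Two stages, following the empirical (non-parametric) approach:

1. **Reference image.** Per channel, the pixel-wise mean of media-only
   well fields (typically ~40), capturing camera offset, media
   fluorescence and the optics' vignetting. Fields whose permissive
   object mask covers more than `max_masked_fraction` (default 0.5%) of
   pixels are rejected as debris-contaminated; if all fields are rejected
   the error lists per-field reasons. The reference is kept real-valued.
2. **Residual scalar offset.** Per field and channel,
   δ = mean(field − reference) over pixels outside a permissive
   all-object mask dilated by 3 pixels, with the identical mask applied
   to both grids. Corrected = field − reference − δ, never clipped, so
   negative pixels are preserved and object sums stay unbiased.

The offset stage is what protects dim nuclei: an uncorrected ±3-count
offset biases the ratio of a nucleus with a ~3,500-count em2 sum by more
than 5%, while after correction the ratio is recovered to well under 1%
(both properties are asserted in the test suite). Cellular
autofluorescence is not modelled or corrected — it is negligible in
these red channels. Plate-wall reflections are out of model; the package
only offers `edge_background_warnings`, which flags edge-row wells whose
offsets deviate from the plate median by more than 3 robust sd.

## Segmentation

* **Stringent mode** (counting/measurement): Otsu threshold on the
  corrected em1 frame (optionally bounded below by an absolute floor),
  hole filling before area filtering (so dim nucleoli cannot fragment an
  object), optional splitting of touching nuclei by watershed seeded
  from distance-transform maxima at least one mean nucleus radius apart,
  then area and mean-intensity floors. Otsu keeps the label count
  invariant under intensity rescaling.
* **Permissive mode** (background masking): objects are detected above
  *local* background — a σ=25 px Gaussian-smoothed copy is subtracted
  first so vignetting is not mistaken for signal — with a low threshold
  of median + 2 robust sd (MAD-based). Connected components under
  `min_object_px` (default 3) pixels are treated as shot-noise speckle
  and dropped: at a 2-sd threshold ~2% of pure-noise pixels fire, and
  without the despeckle their dilation would blanket the frame. The
  surviving mask is dilated by 3 pixels (disk element).

Measurement is taken over stringent labels expanded by 2 pixels
(`measure_expand_px`). This decorrelates the mask boundary — chosen on
the noisy em1 frame — from the pixels being summed; without it, boundary
pixels that fluctuated upward are preferentially included and the em1 sum
(hence the ratio) acquires a ~1% upward bias.

Objects whose em2 sum does not exceed the low-signal floor
5·noise_sd·√area (noise propagated over the object sum; an absolute floor
can be supplied instead) get no ratio and are excluded, as are objects
with any raw pixel at the 12-bit ceiling (4095) in em1 or em2.

## Calibration and classification

Per line, μ and σ are the sample mean and sample sd (n−1) of monoculture
ratios after exclusions, with a minimum of 500 objects (configurable).
Windows are [μ − kσ, μ + kσ] with a single global k (default 3; 5 was
used for the two-line study). Overlapping windows are a hard construction
error reporting the offending pair and the largest non-overlapping k;
an explicit override builds anyway and classifies straddling objects as
"ambiguous" instead of assigning them. Classification gives every object
exactly one category: a line label, "other" (debris), or "excluded".

## The synthetic-data generator

The generator emulates the conditions the analysis assumes, with defaults
chosen to represent the imaging regime the method targets:

| parameter | default | rationale |
|---|---|---|
| ratio distributions | 0.560±0.025, 0.737±0.031, 1.067±0.045 | the three-line monoculture panel; adjacent means >6 pooled sd apart |
| nucleus profile | isotropic 2-D Gaussian, σ = radius/2, truncated at 3σ | diffuse nucleoplasmic marker; nucleolar holes omitted |
| total red signal | lognormal, median 1.2e5 counts (logsd 0.35) | typical nuclear pixel ~1000 counts on the 12-bit scale for a 6 px radius nucleus |
| background | 100 counts, ×(1 − 0.1·r²/r²max) vignette bowl | smooth multiplicative optics non-uniformity |
| per-well offset | Normal(0, 1.5) counts per channel per day | the ±1–3 count well-to-well background drift |
| noise | Poisson shot + Gaussian read (sd 2), rounded, clipped at 4095 | camera model |
| debris | Poisson(5)/field, radius ≤ half nucleus, dim, arbitrary ratio | red-fluorescent debris; media wells use rate 0.5 |
| growth | N₀·g^day, g ∈ {1.155, 1.048, 1.171} | the Day-4/Day-0 fold regime of the longitudinal study |
| plating | per-(well,line) N₀ with 10% cv, drawn once | plating variability that longitudinal folds cancel |

The em1/em2 split of each rendered blob is exact
(added_em1/added_em2 = R before noise), so noise-free fields measured
end-to-end recover every ratio to ≤1e-6 and any residual spread in noisy
runs is attributable to the modelled noise. Nuclei are placed by
rejection sampling with fully disjoint 3σ supports; an unplaceable
request errors with the achievable count. The vignette is applied to the
background term only: equal multiplicative shading of both emission
channels cancels in the ratio, so modelling it on the signal would only
re-scale brightness without exercising any additional failure mode,
while keeping it off the signal preserves the exact-integral contract.
A single master seed drives per-field sub-seeds derived from
(seed, day, field, crc32(well)), so any field is reproducible in
isolation.

**What passing synthetic tests does not show:** real nuclei are not
Gaussian blobs (chromatin texture, nucleoli, mitotic figures), real
debris can overlap nuclei, real ratio distributions have heavier tails
than Gaussians (observed "other" rates on real plates exceed Gaussian theory), and
real plates add focus drift and wall reflections. The synthetic results
validate the *algorithmic* contracts — correction arithmetic, window
logic, accounting — not instrument-level robustness.

## Plate statistics

* **Growth**: G = N(day t)/N(day 0) per well and line; undefined at zero
  baseline. Longitudinal scoring (per-well folds against a no-growth fold
  reference) is compared with cross-well scoring (raw day-t counts
  against 3 sd above the day-0 distribution) by Monte-Carlo; whenever
  plating cv exceeds the per-well measurement cv the longitudinal scheme
  produces strictly fewer false negatives. The false-negative threshold
  is mean + 3·sd of the chosen reference sample (reference choice — Day-0
  or day-t vehicle — is a parameter).
* **Z′-factor**: 1 − 3(σ₊+σ₋)/|μ₊−μ₋| with sample sds; undefined for
  equal means. At a 12σ control separation Z′ converges to 0.5.
* **Reporter quantification**: per-nucleus mean reporter intensity
  (sum/area) is averaged per field first, then summarized as mean ± sd
  across fields per (line, treatment); a field with no objects of a line
  contributes a missing value, not zero.
* **Equivalence test**: two-way fixed-effects ANOVA
  (value ~ treatment + culture-mode) with type-II sums of squares —
  robust to the unbalanced designs that arise when demultiplexed counts
  differ per well — returning the culture-mode main-effect p. Under a
  simulated null its p-values are uniform (KS-checked over 1000
  replications).

## Problem sizes used in the bundled checks

The default test plate is 384×384 px with ~700 nuclei per monoculture
well and ~450 in the co-culture well across 4 fields — enough for the
default 500-object calibration minimum and a few hundred classified
co-culture nuclei, while a full suite run stays under a minute. The
desk-scale fidelity statistics use 10⁵ Gaussian draws per line (three-line
coverage) and 10⁶ draws (two-line misassignment), where binomial error on
the reported percentages is well below the margins being tested.

## Known limitations

* No machine-learned or whole-cell segmentation; nuclei only.
* No FRET correction, spectral unmixing beyond two channels, or
  automated bar-code panel design.
* The mRaspberry-homodimer anomaly (a homogeneous fusion whose measured
  ratio deviates from its parent FP's) is not modelled.
* Windows are global-k; per-line k is not supported.
* The simulator does not model focus drift, photobleaching, maturation
  kinetics, or nucleus overlap in z.
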