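# Methods

## The measurement model

An ROI is a rectangle of 8-bit RGB pixels covering one papillary gingiva.
The quantity of interest is the ratio of mean red to mean green intensity
over the tissue pixels, R/G = Mean_R / Mean_G. In healthy gingiva the ratio
sits around 1.5; inflammation raises it toward 1.9. Blue is carried along
for provenance but plays no role in the index.

The only systematic artifact modeled is the flash halo: a near-saturated,
achromatic reflection. Since white has R/G = 1, an unremoved halo biases the
ratio toward 1 in proportion to its area — an inflamed site with a 15% halo
can read as healthy. Halo removal is therefore a segmentation problem, and
the pipeline treats it as one-dimensional thresholding:

- **Intensity scale.** Gamma correction `b·x^γ` is applied to intensities
  normalized to [0, 1]. On that scale, with b = 1, the transform fixes 0 and
  1 and is monotone, so γ = 2.2 compresses mid-tones (gingiva) while leaving
  near-saturated pixels (halo) essentially untouched — it widens the gap the
  threshold must find. Applied to raw 0–255 data the same exponent would
  overflow the range and the gain would have to be retuned per image; the
  unit-interval convention keeps (b, γ) dimensionless and shape-preserving.
- **Threshold channel.** Otsu needs a single channel. The Rec.601 luminance
  (0.299 R + 0.587 G + 0.114 B) of the gamma-corrected ROI is used because
  halos are achromatic and bright in all channels; thresholding any single
  color channel would conflate halo with inflammation (R) or pallor (G).
- **Otsu with a guard.** Otsu's criterion always produces a split, even in a
  homogeneous ROI where the "bright class" is just the upper half of the
  noise. The split is accepted only when the candidate halo class's mean
  gamma-corrected luminance reaches `sat_guard` (default 0.85; a gingiva
  patch at full 8-bit brightness ~200/255 has corrected luminance ≈ 0.59, a
  halo ≥ 250/255 has ≈ 0.96, so the default separates them with wide
  margin). `force_otsu=True` disables the guard and masks the brighter class
  unconditionally, reproducing unconditional-threshold behavior; it is kept
  for the paired bias experiments.
- **Means on the raw scale.** Channel means are computed from the original
  0–255 values under the retained mask (mask-multiply then divide by the
  retained count — identical to the plain mean over retained pixels, and
  tested as such). Gamma-corrected values are used only to *find* the mask;
  using them in the means would change the estimand.

Degenerate cases are hard errors, not NaNs: an ROI entirely flagged as halo
raises, as does a zero mean-green. A constant ROI has no Otsu split and is
passed through unmasked. No morphological cleanup is applied to the mask by
default (isolated misclassified pixels are negligible against thousands of
ROI pixels); a binary-opening option exists for noisy captures.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `b`, `gamma` | 1.0, 2.2 | dimensionless | gamma transform shape; 2.2 matches typical display-referred encoding and strongly separates halo from tissue |
| `sat_guard` | 0.85 | corrected unit luminance | minimum brightness for an accepted halo class |
| `bins` | 256 | — | Otsu histogram resolution (one bin per 8-bit level) |
| `alpha` | 0.05 | — | significance level; p ≤ 0.10 additionally labeled a "tendency" tier |

## Statistics

Friedman's test uses the tie-corrected statistic (Conover form): GI is
ordinal 0–4, so ties are guaranteed, and the uncorrected statistic would be
conservative. Kendall's W is defined as chi2 / (n(k−1)) with the same tie
correction, so the identity between the two holds exactly with or without
ties. p-values are chi-square by default; `exact=True` enumerates all
(k!)^n within-block permutations when that count is ≤ 250,000 and otherwise
falls back to seeded Monte-Carlo with an add-one correction. Spearman's rho
uses average ranks (scipy) with the t-approximation; exact permutation is
available for n ≤ 8.

The per-jaw reduction keeps the maximum R/G and the maximum GI across the
jaw's three papillary sites *independently* — the two maxima may come from
different sites. This matches the design of summarizing each jaw by its
worst site per variable. No multiple-testing correction is applied by
default (the analyses are few and confirmatory); a Benjamini–Hochberg pass
can be applied downstream on the tidy p-value output if desired.

Longitudinal summaries drop subjects not observed at all four time points
(complete-block requirement of the Friedman test) and report the n actually
used, with a log entry for every drop.

## The synthetic generator

The generator emulates exactly what the estimator consumes:

- **Patches**: constant gingiva-toned base (R, G, B) = (true_rg·base_g,
  base_g, base_b) with i.i.d. Gaussian pixel noise (default sd 4 on the
  8-bit scale), clipped and rounded. Defaults base_g = 100, base_b = 90 give
  a plausible gingiva color around (160, 100, 90).
- **Halos**: anti-aliased disks at level ≥ 250 with a 1-pixel soft edge; the
  ground-truth mask uses the ≥ 50%-coverage rule. Disk area is capped below
  50% of the patch.
- **Cohorts**: 25 subjects × 4 time points × 6 sites by default. True per-ROI
  R/G = time-point mean + site offset + subject random effect
  (sd 0.06) + within-site noise (sd 0.03). The default time-point means are
  BO 1.62, MO 1.52, TO 1.66, IDO 1.76 — the clinically observed pattern of a
  mid-treatment dip and a post-debonding peak, inside the observed cross-site
  band of roughly 1.48–1.88 (BO and TO were placed 0.04 apart so the planted
  ordering is strict and recoverable). Site offsets follow the observed
  pattern of redder lateral maxillary papillae. 30% of ROIs carry a halo of
  4–12% area. GI is a monotone step function of the true R/G (cuts at 1.52,
  1.62, 1.72, 1.82) with ±1 ordinal noise at probability 0.15.
- **Planted GI–R/G link**: for correlation-recovery experiments, paired
  (R/G, GI) values come from a Gaussian copula whose latent correlation is
  calibrated by root-finding so that the *post-discretization* population
  Spearman (GI binned to 5 ordinal levels, midrank grades) equals the
  requested strength. The calibration is analytic — the mixed moment
  E[Φ(X)·1{Y ≤ c}] is a bivariate-normal orthant probability — so no
  simulation enters the target definition.
- One explicit seed drives everything; per-ROI sub-seeds are drawn from the
  cohort stream, so cohorts are bit-reproducible.

The study-scale fixture emits 98 photos × 6 sites = 588 ROIs (a 25 × 4
design minus two photos, matching the photo count retained after quality
control in the motivating study design).

What the generator does *not* emulate: tooth surfaces, brackets and wires,
melanin pigmentation, gingival recession, texture, specular gradients,
camera color response, or JPEG compression noise. Passing tests therefore
demonstrate correctness of the estimator under the stated noise model and
its robustness to saturated halos — not clinical accuracy on real
photographs, which depends on acquisition protocol and ROI placement.

## Numerical choices

- Otsu operates on a 256-bin histogram over the data range; the returned
  threshold is the bin center of the best cut, the brighter class is
  strictly above it, and ties take the lowest cut (first argmax). Tests
  verify equivalence with an exhaustive search over all cuts and partition
  agreement with scikit-image's implementation.
- ROI coordinates are 0-based half-open, `(x0, y0, x1, y1)`.
- Results CSVs print floats at 6 decimals in a fixed column order, so
  repeated runs are byte-identical.
- Monte-Carlo permutation p-values use (count + 1)/(reps + 1).
- Problem sizes in the validation experiments (200 ROIs at 96×96 for the
  halo study, 2000 null replicates for type-I calibration, 25-subject
  cohorts at 80×80 patches) were chosen to make every check decisive at
  desk scale: sampling error in each measured quantity is an order of
  magnitude below the tolerance it is compared against.

## Known limitations

- The R/G ratio reflects color only; edema and volume change are invisible
  to it, so low-grade inflammation that manifests as swelling before redness
  will be under-read.
- Cross-camera comparability is not addressed: no color calibration or
  dynamic-range harmonization is performed, so absolute R/G values are
  device-specific even though within-device longitudinal contrasts are valid.
- The saturation guard assumes halos are the brightest structure in the ROI;
  a specular reflection dimmer than 0.85 corrected luminance passes through
  unmasked (lower `sat_guard` or set `force_otsu` for such captures).
- GI scoring is a human task; the package audits and correlates scores but
  deliberately does not predict them from pixels.
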