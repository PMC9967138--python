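# gingired

Quantifying gingival inflammation from intra-oral photographs.

Gingivitis shows up first as a color change in the papillary gingiva — the
interdental gum tissue — which turns red as microvascular permeability
increases. `gingired` measures that redness objectively from ordinary 8-bit
RGB intra-oral photographs as the **R/G ratio**: the mean red-channel
intensity over a region of interest divided by the mean green-channel
intensity. It is built for longitudinal orthodontic studies in which each
subject is photographed at four time points (BO = before treatment, MO =
mid-point, TO = three-quarters through, IDO = immediately after debonding)
and six anterior papillary sites are scored per visit, and it pairs the
image measurement with the modified gingival index (GI), an ordinal 0–4
visual score, for validation.

## The measurement

Flash photography leaves near-saturated achromatic *halo* reflections on the
wet gingiva. White pixels have R/G = 1, so a halo drags the ROI's ratio
toward 1 and masks inflammation. For an ROI `C_in` with channels
`C_R, C_G, C_B ∈ [0, 255]`, the pipeline is:

1. **Normalize** to the unit interval: `x = C_in / 255`.
2. **Gamma-correct**: `C_out = b · x^γ` (defaults `b = 1.0`, `γ = 2.2`),
   which compresses mid-tones and leaves near-saturated pixels near 1,
   accentuating the halo.
3. **Segment** the halo with Otsu's method on the gamma-corrected Rec.601
   luminance, giving complementary index maps `L` (halo) and `L_inv`
   (retained). A saturation guard only accepts the bright class when its
   mean corrected luminance reaches 0.85, so halo-free ROIs are left intact.
4. **Masked means**: `Mean_c = Σ (C_c ∘ L_inv) / Σ L_inv` for each channel
   on the raw 0–255 scale, and `R/G = Mean_R / Mean_G`.

Longitudinal change is tested per site with the tie-corrected **Friedman
test** (subjects as blocks, time points as treatments) and **Kendall's W**;
the GI↔R/G association is tested with **Spearman's rho** on the highest
value per jaw (maximum of the three papillary sites, each variable reduced
independently), at α = 0.05.

Because clinical photographs cannot be redistributed, the package ships a
synthetic-cohort generator with known ground truth (true R/G per patch,
exact halo masks, planted time effects and a monotone GI link) against which
everything is validated.

## Worked example

Simulate a small cohort, measure every ROI, and run the statistics:

```bash
gingired simulate --subjects 5 --seed 11 --out demo
gingired all --images demo/images --manifest demo/manifest.csv \
             --gi demo/gi_scores.csv --out demo/out --seed 11
# measured 120/120 ROIs; stats written under demo/out
```

`demo/out/results.csv` holds one row per ROI:

```
subject_id,photo_id,site,jaw,timepoint,rg_ratio,mean_r,mean_g,mean_b,retained_pixel_fraction,gi
S01,S01_BO,U_12_13,maxilla,BO,1.743212,174.245781,99.956719,90.051250,1.000000,2
```

(`retained_pixel_fraction` < 1 means a halo was detected and masked.)
`demo/out/longitudinal_rg.csv` is the per-site summary:

```
   site  mean_BO  mean_MO  mean_TO  mean_IDO  p_value  kendalls_w
U_12_13 1.770430 1.659645 1.782344  1.912098 0.003570       0.904
U_11_21 1.597246 1.520292 1.657430  1.747855 0.001817       1.000
...
```

Redness dips at the treatment mid-point and peaks immediately after
debonding (MO < BO < TO < IDO), and the Friedman p-values show the time
effect is significant at every site even with five subjects.
`demo/out/gi_rg_correlation.csv` gives the per-jaw, per-time-point Spearman
rho between the highest GI and the highest R/G; a cell whose GI happens to
be constant at this tiny n is reported as NaN with an explanatory note
rather than failing the run.

The same operations are available as a library (`gingired.measure_redness`,
`gingired.friedman_test`, `gingired.generate_cohort`, ...); the CLI is a
thin wrapper.

## Layout

- `gingired.io` — photos, ROI manifests (JSON/CSV), results tables; the
  site/jaw/time-point vocabulary.
- `gingired.redness` — the measurement pipeline (gamma, Otsu, masking, R/G).
- `gingired.gi` — modified-GI rubric, score validation, rater concordance.
- `gingired.stats` — Friedman, Kendall's W, Spearman, max-per-jaw reduction,
  longitudinal summaries.
- `gingired.synthetic` — ground-truth generators.
- `gingired.pipeline` / `gingired.cli` — batch front end.

See `docs/methods.md` for the modeling choices and their rationale.
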