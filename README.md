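# contraspect

Spectral image-contrast estimation for ordered two-condition image cohorts.

The pipeline treats each image as a realisation of a wide-sense-stationary
2-D random process:

1. **Luminance** — RGB pixels are converted to luminance with
   `(0.299 R + 0.587 G + 0.114 B) / 255`, giving a field in `[0, 1]`.
2. **Contrast** — the field is mean-centred and its autocovariance function
   is computed through the 2-D FFT (Wiener–Khinchin route). The value at lag
   (0, 0) is the *average image contrast*: the plug-in variance of the
   luminance field, reported both on the variance scale (max 0.25) and as
   its square root, the RMS contrast (max 0.5). A brute-force lag-summation
   oracle (`autocorrelation_direct`) independently validates the FFT path,
   and a radially averaged ACF profile is available for shape analyses.
3. **Timeline & comparison** — per-image contrasts are merged with a
   chronologically ordered catalog and the two exposure conditions
   (`low` / `high`) are compared with a self-contained Mann–Whitney U test:
   exact p-values by the counting recursion for tie-free data up to
   n = 28, otherwise a tie- and continuity-corrected normal approximation.
4. **Synthetic data** — generators for images of analytically known contrast
   (uniform, checkerboard, grating, Gaussian random field, two-tone) and
   for full synthetic cohorts (default 19 low / 9 high, matching the
   packaged 28-row reference catalog) make the whole chain verifiable
   without any original source images.

## CLI

```sh
# generate a synthetic cohort to play with
contraspect synth-cohort --out demo --seed 7

# per-image contrast CSV
contraspect contrast --catalog demo/catalog.csv --out demo/results

# two-condition rank test + timeline plot
contraspect compare --contrasts demo/results/contrast.csv --out demo/results
```

`contrast` accepts `--crop-fraction` (strip a border fraction),
`--max-dim` (downsample large plates), `--linearize-srgb` (decode gamma
before the luminance weights) and a YAML `--config` overriding any flag;
every output row carries a `config_digest` hash of the analysis settings.
`compare` accepts `--metric variance|rms` (the ranks, hence p, are
identical) and `--sidedness two_sided|one_sided_greater`.

For user-supplied real images, `scripts/analyze_plates.py` runs the whole
analysis from a catalog CSV you provide; its p-value is printed for
inspection only, since it depends on plate resolution and cropping.

## Caveats

Contrast values computed from aged paintings reflect the current state of
the pigments; fading over time is not modelled. No gamma linearisation is
applied by default (the luma weights are conventionally applied to stored
8-bit values); `linearize_srgb` exists for sensitivity analyses.
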