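# Methods

## The counting model

The pipeline treats a fluorescence micrograph as a two-class scene: dark
background and bright spore bodies (chlorophyll autofluorescence, ~685 nm).
Counting proceeds in four steps.

1. **Thresholding.** Foreground = pixels with intensity strictly above a
   threshold. The threshold is either a fixed, pre-determined value (the
   recommended mode for an assay campaign: determine it once per optical
   setup, then apply it to every image) or computed per image by Otsu's
   method. Otsu requires a populated field: on a nearly empty or constant
   image the histogram has no foreground mode to split, and the computed
   threshold lands inside the background noise (a constant image raises a
   named error; sparse fields should use the fixed mode). The applied
   numeric threshold is always written to the run log.
2. **Particle enumeration.** Connected components of the mask
   (8-connectivity by default, so diagonal contacts merge — the usual
   particle-analysis convention) are measured: area, perimeter,
   circularity 4πA/P², centroid, bounding box, border contact. The sum of
   particle areas equals the mask's foreground area exactly.
3. **Gating.** Particles are kept if they satisfy pre-determined size and
   shape bounds. The default gate (area ≥ 0.3·A₁, circularity in
   [0.4, 1 + ε], border particles kept but flagged) rejects sub-spore debris
   such as detached flagella while keeping spores and compact clusters. For
   scenes known to be debris-free, an area-only gate (no circularity cut) is
   preferable: chains of three or more touching spores can fall below
   circularity 0.4, and discarding them would defeat the cluster correction.
   The acceptance script uses the area-only gate for exactly this reason.
4. **Cluster correction.** Touching spores merge into one particle, so the
   count is N = Σ Aᵢ / A₁ with A₁ the mean single-spore area. The correction
   assumes clusters form by contact, not overlap, so a k-spore cluster has
   roughly k times the single area. A per-particle variant
   Σ max(1, round(Aᵢ/A₁)) is available by flag; the global form is the
   default. Fractional counts are reported alongside the rounded integer
   (ties away from zero); downstream ratios use the fractional value.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `pixel_size_um` | user-supplied (or `infer_pixel_size`) | μm per pixel edge; all areas scale with its square |
| A₁ (`single_spore_area_um2`) | 5.0 × 10³ μm² | single-spore reference area of the optical setup. A calibration constant, not a biological one: it can be re-estimated as the median area of isolated, tightly gated particles (`estimate_single_spore_area`, ≥ 20 particles) |
| gate | area ≥ 0.3·A₁, circularity [0.4, 1.05] | what counts as a spore/cluster |
| connectivity | 8 | particle merge rule |
| threshold | Otsu | per-image automatic; fixed value recommended for campaigns and required for sparse fields |

Note on A₁: the default 5.0 × 10³ μm² reflects the optics it was calibrated
on and is hard to reconcile with the ~10 μm long axis of an *Ulva* spore
body (~50 μm² cross-section, aspect ratio ~1.5). The package treats A₁
purely as the calibration divisor, and the synthetic generator parameterises
spore area directly. Dense fields (hundreds of spores in a
2.4 mm × 1.8 mm = 4.32 × 10⁶ μm² field) are only physically packable at the
morphology-scale area, so rendered benchmarks — the acceptance script and
the heavier tests — use 50 μm² spores with A₁ set to the generator mean.
The arithmetic of the correction is scale-free: N = ΣA/A₁ behaves
identically at either scale.

## Numerical choices

- **Perimeter / circularity.** Perimeter is the Crofton estimate over four
  directions, floored at the equivalent-disk perimeter 2√(πA) (the
  isoperimetric bound). Crofton is nearly unbiased for convex rasterised
  shapes — a rasterised disk measures circularity within ~1% of 1.0 at any
  radius — but collapses on 1–4 px specks, where unfloored circularity can
  exceed 1.7; the floor caps circularity at 1.0 by construction.
- **Rounding.** Corrected counts round half away from zero.
- **Degenerate t-tests.** Zero variance in both groups: identical means →
  (t = 0, p = 1); different means → (t = ±∞, p = 0). Pooled
  (n₁ + n₂ − 2 df) is the default variant; Welch–Satterthwaite available.
  The pooled p agrees with the exact permutation p to within ~0.02 for
  moderate effects at n ≤ 10, but not in the far tail, where the permutation
  distribution is floored at its lattice resolution 2/C(n, n₁) (≈ 0.029 for
  two groups of four) while the t p-value keeps shrinking.
- **Band intensity.** Peak height = maximum absorbance in the wavenumber
  window; optional linear-endpoint baseline subtraction, negative corrected
  heights floored at 0. The calibration constants (0.0175, 0.2590) are
  external and overridable. The quoted worked example (I₁ = 9.79,
  I₂ = 3.28) evaluates to 11.4566; its customary citation as "11.4" keeps
  the first three significant digits.
- **Settlement efficiency** is clipped to ≤ 1 with a warning rather than
  reported silently above 100%.
- **Field summary** uses the sample SD (n − 1); a single field reports
  SD = 0.

## The synthetic generator

`generate_scene` emulates what the counting method actually sees, not the
full physics of fluorescence microscopy:

- spores are uniform-intensity ellipses (default aspect ratio 1.5, area
  CV 15%) with an area-sampled anti-aliased edge — interior texture is
  irrelevant to a hard threshold;
- a `cluster_fraction` of spores is placed in contact with an existing
  spore: the centre distance descends until the rasters touch, and
  placements overlapping more than ~8% of the new spore are rejected, so
  merged components keep area ≈ the sum of their members (the correction's
  assumption);
- non-clustered placements are provably disjoint (separating-axis check
  along the centre line); an over-dense demand raises a packing error after
  bounded retries;
- debris specks are elongated sub-gate ellipses; the Cy5 channel adds a pad
  annulus per spore (pad area parameterised per spore) at lower intensity
  than the spore body;
- noise is additive Gaussian, default SD = 5% of the spore intensity —
  enough to exercise Otsu without defeating it; background level 20, spore
  intensity 200;
- identical spec (including seed) ⇒ bit-identical scene.

Not emulated: optical point-spread blur, photobleaching, uneven
illumination, intensity variation between spores, motile spores, real
debris morphology. Passing the synthetic benchmarks therefore shows that
the counting arithmetic and gating logic are correct under the stated noise
and clustering, not that segmentation is robust to every real-world imaging
artifact; on real data the fixed threshold and the gates must be calibrated
to the instrument.

Ground truth records the exact count, per-spore sampled and rasterised
areas, centroids, and the spore/pad/debris masks (a spore's rasterised area
counts newly covered pixels, so Σ rasterised areas = mask area exactly).

## Benchmark problem sizes

The rendered benchmarks use fields of 2400 × 1800 μm at 0.75 μm/px with
50 μm² spores, CV 15%, 20% clustering and default noise. The acceptance
script measures (i) the maximum relative counting error over 20 fields of
300 spores and (ii) the relative standard error of the mean count over 18
fields with per-field truth drawn Poisson(500); the test suite runs smaller
variants of the same scenes so the default run stays fast. The binomial
thinning model of `generate_assay` (each potential settler settles
independently with probability p(c)) stands in for the dish experiments
when exercising the dose-response and significance machinery.

## Known limitations

- The cluster correction is exactly unbiased only when cluster members keep
  their full area; deep overlaps (not produced by the generator, possible in
  reality) bias the count down.
- Otsu thresholding fails on nearly-empty fields (see above); campaigns
  should fix the threshold once.
- The single-channel pad fallback can only exclude spore bodies that the
  Cy5 threshold separates from pad material; when pad and body intensities
  are close, a chlorophyll-channel spore mask is required.
- No watershed splitting: spores merged by genuine overlap stay merged and
  are resolved arithmetically, not geometrically.
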