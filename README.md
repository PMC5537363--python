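# sporecyte

Image cytometry for algal spore settlement assays.

Soft marine fouling is dominated by green algae such as *Ulva*, whose motile
spores settle on submerged surfaces, glue themselves down with a
glycoprotein adhesive pad, and found new colonies. Screening antifouling
biocides and coatings therefore hinges on one number: how many spores
settled on a substrate under a given condition. `sporecyte` computes that
number — and the quantities built on it — directly from fluorescence
micrographs, using the intrinsic chlorophyll autofluorescence of the spores
as a label-free signal. It is written for bench scientists running
settlement assays and for method developers who need a fully synthetic,
ground-truthed test bed for counting pipelines.

## What it computes

**Cluster-corrected spore count.** A micrograph is thresholded (fixed value
or Otsu), connected components are enumerated as particles, and
pre-determined size/shape gates reject debris (broken flagella, specks).
Touching spores merge into a single particle, so a raw particle count
undercounts; the corrected count divides the total gated area by the mean
area of a single spore:

    N = Σᵢ Aᵢ / A₁

where `Aᵢ` are gated particle areas (μm²) and `A₁` is the single-spore
reference area — a calibration constant of the optical setup (default
5.0 × 10³ μm², overridable and re-calibratable from isolated particles).
Averaging 15–20 fields per condition brings the relative standard error of
the mean count, `100·SD/(mean·√n)`, to a few percent.

**Settlement efficiency.** The mean per-field count is scaled to the whole
substrate by the area ratio and divided by the number of spores added:
`eff = N̄ · (substrate area / field area) / N₀`.

**Adhesive-pad area.** In Cy5-labelled images spore bodies fluoresce along
with the pads, so `pad area = Cy5 foreground ∖ spore mask` (set difference,
exact: pad + excluded spore area = Cy5 area).

**FTIR lipid/protein ratio.** From band heights I₁ (1730–1800 cm⁻¹, ester
carbonyl) and I₂ (1650–1700 cm⁻¹, amide I):
`mol phospholipid / kg protein = (I₁/I₂ − 0.0175) / 0.2590`.

**Assay statistics.** Growth-rate ratios (length grown under biocide over
length grown in seawater), per-biocide dose-response tables (mean ± SD vs
concentration), and pooled/Welch two-sample t-tests with the figure star
convention (* p < 0.01, ** p < 0.001).

**Synthetic scenes.** A generator renders 2.4 mm × 1.8 mm fields of
ellipsoidal spores (optional contact clusters, debris, Cy5 pad annuli,
Gaussian noise) with exact ground truth, so every stage is testable without
a microscope.

## Worked example

```bash
python examples/count_spores.py
```

```
true spore count            : 300
raw particle count          : 235
total gated area            : 14959 um^2
cluster-corrected count     : 299.2
relative error vs truth     : 0.27%
```

The field contains 300 spores, 20% of them touching a neighbour, so only
235 connected particles are found; dividing the total gated area by
A₁ = 50 μm² recovers 299.2 — within 0.3% of the truth. The other examples
(`settlement_assay.py`, `adhesive_pads.py`, `ftir_ratio.py`,
`growth_inhibition.py`) walk through the dose-response, pad, FTIR and
growth analyses the same way; each prints what the numbers mean.

The same pipeline is available from the shell:

```bash
sporecyte simulate --n-spores 100 --out scenes/
sporecyte count scenes/*_chl.tif --pixel-size 1.5 --out results/
sporecyte ftir pad_spectrum.csv
```

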