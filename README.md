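# cytodose

Single-cell cytoskeletal morphometrics and dose-response regime analysis
for fluorescence microscopy.

## The problem

Intracellular fluorescent probes (e.g. a GFP-tagged actin-binding peptide)
are delivered with highly heterogeneous per-cell uptake, so population
averages hide strong dose-dependent side effects on the very structures
being imaged.  `cytodose` implements the single-cell alternative: measure
each cell's probe expression and its cytoskeletal/morphological state from
the same multi-channel image, pool cells into expression bins to form
dose-response curves (DRCs), and statistically segment each curve into a
**no-effect** regime, a **dose-response** regime and a **saturation
plateau**.  It is aimed at cell biologists and image analysts validating
live-cell reporters or quantifying any expression-dependent phenotype.

A synthetic-data generator with complete ground truth (rendered cells,
fibres, nuclei, migration tracks, drug-response time series) makes every
stage testable without microscope data and doubles as a benchmark tool.

## What is computed

Per cell, from GFP / stain / DAPI channels:

- **total GFP** `= Σ_pixels max(I − background, 0)` inside the cell outline
  — the expression surrogate;
- morphometrics: spread area, aspect ratio, perimeter **stellate factor**
  (perimeter / convex-hull perimeter − 1);
- fibre metrics from a three-step segmentation (multi-scale ridge
  enhancement → half-maximum refinement → diffuse-background subtraction
  by grey-scale opening): **fibre amount** (stain intensity organized in
  fibres), thickness, length, orientation coherence, radiality;
- nucleus-referenced statistics: projected nuclear area/axes,
  **nuclear/cytosolic ratio** (mean stain in the nucleus over an
  equal-area adjacent annulus) and **fibre-colocalized intensity**.

Per population:

- DRCs: cells sorted by total GFP, cut into equal-count bins (≥ n_min
  cells), pooled by geometric mean, mean or median with matching
  dispersion;
- the **ratio of variances** at each interior bin *i* of a curve *d*,

      RoV_i = var(d_{i+1..i+N}) / var(d_{i−N..i−1}),

  whose peaks (variance rising = dose-response onset; collapsing =
  saturation onset) yield per-curve candidate thresholds; geometric
  averaging across descriptors gives two global expression thresholds
  G1 < G2 used to sort individual cells into the three regimes;
- time-lapse metrics: total distance migrated, **migration
  directionality** `MD = d(P_0, P_T) / Σ_i d(P_i, P_{i+1})`, F-actin
  **interframe change** `IFC_i = 100·(FA_{i+1} − FA_i)/FA_i` and
  drug-induced **disassembly** `100·(FA_0 − FA_30)/FA_0`.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

`examples/02_dose_response_regimes.py` draws 4000 cells whose "area"
responds to expression through a piecewise transfer function (flat below
10^3.5, log-linear up to 10^5, flat above, 5% cell-to-cell scatter),
builds the DRC and segments it:

```
40 bins of >=100 cells each
    up transition at expression      2775 (bin 14, |log RoV score| 5.51)
  down transition at expression    112201 (bin 30, |log RoV score| 5.47)
global thresholds: G1 = 2775 (true 10^3.5 = 3162), G2 = 112201 (true 10^5 = 100000)
cells per regime: {'no_effect': 1450, 'dose_response': 1599, 'saturation': 951}
```

The two detected transitions sit within ~0.06 decades of the generative
breakpoints; the cells-per-regime counts are the per-cell sorting by the
recovered thresholds.  The other examples cover simulation + quantification
(`01`), migration tracks (`03`), drug-induced disassembly (`04`) and
nuclear/fibre stain statistics (`05`).

## Command line

A thin CLI wraps the same functions:

```sh
cytodose simulate --n-cells 50 --out sim/ --seed 1
cytodose quantify --in sim/ --out cells.csv
cytodose drc --cells cells.csv --descriptor area --pool gmean --nmin 100 --out drc.csv
cytodose regimes --cells cells.csv --descriptors area,fibre_amount --out thresholds.json
cytodose migrate --positions pos.csv --out tracks.csv
cytodose disassemble --series fa.csv --t-end 30 --out out.csv
cytodose coloc --in sim/ --out coloc.csv
cytodose run-all --config run.json
```

Images are per-channel 16-bit TIFFs with a JSON sidecar (channel order,
pixel size); tables are headered CSV; thresholds and configuration are
JSON.

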