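# Methods

This document records the model assumptions behind each stage of
`picosize`, the parameters with their units and defaults, what the
synthetic-data generator does and does not emulate, the numerical
choices, and the known limitations. Nothing here is an empirical claim
about real oceans; every number either is a configurable default or is
computed by the code in this repository.

## 1. Flow-cytometry route (`picosize.fcm`)

### Gating

Events carry three signals: forward scatter `FSC` (size proxy), orange
fluorescence `FL2` (phycoerythrin) and red fluorescence `FL3`
(chlorophyll). Gating applies fixed thresholds in a fixed rule order:

1. `FL3 < fl3_threshold` → **unclassified** (non-photosynthetic noise);
2. else `FL2 ≥ fl2_threshold` → **Synechococcus** (phycoerythrin);
3. else `FSC < fsc_threshold` → **Prochlorococcus**;
4. else → **picoeukaryote**.

| parameter | units | default |
|---|---|---|
| `fl2_threshold` | a.u. | 50 |
| `fl3_threshold` | a.u. | 5 |
| `fsc_threshold` | a.u. | 128 |
| `log_transform` | — | False |

The rule order matters: a large, phycoerythrin-bright cell is
Synechococcus, not a picoeukaryote. `log_transform` gates on log10
signals with log10 thresholds; for positive signals the labels are
identical (tested), it only exists for workflows storing log-scale data.

Assumptions: thresholds are global (no per-sample re-gating, no
cluster-based gating); populations are separable in these three
channels; doublets and detritus land in `unclassified` via FL3.

### Abundance

`abundance = gated events / analyzed_volume_ml` (cells · mL⁻¹), with
`analyzed_volume_ml` default 0.1 mL. No flow-rate calibration or bead
ratio correction is modeled.

### Size calibration

Let `r = MFSC / MFSC_ref` with MFSC the arithmetic mean FSC of the gated
population. Two forms:

- `log_linear` (analysis default): `d = d_ref · exp(k·(r − 1))`,
  monotone increasing in scatter, slope `k` (default 1.0).
- `printed_power`: `d = d_ref^r`. For `d_ref < 1` μm this is
  *decreasing* in scatter — physically inverted — so the code emits a
  `UserWarning` whenever it is evaluated off-anchor with `d_ref < 1`.
  It is retained because some published workflows state this form; it
  is not used by the analysis scripts.

Both forms return exactly `d_ref` (default 0.6 μm, a bead-equivalent
Prochlorococcus reference) at `r = 1`; `mfsc_ref` defaults to 100 a.u.
`population_summary` and `pooled_diameter_table` by default
*self-calibrate*: `mfsc_ref` is re-anchored on the gated
Prochlorococcus population of the data at hand (so Prochlorococcus gets
`d_ref` by construction and other populations are sized relative to it),
while form, slope and `d_ref` come from the supplied model.

Survey-wide diameters are reported as mean ± sd: the mean from the
pooled population MFSC, the sd from the spread of per-event calibrated
diameters (ddof = 1).

## 2. Size-fractionation route (`picosize.sm`)

### Fractions

Serial filtration bounds: 0.2, 0.6, 1.2, 2.0 μm → fractions 0.2–0.6,
0.6–1.2, 1.2–2 μm with midpoints 0.4, 0.9, 1.6 μm. The 2.0 μm
pre-filter removes larger material from the picoplankton dataset.
Bounds are configurable (`parse_fractions`).

### OTU filtering

Three removal rules, applied to the raw count table with its taxonomy:

1. **Low abundance**: total reads across all samples *of the OTU's
   marker* strictly below `min_total_fraction` (default 5 × 10⁻⁵, i.e.
   0.005%) of that marker's grand total. Per-marker denominators keep
   the 16S and 18S libraries from diluting each other's threshold.
2. **Low confidence**: annotation confidence `< min_confidence`
   (default 0.6).
3. **Excluded lineages**: Archaea, Fungi, Embryophyta, Metazoa
   (configurable), plus OTUs with no annotation.

Filtering is idempotent: removing reads can only lower a marker's total,
so no surviving OTU can fall below the threshold on a second pass
(tested, including the exact-threshold boundary).

### Size spectra and diameter

For a group (the two cyanobacterial genera match the taxonomy `group`
column exactly; `picoeukaryote` means every 18S OTU not excluded and not
background/debris), reads are summed per fraction and normalized to
proportions `N%_f`. Two pooling conventions:

- `normalize="raw"`: pool raw read counts (the convention behind
  published per-fraction percentages; used by the analysis because the
  simulated design has equal per-sample depth);
- `normalize="library"`: scale each sample to its library size first,
  so uneven sequencing depth cannot masquerade as size structure.

The diameter is `d = Σ_f midpoint_f · N%_f` (μm). Proportions must sum
to 1 within 10⁻⁶. This estimator is bounded by the extreme midpoints
[0.4, 1.6 μm] by construction — it cannot see sizes outside the
filtered window, one of its structural biases.

## 3. Statistics (`picosize.stats`)

All computed from formulas; SciPy supplies only reference distributions
(F, χ², t). Independent cross-checks against `scipy.stats` and
`scikit-bio` live in the test suite.

- **Richness** S: OTUs with count > 0.
- **Chao1**: `S + F1²/(2·F2)` (classic form); when `F2 = 0`,
  `S + F1(F1−1)/2` (bias-corrected fallback).
- **Shannon** (natural log): `−Σ p ln p`.
- **Simpson** (Gini–Simpson): `1 − Σ p²`.
- **One-way ANOVA**: F = between/within mean squares, p from
  `F(k−1, N−k)`.
- **Kruskal–Wallis**: midranks, tie-corrected H, p from `χ²(k−1)`.
- **Pearson r** with the t-transform p-value
  `t = r·√((n−2)/(1−r²))`; returns NaN for zero-variance input.
- Significance stars at 0.05 / 0.01 / 0.001; optional Benjamini–
  Hochberg correction for the correlation matrices.

Environmental correlations require ≥ 3 shared depths and exclude
chlorophyll a by convention in the analysis scripts, because in the
simulator chlorophyll is itself a function of the communities.

## 4. Comparison (`picosize.compare`)

`compare_diameters` flags a group as agreeing when the SM point estimate
falls within the FCM `mean ± n_sd · sd`. Default `n_sd = 2.0`: the
cytometric mean ± sd describes a *population size distribution*, and the
question asked is whether the SM estimate lies in its central ~95%
range; at 1 sd even two unbiased estimators of the same population
disagree often. `profile_concordance` compares vertical profiles only
by Spearman rank (reads and cells · mL⁻¹ are incommensurable) plus
whether both peak at the same depth.

## 5. Synthetic-data generator (`picosize.synthetic`)

The generator emulates, with ground truth retained at every stage:

- **Cell sizes**: log-normal per taxon (median `size_median_um`, log-sd
  `size_log_sd`).
- **Depth structure**: fixed relative abundance profiles over the
  sampled depths (5, 25, 50, 113, 150, 200 m; 113 m plays the deep
  chlorophyll maximum).
- **Environment**: temperature, salinity and nutrients linear in depth
  between fixed anchors (e.g. temperature 29.1 → 15.7 °C over
  5 → 200 m); chlorophyll a a Gaussian bump (max 0.49 μg · L⁻¹ at
  113 m, width 35 m); optional multiplicative noise (default 0).
- **FCM events**: taxa drawn ∝ depth profile; FSC is the exact inverse
  of the configured calibration at the cell's drawn diameter times
  log-normal noise (log-sd default 0.05); FL2/FL3 log-normal per taxon.
  `simulate_event_series` scales per-depth event counts with the total
  cell concentration (fixed analyzed volume ⇒ proportional counts).
- **Serial filtration**: exact integer cell accounting
  (captured + passed + discarded = n); retention per filter is logistic
  in `log(d/pore)` with steepness 25 (or an ideal step), filters met in
  decreasing pore order, first success captures.
- **Fragility**: a captured cell of a fragile taxon breaks with
  probability `fragility`, moving `frag_split` (default 0.5) of its unit
  read weight into the smallest fraction — the mechanism by which large
  but delicate cells contaminate small fractions. Same-seed coupling
  makes the small-fraction share strictly monotone in fragility.
- **Debris**: taxa flagged `debris` deposit uniformly across fractions
  (clogging/adsorption, not sieving) and emit no FCM events. They model
  the background material (shed plastids, metazoan fragments) that real
  libraries contain.
- **Reads**: per (depth, fraction, marker) sample, one multinomial draw
  of fixed size `read_depth` over captured weight × rRNA copy number.
  **Consequence**: read counts are compositional. A sample containing a
  single taxon always shows a flat read share regardless of absolute
  material, so per-fraction read proportions are informative about size
  only when a shared background (debris) anchors each library. The
  stock community therefore includes dominant debris taxa in both
  markers; this is a design requirement of the generator, not a tuning
  knob.
- **Contaminants** (`with_contaminants`): an archaeon, a fungus, a
  metazoan, a low-confidence OTU, an unannotated OTU and an
  ultra-rare OTU — one for each filter rule.

The generator does **not** emulate: PCR/primer bias, chimeras or
sequencing error (reads map to true taxa); filter saturation or volume
effects; diel or seasonal cycles; light fields; aggregation/doublets;
viruses or heterotrophs beyond the debris/contaminant stand-ins; real
taxonomic breadth (the stock community has ~15 taxa, not thousands of
OTUs).

### Stock community defaults (selected)

| taxon | marker | median μm | depth peak | notes |
|---|---|---|---|---|
| Prochlorococcus | 16S | 0.6 | 113 m | copy number 1 |
| Synechococcus | 16S | 0.9 | surface | copy number 2 |
| Micromonas, Pelagomonas, … | 18S | 1.0–1.6 | various | picoeukaryotes |
| Hemiselmis | 18S | 1.5 | 113 m | fragility 0.5 |
| debris (both markers) | — | — | uniform | `debris=True`, no events |

## 6. Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng`;
  multi-component simulations split seeds with `SeedSequence.spawn`, so
  every depth/stage gets an independent stream and outputs are a pure
  function of (config, seed). The end-to-end workflow is byte-identical
  across reruns (tested).
- Default seed 20181104.
- Population MFSC uses the arithmetic mean (the "M" in MFSC); diameter
  sd uses ddof = 1.
- Kruskal–Wallis uses midranks with the standard tie correction;
  p-values are upper-tail survival functions (`sf`), not `1 − cdf`, for
  accuracy in the tails.
- Tables are plain TSV/CSV; sample columns are flat ids
  `<depth>m_<fraction>_<marker>` on disk and a
  (depth, fraction, marker) MultiIndex in memory. Depths are
  canonicalized to floats on read.

## 7. Limitations

- The SM diameter is bounded by the fraction midpoints and is biased
  toward the interior of the filtered window; it cannot distinguish
  sizes within a fraction.
- The FCM route sizes only relative to the self-calibration anchor; if
  the Prochlorococcus reference diameter is wrong, all diameters scale
  with it.
- The `printed_power` calibration is physically inverted below 1 μm and
  kept only for comparability; do not use it for analysis.
- Compositional read counts mean per-group fraction proportions are
  meaningful only with a shared background per library (see §5); with a
  fixed read depth, absolute read counts carry no abundance information
  across samples.
- Agreement at `mean ± 2 sd` is a weak test when the cytometric sd is
  large (the picoeukaryote sd spans most of the pico range); the
  comparison table reports absolute and relative differences alongside
  the flag for that reason.
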