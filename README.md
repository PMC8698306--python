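# picosize

Sizing marine picophytoplankton two independent ways — and checking that
the two ways agree.

## The scientific problem

Picophytoplankton (photosynthetic cells < 2 μm: *Prochlorococcus*,
*Synechococcus* and picoeukaryotes) dominate primary production in
oligotrophic oceans, but measuring how big their cells actually are is
awkward at sub-micron scales. Two routes are in common use:

1. **Flow cytometry (FCM).** Events are gated into the three populations
   from their fluorescence and scatter signals (orange FL2 separates
   phycoerythrin-bearing *Synechococcus*; red FL3 separates
   photosynthetic cells from noise; forward scatter FSC separates small
   *Prochlorococcus* from larger picoeukaryotes). A population's mean
   forward scatter (MFSC), compared against a reference population of
   known bead-equivalent diameter, yields a calibrated cell diameter.
2. **Size-fractionated filtration + sequencing ("SM").** Seawater is
   passed serially through 2.0, 1.2, 0.6 and 0.2 μm filters; the
   0.2–0.6, 0.6–1.2 and 1.2–2 μm fractions are sequenced (16S for the
   cyanobacteria, 18S for picoeukaryotes). The distribution of a group's
   reads over the three fractions is a crude size spectrum, and the
   midpoint-weighted average
   `d = Σ_f midpoint_f · N%_f` (midpoints 0.4, 0.9, 1.6 μm)
   is a sequencing-based diameter estimate.

Each route has independent failure modes (gating thresholds and bead
calibration for FCM; cell breakage, filter clogging, rRNA copy number
and compositional read counts for SM), so their agreement on the same
water is a meaningful cross-validation. This package implements both
routes, the statistics around them (alpha diversity, fraction
comparisons, environmental correlations), and a ground-truthed community
simulator that makes the whole chain testable end to end.

## The model

- **Gating** applies fixed thresholds in a fixed rule order: events below
  the FL3 threshold are unclassified noise; of the rest, FL2 above
  threshold → *Synechococcus*; FSC below threshold → *Prochlorococcus*;
  otherwise picoeukaryote.
- **Calibration** maps the MFSC ratio `r = MFSC / MFSC_ref` to diameter.
  Two forms are provided: `log_linear` (default for analysis),
  `d = d_ref · exp(k·(r − 1))`, monotone increasing; and
  `printed_power`, `d = d_ref^r`, which is *decreasing* in scatter for
  `d_ref < 1` μm and therefore emits a warning when used off-anchor.
  Both return exactly `d_ref` (default 0.6 μm) at `r = 1`.
- **The SM route** filters OTUs (per-marker relative abundance < 0.005%,
  annotation confidence < 0.6, non-target lineages, unannotated),
  computes each group's read proportions over the fractions, and applies
  the midpoint formula.
- **The simulator** draws log-normal cell sizes per taxon, pushes cells
  through serial filtration with a logistic (or ideal step) retention
  model, optional cell breakage ("fragility") that leaks material into
  the smallest fraction, fraction-uniform debris material, rRNA copy
  numbers, and fixed-depth multinomial read sampling per
  (depth, fraction, marker) sample. FCM events are generated by exactly
  inverting the configured calibration at each cell's true diameter,
  plus log-normal noise. Every stage keeps its ground truth, so
  parameter recovery can be asserted, not eyeballed.

See `docs/methods.md` for assumptions, parameter tables and limitations.

## Worked example

```python
import picosize as ps

art = ps.run_full_workflow(out_dir="scratch/demo", seed=20181104)
print(art["comparison"][["fcm_mean_um", "fcm_sd_um", "sm_um", "within_interval"]])
```

```text
                 fcm_mean_um  fcm_sd_um     sm_um  within_interval
group
Prochlorococcus     0.600000   0.087519  0.632169             True
Synechococcus       0.919257   0.132179  0.926430             True
picoeukaryote       1.228320   0.358303  1.316533             True
```

The same pipeline is available step by step on the command line:

```bash
picosize simulate --out scratch/sim --seed 20181104
picosize fcm  --events scratch/sim --out scratch/fcm
picosize sm   --otu scratch/sim/otu.tsv --tax scratch/sim/taxonomy.tsv \
              --raw-counts --out scratch/sm
picosize stats --otu scratch/sm/otu_filtered.tsv \
               --env scratch/sim/environment.csv \
               --tax scratch/sim/taxonomy.tsv --out scratch/stats
picosize all  --out scratch/run        # the whole workflow in one go
```

And the published-value computation needs no simulation at all:

```python
import pandas as pd, picosize as ps
props = pd.Series([0.5986, 0.2793, 0.1221],  # Prochlorococcus N% per fraction
                  index=["0.2-0.6", "0.6-1.2", "1.2-2"])
ps.estimate_diameter_sm(props)     # -> 0.68617  (≈ 0.69 μm)
```

## Layout

- `src/picosize/` — the library (all computation lives here):
  `fcm`, `sm`, `stats`, `synthetic`, `compare`, `io`, `cli`, `fractions`
- `analysis/` — thin numbered driver scripts over the library
- `scripts/acceptance.py` — standalone recomputation of the headline values
- `tests/` — unit, property-based (hypothesis) and acceptance tests
- `docs/methods.md` — model assumptions, parameters and limitations
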