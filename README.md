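# synquant

Quantification of supramolecular signaling structures in the T cell
immunological synapse from 3D time-lapse fluorescence imaging.

When a T cell engages an antigen presenting cell (APC), GFP-tagged
signaling sensors (LAT, TCRζ, F-tractin, DAG sensors, …) redistribute
within seconds into large subcellular structures at the cell–cell
interface: a central supramolecular activation cluster (cSMAC), a µm-deep
presumably degradative invagination, peripheral F-actin rings, interface
lamellae, and more. The distribution of these patterns over time — across
dozens of cell couples per condition — is a sensitive fingerprint of T cell
signaling; effector T cells and T cells with regulatory capability differ
sharply in it. `synquant` implements the complete quantification pipeline
for such experiments, together with a ground-truthed synthetic image
generator so every stage is testable without microscope data.

## What the pipeline computes

Given 4D spinning-disk acquisitions (by default 21 z-sections at 1 µm
intervals every 20 s) of a GFP⁺ T cell conjugated to a non-fluorescent APC:

1. **Couple tracking** — per-frame T cell/APC segmentation, contact
   detection, interface geometry (center **c**, inward normal **n̂**,
   diameter *d*), and the tight-coupling reference frame
   *t₀* = min(first full-width frame, contact + 40 s), whichever comes
   first.
2. **Pattern classification** — interface enrichment
   *E* = I_shell / I_background − 1 against the 35% rule (*E* < 0.35 ⇒ no
   accumulation), then one of six mutually exclusive patterns
   {central, invagination, diffuse, lamellal, peripheral, asymmetric} by
   geometric rules applied to the enriched voxel set, in fixed precedence
   (depth first: an invagination reaches > 1.5 µm behind the interface
   while the cSMAC stays at it).
3. **Shape standardization** — each cell is reoriented with the interface
   facing up (one-point landmark + normal alignment) and morphed onto a
   canonical half-spheroid grid; enrichment is the ratio of the mean
   probability in the *interface enrichment region* (top 10% voxels of the
   cohort-average map) to the whole-cell mean, and likewise for a *central
   core* cylinder of relative radius and depth 0.5.
4. **Morphometrics** — interface diameter, cell width/length along the
   (possibly bent) midline, neck detection with the > 1.3 µm scorable-
   lamella rule, T cell shape factor = lamellal length / interface
   diameter, and off-interface lamella detection.
5. **Cohort statistics** — percent-of-couples time courses with binomial
   (or per-experiment) dispersion, the log₂(central/invagination) ratio
   curve (continuity-corrected, log₂((k_c+½)/(k_i+½))), cumulative
   off-interface lamella fractions, and exact two-proportion condition
   comparisons with Holm adjustment.

The synthetic generator (`synquant.synth`) renders couples as spheres with
a flattened contact disc, places sensor accumulation templates for each of
the six patterns at controllable contrast, adds Poisson + Gaussian camera
noise, draws per-couple pattern timelines from programmable per-timepoint
frequency schedules, and supports shape events (early lamellae, necks,
off-interface protrusions). Everything is deterministic given a seed.

## Worked example

```python
from synquant import (AcquisitionSpec, SynthCoupleSpec, simulate_couple,
                      track_couple, classify_timeline, pattern_frequencies,
                      central_invagination_ratio, simulate_cohort,
                      teff_like_schedule)

spec = SynthCoupleSpec(
    seed=42, contact_frame=1,
    acquisition=AcquisitionSpec(n_frames=8),
    pattern_schedule=[(1, "central"), (5, "invagination")],
)
series, truth, frame_labels = simulate_couple(spec)
track = track_couple(series)
print(f"tight coupling at frame {track.t0} "
      f"(interface diameter {track.interfaces[track.t0].diameter:.2f} um)")
timeline = classify_timeline(track, series.data[:, 0], series.spacing)
for t, label in sorted(timeline.items()):
    print(f"  {t:+6.0f} s  {label}")
```

prints

```
tight coupling at frame 1 (interface diameter 6.00 um)
     -20 s  none
      +0 s  central
     +20 s  central
     +40 s  central
     +60 s  central
     +80 s  invagination
    +100 s  invagination
    +120 s  invagination
```

i.e. the couple forms instantly (full interface width in its first contact
frame, so the 40 s rule never fires), the sensor is classified as cSMAC-
like central accumulation for the first minute and as the deep
invagination afterwards — exactly the programmed schedule. At cohort
level:

```python
sched = teff_like_schedule("teff_like", n_couples=500, seed=7)
table = pattern_frequencies(
    [s.timeline for s in simulate_cohort(sched)], "teff_like")
row = table[table.pattern == "central"].iloc[0]
print(f"central: {row.percent:.1f} +/- {row.se:.1f}% of {row.n} couples")
ratio = central_invagination_ratio(table)
print(f"log2 central/invagination: "
      f"{ratio.log2_central_over_invagination.iloc[0]:.2f}")
```

```
central: 40.6 +/- 2.2% of 500 couples
log2 central/invagination: 1.49
```

The schedule programmed 42% central and 13% invagination at +20 s; the
draw of 500 couples recovers 40.6 ± 2.2% and a positive log₂ ratio
(central-preferring), as an effector-like condition should.

## Command line

```sh
synquant run-all --out results/demo --seed 1          # built-in demo config
synquant simulate --config cfg.yaml --out cohorts/    # OME-TIFFs + truth CSVs
synquant track cohorts/teff/*.ome.tif --out tracks/
synquant classify ... / standardize ... / morph ... / summarize ...
```

`run-all` emits tidy CSVs (patterns, frequencies, ratio, morphometry,
cumulative off-interface, condition comparisons, standardized-map
ratios), the average standardized map, and SVG time-course/ratio figures;
identical config + seed gives byte-identical CSVs.

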