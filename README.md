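# polorder

Analysis of **excitation-resolved fluorescence polarization microscopy (FPM)**
for quantifying the orientational order of fluorophore dipole ensembles in
punctate cell–cell junctions (desmosomes). It is aimed at microscopists who
acquire four-polarization excitation stacks and want per-pixel order maps,
per-junction order statistics, and the group comparisons used to track
junction assembly — plus a forward simulator with known ground truth for
validating every stage without real micrographs.

## The measurement

A field is imaged four times with linear excitation polarization at θ = 0°,
45°, 90°, 135° from the x-axis. After flat-field correction and pixel-wise
max-normalization of the four intensities I0, I45, I90, I135:

```
A  = I0 − I90            B  = I45 − I135
OF = √(A² + B²)          α  = arctan2(B, A) / 2
```

The **Order Factor (OF)** reports how aligned the dipoles within one pixel
are; the **azimuth α** (axial, reported on (−90°, +90°]) is their mean
in-plane orientation. Puncta are segmented from the average-intensity image
(top-hat radius 3, Otsu threshold, 4-connected components), filtered by local
signal-to-background (S/B < 3 excluded), and summarized per object by the mean
OF and by the **azimuthal disorder** s0 — the circular standard deviation of
member azimuths computed on doubled angles:

```
r̄ = (1/N) Σ exp(2iαₙ),   R = ‖r̄‖,   s0 = √(−2 ln R) / 2   (degrees)
```

Timepoint groups are compared with Kruskal–Wallis + Dunn (comparisons
restricted to neighboring timepoints and the untreated control before
adjustment), fragment-count tables with one-way ANOVA + Sidak, and
scratch-wound border pairs (nearest vs farthest punctum from the leading edge)
with a paired t-test. See `docs/methods.md` for the full model and the
numerical conventions.

## Worked example

Simulate a "gradual assembly" series — five labels whose dipole spread σ_d
tightens from 60° to 10° — run the full pipeline, and compare object OF across
labels:

```python
import polorder as po

fields, manifest = po.render_assembly_series(
    po.SPREAD_PRESETS["gradual"], rng=7, n_fields_per_label=3)
objects = po.process_fields(fields)              # correct → map → segment → filter
report = po.compare_timepoints(objects, metric="mean_of",
                               order=["2h", "4h", "6h", "8h", "no-pulse"])
print(report.group_summary.to_string(index=False))
print(f"Kruskal-Wallis H = {report.statistic:.1f}, p = {report.p_value:.3g}")
for c in report.comparisons:
    print(f"  {c.group_a} vs {c.group_b}: z = {c.statistic:+.2f}, "
          f"adjusted p = {c.p_adj:.3g}")
```

Output:

```
   group   n   median  iqr_low  iqr_high
      2h 255 0.238423 0.205156  0.268670
      4h 255 0.528644 0.483163  0.566476
      6h 255 0.768567 0.737897  0.791014
      8h 255 0.876554 0.860945  0.893956
no-pulse 255 0.911907 0.898775  0.924853
Kruskal-Wallis H = 1190.3, p = 2.02e-256
  2h vs 4h: z = -7.81, adjusted p = 4.1e-14
  4h vs 6h: z = -7.88, adjusted p = 2.33e-14
  6h vs 8h: z = -8.83, adjusted p = 7.41e-18
  2h vs no-pulse: z = -30.15, adjusted p = 8.33e-199
  4h vs no-pulse: z = -22.34, adjusted p = 1.07e-109
  6h vs no-pulse: z = -14.46, adjusted p = 1.48e-46
  8h vs no-pulse: z = -5.63, adjusted p = 1.24e-07
```

The median object OF rises monotonically as the simulated dipole spread
tightens (0.24 → 0.91 over 255 retained puncta per label), every restricted
pairwise comparison is significant after adjustment, and the same pipeline
reports the complementary trend (falling azimuthal disorder) via
`metric="azimuth_csd_deg"`.

The same stages are available from the shell:

```
polorder simulate --preset gradual --seed 7 --out-dir sim/
polorder objects --in sim/2h-f0.tif --flat sim/2h-f0_flat.tif --out objects.csv
polorder stats timepoints --objects objects.csv
```

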