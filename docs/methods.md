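# Methods

## The measurement

Excitation-resolved fluorescence polarization microscopy (FPM) probes the
in-plane orientational order of fluorophore transition dipoles. Each field of
view is acquired as a stack of four images at excitation polarizations 0°,
45°, 90° and 135° (measured from the positive x-axis). A dipole at in-plane
angle φ absorbs in proportion to cos²(θ − φ), so the four-channel modulation of
a pixel encodes both how aligned its dipole ensemble is and the ensemble's mean
orientation.

Processing chain per field:

1. **Flat-field correction.** Reference stacks acquired on a uniformly
   autofluorescent slide are averaged per polarization and normalized to the
   single global maximum of the averaged four-image stack. The raw stack is
   divided element-wise by this reference. Flat fields containing elements
   ≤ 1e−6 of their maximum are rejected at build time — division semantics are
   otherwise undefined. Note the normalized reference is known only up to
   scale, so corrected intensities recover the unvignetted scene up to a
   global factor; every downstream quantity (OF, azimuth, S/B) is a ratio and
   is unaffected.
2. **Pixel-wise normalization.** Each pixel's four intensities are divided by
   their maximum across polarizations. Pixels whose maximum is 0 carry value 0
   and a `valid_mask = False` flag that propagates downstream (0/0 has no
   physical meaning).
3. **Order Factor and azimuth.** With normalized intensities I0, I45, I90,
   I135:

       A = I0 − I90,   B = I45 − I135
       OF = √(A² + B²),   α = arctan2(B, A) / 2

   α is axial (180° ambiguity) and reported in degrees on (−90, +90];
   computation is in radians internally. Two deliberate properties:

   * **OF is not clipped.** Because of the per-pixel max-normalization the
     estimator is not rotation invariant: a perfectly aligned ensemble yields
     OF = 1 on an acquisition axis but 2/(1 + cos 45°) ≈ 1.172 at 22.5°
     between axes. Clipping would silently alter the published estimator; the
     value is reported as computed and the property is covered by a test.
   * **α is undefined where OF = 0.** arctan2(0, 0) is convention-dependent;
     such pixels are flagged rather than assigned 0 so the disorder statistics
     never ingest fabricated angles.
4. **Segmentation.** The average-intensity image (mean of the four corrected
   channels) is background-flattened with a white top-hat transform (disk
   structuring element, radius 3 px), thresholded by Otsu's method (256
   histogram bins, computed on the top-hat image itself), and split into
   4-connected components.
5. **Object metrics.**
   * object OF = mean OF over member pixels (pixels with `valid_mask = False`
     carry no measurement and are excluded; an object needs ≥ 2 defined
     azimuths or it is flagged and dropped by the filter);
   * azimuthal disorder s0 = circular SD of member azimuths. Angles are
     doubled to remove the axial ambiguity: r̄ = (1/N) Σ exp(2iα_n),
     R = ‖r̄‖, s_2α = √(−2 ln R), and s0 = s_2α / 2 maps back to the azimuth
     scale. R < 1e−12 (perfect dispersion up to rounding; e.g. equal mass at
     0° and 90°) reports +∞ with a warning; a wrapped-normal population with
     SD σ recovers s0 ≈ σ, which is the estimator-recovery test.
   * local S/B = object mean over background-ring mean on the
     average-intensity image. A 3-pixel buffer around the object is excluded;
     the ring is the next 2-pixel zone. Widths are measured in city-block
     distance by default, matching the 4-connectivity of the components
     (Chebyshev available via `metric="chessboard"`). Ring pixels inside any
     other object or its buffer are excluded — puncta cluster along borders
     and neighbor signal would inflate the background. Edge objects are kept
     unless their ring is fully clipped.
6. **Filtering.** Objects with S/B < 3 are excluded; the rule is strict, so
   S/B = 3.0 is retained and 2.99 is not.

## Line scans and border pairing

An OF line scan between two anchor points uses 18 parallel lines at 1-px
lateral spacing (≈ 2 μm at 0.108 μm/px), sampled at 1-px steps with bilinear
interpolation and averaged along the normal direction. Masking is
conservative: a sample contributes only if its entire 4-pixel bilinear support
lies inside the analysis mask. Anchors are explicit coordinates (from config
or simulation ground truth) so scans are reproducible.

For wounded monolayers, the two puncta flanking a border are grouped by
distance to the leading edge (nearest = A, farthest = B) and compared with a
two-sided paired t-test across borders. Confluent controls have no edge, so
each border's puncta are randomly split (seeded) into A′/B′ halves compared by
group means.

## Statistics

Timepoint comparisons of object OF or s0 use Kruskal–Wallis followed by Dunn's
multiple-comparisons test; fragment-count tables use ordinary one-way ANOVA
followed by Sidak-adjusted pairwise tests on the pooled ANOVA error term.
In both, comparisons are restricted **before** adjustment to neighboring
timepoints plus each timepoint vs the no-pulse control (7 comparisons for a
4-timepoint series), and the adjustment runs over exactly that set. Dunn's
test uses midranks with the standard tie correction
Σ(t³−t)/(12(N−1)) and Bonferroni adjustment over the comparisons made; it is
implemented in `polorder.stats` and validated against hand-computed oracles.
Degenerate inputs (all observations identical; zero-variance paired
differences) are flagged in the report notes rather than returning NaNs
silently.

## The synthetic-scene generator

Real acquisitions of this kind are not publicly deposited, so the package
ships a forward simulator whose ground truth makes every stage verifiable.

**Dipole model.** Each punctum is a disk (default diameter 5 px, roughly a
diffraction-limited desmosome at 60×/1.49 NA, 0.108 μm/px) of dipoles
following a wrapped normal around a mean azimuth — chosen for its closed-form
second circular moment c₂ = exp(−2σ²), which gives the analytic channel
response ⟨cos²(θ−φ)⟩ = ½(1 + c₂ cos 2(θ−μ)) and hence an analytic
ground-truth OF:

    OF_true = 2 c₂ / (1 + c₂ · max(|cos 2μ|, |sin 2μ|)).

**Spread partition.** The punctum's total dipole spread σ_d is split into a
within-pixel component σ_w and a between-pixel component σ_b with
σ_w² + σ_b² = σ_d² (equal split by default): each pixel's sub-ensemble mean is
drawn around the punctum mean with spread σ_b, and the pixel's four-channel
modulation uses c₂(σ_w). One knob therefore degrades both readouts together —
σ_w lowers pixel OF, σ_b raises the object's azimuthal disorder — the way
junction immaturity affects both.

**Rendering.** expected = background + puncta responses, blurred by an
isotropic Gaussian PSF (default σ = 1.2 px), multiplied by a radial vignette
(default 30% corner falloff), then Poisson shot noise and Gaussian read noise
(default σ = 2 photons-equivalent). Defaults: background 20 and punctum
amplitude 400 expected photons/pixel, giving bright puncta at S/B ≈ 8–10 after
blur. Rendering is bit-deterministic given the scene seed.

**Study-design presets.** The assembly series renders five labels
(2h, 4h, 6h, 8h, no-pulse) with per-label spread schedules: "gradual"
60→40→25→15→10°, "constant" 10° throughout, "stepwise" 60/60/60/10/10°; three
256×256 fields of ~85 puncta per label give ≥ 200 retained objects per label.
Scratch-wound scenes place borders perpendicular to a straight leading edge
with spread either graded in edge distance (55°→10°) or flat (confluent
control). These sizes keep the full acceptance run under a minute; they are
the package's default study scale.

**What the simulator does not emulate.** Out-of-plane dipole tilt (the
measurement is an in-plane projection), vectorial high-NA excitation,
emission-side anisotropy, photobleaching, spectral bleed-through, irregular
(curved, crowded) border geometry, and camera fixed-pattern artifacts beyond a
smooth vignette. Passing tests therefore demonstrate correctness of the
estimators and pipeline logic under the stated model, not robustness to every
property of real micrographs. Note also that the PSF spatially correlates
neighboring pixels, so the measured azimuthal disorder of a punctum
underestimates σ_b in absolute terms while remaining strictly monotone in it —
the monotonicity, not the absolute scale, is the validated readout.

## Numerical choices

* Otsu: 256 equal-width bins on the top-hat image; matches exhaustive
  between-class-variance maximization (tested).
* Circular SD: R < 1e−12 → +∞ sentinel; R ≥ 1 → 0.
* Bit-exactness: the vectorized OF/azimuth maps equal a per-pixel scalar-loop
  oracle exactly (same IEEE operations in both paths).
* Line-scan interpolation: bilinear; samples with any support pixel outside
  the mask are dropped entirely.
* Simulated raw stacks are written as 16-bit unsigned TIFF, derived rasters as
  32-bit float TIFF; in-memory computation is float64 throughout.

## Known limitations

* S/B is computed on the average-intensity image; a single-channel variant is
  not offered.
* Watershed splitting of touching puncta, subpixel localization and time-lapse
  tracking are out of scope.
* The wrapped-normal dipole model is a modeling choice, not a biological
  claim; presets are labeled as models.
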