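# Methods

This note documents the model, the parameter choices, and the synthetic
data generator of `cathdose`, in enough detail to audit or re-derive every
number the package produces.

## 1. Phantom geometry and regions

The operator's head is modelled as an anthropomorphic head phantom with
four TLD-bearing slices (numbered 2–5, each 2.5 cm thick) rasterized on a
512×512 pixel matrix (0.45 mm in-plane spacing, matching a head CT
reconstruction). Each slice carries a brain mask and a grid of drilled
holes; two extra positions outside the slices represent the eye lenses.

Brain regions are defined by simple thresholds on the raster (0-based,
`x` = column):

| region | rule |
|---|---|
| upper | slices 2–3 |
| lower | slices 4–5 |
| left  | x ≥ 248 |
| right | x ≤ 247 |
| front | y ≤ 262 |
| rear  | y ≥ 263 |

The left/right and front/rear splits are exhaustive and mutually exclusive
(adjacent thresholds are validated), so every brain pixel belongs to exactly
one label per axis. Masks are serialized as per-row run-length encodings in
JSON, keeping geometry files small and text-only.

## 2. TLD dosimetry

Each hole holds a TLD pair. A reading converts to absorbed dose as

```
dose = raw_reading × calibration_factor × energy_correction   [µGy]
```

Pair members are averaged. Doses below the 10 µGy detection limit are
flagged; a relative pair discrepancy `|d1 − d2| / (d1 + d2)` above 0.10 is
flagged as suspect. Each measurement session (one C-arm configuration)
records the patient-phantom P_KA delivered, and every position dose is
normalized to a conversion coefficient `CC = dose / P_KA`
(µGy per Gy·cm²). Session P_KA values of a few hundred Gy·cm² keep all
true doses well above the detection limit.

## 3. Dose maps and region means

Per slice, the hole CCs are interpolated to the full pixel grid with a
thin-plate-spline radial basis function (`scipy.interpolate.RBFInterpolator`,
smoothing 0, degree-1 polynomial tail). This choice makes the interpolant
exact at the measurement points and reproduces affine fields exactly; the
degree-1 tail keeps extrapolation outside the hole convex hull linear
rather than divergent. Negative extrapolated values are clipped to zero and
the clipped fraction is reported. At least three non-collinear points per
slice are required (checked via matrix rank).

Region mean CCs are pooled pixel means over all slices intersecting the
region — i.e. weighted by region volume, not by slice. Eye-lens CCs come
directly from the eye positions (single pair, no interpolation).

Accuracy caveat: interpolation is only trustworthy inside the convex hull
of the holes; the end-to-end validation below therefore checks recovery
against ground truth restricted to the hull.

## 4. Clinical exposure binning

Irradiation-event logs carry per-event modality, C-arm rotation and
angulation, and P_KA. Events are retained only if `|rotation| ≤ 45°` **and**
`|angulation| ≤ 45°` (closed interval, conjunctive). Retained angles are
binned to centers −30/0/+30 with edges at ±15°: `[−45,−15) → −30`,
`[−15,15) → 0`, `[15,45] → +30`. The 3×3 projection grid × 2 modalities
gives 18 cells; each cell's weight is its P_KA sum divided by the total
in-range P_KA, so the weights sum to exactly 1 over retained events.

## 5. Exposure weighting

Acquisition CCs exist for all nine projections, but fluoroscopy was measured
at one reference projection only (LAO30). Fluoroscopy CCs for every
projection are obtained per target by scaling:

```
CC_fl(p, t) = CC_acq(p, t) × CC_fl(LAO30, t) / CC_acq(LAO30, t)
```

i.e. the fluoroscopy/acquisition spectrum-and-geometry ratio is assumed
projection-independent. The extra-large-patient configuration (LAO30_XL) is
a sensitivity measurement and is excluded from weighting. The weighted CC
per target is the fraction-weighted sum over the 18 cells; missing cells
and weight sums deviating from 1 (tolerance 1e−9) are hard errors.

## 6. Dose projection

Annual dose per target is `CC_w × P_KA,annual / 1000` in mGy, computed at
full precision; reported doses are rounded to the nearest integer mGy
(half away from zero). Years to threshold divide the 0.5 Gy tissue-reaction
threshold (both brain and eye lens) by the **full-precision** annual dose
and floor the result — completed working years without exceedance. Zero
annual dose yields an infinite sentinel ("never"). A "nearest" rounding
mode is available for comparison.

Shielding scenarios are multiplicative transmissions: ceiling-suspended
shield 0.25 (all targets), leaded eyewear 0.70 (eye lenses only, applied on
top of the shield). These are best-case factors for correctly positioned
devices; real-world compliance is lower, so shielded projections are
optimistic.

The default routine workload is 150 CA × 10 + 10 PCI × 25 + 150 CA/PCI × 29
+ 150 TAVI × 33 Gy·cm² = 11 050 Gy·cm²/yr, representative of a high-volume
structural/coronary operator.

## 7. Synthetic data generator

The generator emulates the measurement campaign so the pipeline can be
validated end to end without lab data.

**Scatter field.** The operator-side scatter field is modelled as an
exponential: `CC(r) = CC_ref · exp(−((r − r0) · ĝ) / L)` with `r0` at the
brain-mask centroid of the middle slice, fall-off direction
`ĝ ∝ (−0.67, 0.47, −0.58)` (the field decreases away from the patient, i.e.
toward the operator's right, rear, and top — the operator's left side faces
the scatter source) and fall-off length `L = 60 mm`, chosen so the
left/right region-mean ratio of the default field approaches the factor ~2
asymmetry seen in measured operator head doses. Eye positions receive a
fixed `eye_factor = 4.0` enhancement, reflecting that unshielded surface
points receive several times the mid-brain dose.

**TLD noise.** Each position gets two readings. True dose × unit-mean
lognormal noise (CV 2%) is divided by a per-dosimeter calibration factor
(U(0.95, 1.05)) and energy correction (U(0.97, 1.03)) to produce the raw
reading, so the dosimetry chain must invert both to recover the dose.

**Sessions.** Eleven sessions: the nine standard projections (acquisition),
an extra-large-patient variant and a fluoroscopy variant of LAO30. Session
reference CCs are anchored to the bundled measured CC table so synthetic
outputs land in a realistic range; session P_KA spans 310–500 Gy·cm².

**Event log.** 25 552 events over 249 procedures. Angles are drawn from a
categorical distribution over the nine projection cells plus a 2.5%
out-of-range mass (one axis uniform in (46°, 90°) with random sign);
within-cell angles are uniform within the bin. Per-event P_KA is lognormal
per modality (fluoroscopy mean 0.10, acquisition mean 0.25 Gy·cm²); the
per-event modality probability is solved analytically from the lognormal
means so that the expected fluoroscopy share of in-range P_KA is 64.1%.

**What the generator does not emulate:** beam-quality (kVp/filtration)
dependence of the CC ratio across projections, table/shield geometry,
operator movement, TLD fading or supralinearity, and correlations between
angles and P_KA within a procedure. These are deliberate simplifications —
the generator's job is to produce inputs with the right structure and
magnitudes, not a Monte-Carlo-grade scatter model.

## 8. Numerical and design choices

- Thin-plate-spline RBF with zero smoothing: exact at data points; the
  alternative (smoothed fits) would bias region means at this sparse hole
  density.
- Clipping negative extrapolation to zero rather than masking: region means
  must integrate over the full mask, and small negative lobes outside the
  hull are artefacts, not signal.
- The field's defining direction is stated as a fall-off direction and the
  field is validated to be non-increasing along it — this is the
  unambiguous invariant; a "toward the source" phrasing inverts sign
  depending on convention.
- Years-to-threshold uses floor on the full-precision dose, not the rounded
  integer dose: rounding first would change 64 → 62 years for the whole
  brain and is a reporting artefact, not physics.
- Dataclasses (not an external validation framework) with `__post_init__`
  checks keep the dependency set minimal; all validation errors name the
  offending position, cell, or parameter.
- Determinism: all randomness flows from `numpy.random.default_rng(seed)`;
  the CLI pipeline is byte-identical across runs at a fixed seed (verified
  by test).

## 9. Problem sizes and validation

Full-scale runs use the 512×512 raster, 4 slices (~100 holes), 25 552
events; the complete CLI pipeline runs in ~2 s and the acceptance script in
<2 s. Tests use a 96–128 px raster and 3 000 events for speed. End-to-end
validation simulates readings from a known field, runs the full chain, and
requires hull-restricted region means within 10% of ground truth; binning
conservation, weight normalization, affine-reproduction of the interpolant,
and the headline clinical numbers (8 mGy/yr whole brain, 64/13/8 years to
thresholds, ×2 left/right asymmetry) are asserted exactly or to reporting
precision.

## 10. Limitations

- Conversion coefficients are phantom- and lab-geometry-specific; applying
  them to another catheterization suite assumes similar room layout and
  operator position.
- The fluoroscopy scaling assumes a projection-independent
  fluoroscopy/acquisition ratio, measured at a single projection.
- Region means weight pixels equally (volume-weighted), not
  perfusion- or radiosensitivity-weighted.
- Years-to-threshold assumes a constant workload and no dose-rate effects;
  thresholds themselves carry substantial uncertainty.
- Shielding factors are best-case; no compliance model is included.
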