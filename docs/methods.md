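# Methods

## Measurement model

The package analyzes acquisitions of the saturating-pulse PAM protocol:
a dark-adapted plant is probed with weak measuring light (0.1 µmol
photons m⁻² s⁻¹) to record the minimal fluorescence Fo, a saturating
pulse (> 6000 µmol) closes all PSII centers to give Fm, then actinic
light (200 µmol) drives steady-state photosynthesis, yielding F and —
under a second saturating pulse — Fm′. Excitation is at 460 nm with
fluorescence detected above 650 nm; two narrow-band reflectance frames
(510 nm, 550 nm) are taken at the same bed position. The derived
indicators are Fv/Fm = (Fm − Fo)/Fm, ΦPSII = (Fm′ − F)/Fm′ and the
relative reflectance 550/510. Working ranges used throughout: healthy
Fv/Fm ≈ 0.8 (affected below 0.75), healthy ΦPSII ≈ 0.4 at this actinic
level (stressed near 0.3), healthy 550/510 above 1.5.

## Synthetic scene generator

The generator stands in for the instrument so that every downstream
stage can be tested against exact ground truth.

**Geometry.** A 520 × 696 frame (the sensor resolution) holds
`n_plants` (default 6) on a grid; each plant is a rosette of
`leaves_per_plant` (default 6) overlapping ellipses, alternately
tagged *old*/*new*, so each plant is one connected component. Layouts
whose per-plant cell falls under 16 px are rejected (leaves could not
be placed without plants merging).

**Physiology.** Ground truth is carried per pixel: `phi_max` (the
quantity measured as Fv/Fm), `phi_op` (ΦPSII) and `chroma`, a
greenness driver that scales both the Fm amplitude and the 550/510
target (healthy chroma = 1 ⇒ ratio 1.6). Biological texture is
Gaussian per-pixel (sd 0.02 on the phi fields, 0.03 on chroma) plus
per-leaf offsets (sd 0.015), mean-centered over the footprint so the
healthy working point (0.80 / 0.40 / 1.6) is exact before sensor
noise. Healthy pixel-level Fv/Fm spread is therefore ≈ 0.03, which is
what the diagnosis heterogeneity threshold is calibrated against.

**Stress treatments.** Severity s(day) ∈ [0, 1] is non-decreasing;
spatial expression is fixed per stress type.

- *Drought* (uniform): phi_op is scaled from 0.40 down to a floor of
  0.25 at s = 1 (the wilted plateau); phi_max and chroma are untouched
  until s > 0.7, then fall to 0.72 and ratio 1.36 at s = 1 — the
  "ΦPSII responds first" signature. The default severity course
  saturates at day ≈ 6.5 of a nine-day run so the footprint-mean
  ΦPSII passes ≈ 0.29 on day 5 and sits at 0.25 on days 7–9.
- *Nitrogen deficiency* (old leaves first): all three fields scale
  down (Fv/Fm 0.80 → 0.55, ΦPSII 0.40 → 0.22, ratio 1.6 → 1.28 on old
  leaves at s = 1). New leaves follow the same course lagged by 2 days
  and attenuated by a factor 0.3; the sustained old/new gap is what
  drives the rising Fv/Fm standard deviation (≈ 0.03 → ≈ 0.10 over
  nine days). A pure lag without attenuation would let the gap close
  again late in the course, which contradicts the persistent
  heterogeneity this stress is recognized by.
- *Disease* (patchy lesions): two circular lesions per plant, seeded
  deterministically per plant, grow with severity (radius
  2 px + 3 px/day·s·(n_days − 1)); inside them all three fields drop
  to 30% of healthy. Lesions are deep (Fv/Fm ≈ 0.24) and clumped,
  unlike the moderate, leaf-wide nitrogen response.

**Rendering.** With vignetting v(r) = 1 − 0.15 (r/r_max)²:
Fm = 3000·chroma·v, Fo = Fm(1 − Fv/Fm), Fm′ = Fm(1 − q) with
q = ½(phi_max − phi_op)/phi_max, F = Fm′(1 − ΦPSII); R510 = 100·v,
R550 = R510·1.6·chroma. q is a bookkeeping quencher chosen so the
noiseless stack inverts exactly to the generating fields (non-photochemical
quenching kinetics are out of scope). Fluorescence background is 30
counts; soil reflectance is 60/45 counts (ratio 0.75, well below
leaves). Sensor noise is Gaussian read noise (sd 5 counts) plus
shot noise (variance 0.5 × signal); noisy frames are rounded and
clipped to 12 bits, with a warning if > 0.1% of plant pixels saturate.
A fully noiseless render keeps exact float frames (clip only): integer
quantization and the ≤ 1e-6 round-trip guarantee are mutually
exclusive, so the analytic stack is an in-memory object and
`write_stack` (16-bit TIFF) accepts only integral counts.

**Nutrition preset.** `nutrition_calibration_pairs` emulates leaf
sampling across nitrogen-strength treatments: total N uniform on
15–45 mg per g dry weight, Fv/Fm = 0.60 + 0.005·N + ε. The noise sd
(0.0182) is set analytically so the expected coefficient of
determination of the linear fit is 0.85, matching the reported
strength of this relation; it is a calibrated target, not a derived
quantity.

## Segmentation

*Fluorescence route:* non-plant matter barely fluoresces, so the Fm
frame is thresholded. The threshold is Otsu's value computed on
log1p(Fm) — in log space the background/plant separation dominates, so
dimmed diseased tissue is not split off with the background, which
raw-count Otsu does once lesions sit an order of magnitude below
healthy tissue — floored at the robust background estimate
(median + 5 × MAD-sd). Constant frames yield an empty mask with a
warning.

*Multispectral route:* pixels are clustered into two classes on the
standardized features (R510, R550, R550/R510) with K-means (k = 2, ten
seeded restarts); the cluster with the higher mean 550/510 is labelled
plant, so the labelling is independent of initialization. On frames up
to 256 pixels a separating-hyperplane candidate scan (threshold splits
along the feature axes, principal axes and iterated centroid-difference
directions) supplements Lloyd's iterations, which on tiny inputs with
duplicate pixels and symmetric distances can provably stall short of
the global minimum-SSE partition.

Both routes are followed by small-component removal (4-connectivity,
default minimum area 25 px). Against generator ground truth at default
noise both reach Jaccard overlap ≥ 0.95 (in practice ≈ 1.0).

## Indicator maps and statistics

Ratios are computed on mask pixels whose denominator exceeds 1% of the
frame's robust (99th-percentile) maximum; other pixels are undefined
(NaN) rather than unstable. Noise-induced negative values are clamped
to 0 (and counted) instead of discarded so maps stay aligned with the
mask; fluorescence indicators are kept in [0, 1). Summaries use the
population standard deviation — the pixel set is the full plant
region, not a sample — and linear-interpolation quartiles. Pseudo-color
maps use fixed display ranges (0–0.85 for the fluorescence indicators,
0–2.0 for the ratio) so day-series panels are comparable, with
undefined pixels black and an embedded color bar.

## Stress classification

Per-day flags: ΦPSII ≤ 0.30 (the boundary itself counts as stressed),
Fv/Fm < 0.75, 550/510 < 1.5. Trajectory features: least-squares slope
of each day series ("declining" below −0.01/day; "rapid" ΦPSII decline
below −0.05/day), rising Fv/Fm std exceeding 0.08 (healthy sits near
0.03), and a patchiness score — the mean, over plant pixels below an
impairment threshold, of the fraction of their in-plant 4-neighbours
also below it. Under spatially independent impairment at density p the
score is ≈ p; clumped lesions push it toward 1. The impairment
threshold defaults to Fv/Fm = 0.5: lesions (≈ 0.24) fall below it,
nitrogen-deficient old leaves (≥ 0.55) do not, so leaf-wide nitrogen
damage — itself spatially contiguous — does not masquerade as lesions.

Rule table, evaluated in order: **disease** if the decline is rapid or
patchiness exceeds 0.4 (ties against the nitrogen pattern resolve to
disease, since acting before spread matters most); **nitrogen
deficiency** if all three indicators decline gradually with rising
heterogeneity and low patchiness; **drought (severe)** if ΦPSII has
declined into its flag with Fv/Fm and 550/510 also flagged and no
heterogeneity rise; **drought (early)** if ΦPSII alone declines into
its flag while the other two stay normal throughout; **healthy** if no
flags ever arise; otherwise **indeterminate**. A classification needs
at least three days. If the full series is indeterminate (e.g. recovery
days trailing a severe episode), the most recent determinate prefix
label is reported ("latest consistent label"). The confidence is the
fraction of the six evidence flags matching the label's expected
pattern. Temperature and other confounders are not modelled; a
free-text exclusion note can be attached to the report.

## Calibrations

The ΦPSII/water-potential relation is operationalized as monotone
piecewise-linear interpolation through its three quoted working points
— no functional form is assumed beyond them — and clamps (with a
warning) outside −2.5…−0.5 MPa; the inverse is exact to 1e-9 on the
valid range. The Fv/Fm/total-N relation is an ordinary least-squares
line with R² reported, plus prediction and inversion. The Nessler
computation fits OD480 against the nitrogen mass of each standard
(0–10 mL of 10 mg/L ammonium sulfate; N fraction 2·14.007/132.14),
inverts the line for the sample aliquot, and scales by
digest volume / aliquot volume / dry mass (defaults 50 mL / 1 mL /
0.1 g), reporting mg N per g dry weight. Sample ODs above the top
standard are an error (dilute and re-read), not an extrapolation.

## What the synthetic data does and does not show

The generator reproduces the *signatures* the method relies on —
indicator working points, the temporal ordering of drought responses,
old-leaf-led nitrogen heterogeneity, lesion patchiness, sensor noise
and vignetting — with clean elliptical leaves, no leaf overlap between
plants, no growth or movement between days, no specular soil
reflections, no ambient-light leakage, and no leaf curling (the
morphology cue real gray mold adds). Passing tests therefore validate
the algebra, the segmentation behaviour under the modelled noise, and
the separability of the encoded stress patterns; they do not establish
classifier accuracy on real greenhouse imagery, where confounders
(temperature, mixed stresses, occlusion) are expected to widen the
indeterminate class.

## Problem sizes and determinism

Default runs use full-resolution 696 × 520 frames, 6 plants and
nine-day series; the test suite exercises the classifier on 40 such
labelled series (10 seeds × 4 classes) and scaled-down scenes
elsewhere. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); per-day render noise uses seeds spawned
from the dataset seed, so every output — arrays, TIFFs, CSV/JSON — is
bit-reproducible for a given configuration and seed.
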