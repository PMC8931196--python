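# Methods

This note records the models, parameter choices and known limits of the
synthetic trachea-PAT pipeline. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Digital trachea phantom

A cross-section is two concentric disks: an air lumen of radius r (no
chromophores, no signal) inside a soft-tissue wall annulus of thickness T,
plus circular intramural vessel inclusions. Per cohort group, the lumen area
πr² is drawn from Normal(CSA_mean, CSA_sd²) and T from Normal(TWT_mean,
TWT_sd²), both truncated at > 0 (100 retries, then a degenerate-spec error).
The built-in group parameters are, in mm / mm²:

| group | TWT (mean ± sd) | CSA (mean ± sd) | contrast mechanism |
|---|---|---|---|
| A | 0.82 ± 0.02 | 16.28 ± 0.33 | — (healthy control) |
| B | 1.14 ± 0.04 | 12.37 ± 0.30 | water × 1.5 (edema) |
| C | 1.50 ± 0.30 | 8.78 ± 0.92 | 12 vessels (granulation) |
| D | 1.17 ± 0.11 | 12.47 ± 0.27 | collagen × 2 (scar) |

Wall composition (relative concentration, volume-fraction-like units): water
0.65, collagen 0.20, HbO₂ 0.08 before group boosts. Vessels are 0.15 mm
partial-volume blood disks (30% blood volume, SO₂ 0.75 → HbO₂ 0.225, HbR
0.075) placed uniformly inside the annulus with 0.02 mm clearance from both
boundaries; a vessel shrinks to 0.35·T in very thin walls. Every pixel
carries at most three nonzero chromophores (wall: HbO₂+collagen+water;
vessel: HbO₂+HbR), which is what keeps three-wavelength unmixing locally
identifiable (see below). The stenosis-rate ground truth uses the healthy
mean lumen area 16.28 mm² as the fixed reference:
SR = (1 − CSA/16.28)·100.

Respiration scales the lumen radius by √(1 + a(1 − cos φ)/2) with modulation
depth a = 0.15 by default, so CSA is minimal at φ = 0 (end-exhalation) and
maximal, CSA·(1+a), at φ = π; wall cross-sectional area is conserved exactly
and vessels track the wall radially.

What the phantom deliberately omits: cartilage C-rings, mucus, eccentric or
non-circular lumens, 3-D airway geometry, acoustic heterogeneity of the air
column. Passing recovery tests therefore demonstrates the fidelity of the
measurement chain on idealized near-circular cross-sections, not performance
on anatomically realistic airways.

## Optics

μₐ(λ) = Σᵢ εᵢ(λ)·cᵢ with the bundled extinction table (cm⁻¹ per unit
relative concentration) at 760/840/910 nm. Hemoglobin entries are whole-blood
absorption at 150 g/L computed from the standard tabulated molar extinction
coefficients; water is the pure-water spectrum; collagen follows published
dry-collagen NIR measurements (shoulder at 760 nm, minimum near 840 nm, rise
toward the ~910 nm feature). The table is read verbatim — no interpolation
between listed wavelengths. Initial pressure is p₀ = Γ·μₐ·Φ with Γ = 1 and
uniform Φ = 1 by default (an exponential-decay Φ is available for robustness
experiments); all downstream concentrations are therefore Γ·Φ-scaled relative
values, as clinical MSOT reports.

## Forward acoustics

2-D slice model for the concave arc: 128 point-like elements spanning 180° at
50 mm radius (angles inclusive of both endpoints, arc centered on +y), 5 MHz
center frequency, 50 MHz sampling, homogeneous c = 1500 m/s. The ideal trace
is the time-of-flight binning of p₀·A/(2πd) (A = pixel area, cylindrical
spreading), convolved with the derivative of a Gaussian-windowed sinusoid
whose spectral FWHM is `fractional_bandwidth` × 5 MHz (default 0.7). Noise is
white Gaussian per simulated frame, with 10 frames averaged by default; the
default per-frame noise level is 5% of the peak noiseless amplitude across
wavelengths (one absolute level shared by all wavelengths), i.e. ~1.6%
effective after averaging — a deliberately conservative SNR for an averaged
in-vivo acquisition. Element directivity, multiplexing, frequency-dependent
attenuation and 3-D spreading are not modeled.

## Reconstruction

Universal back-projection: q(t) = g(t) − t·g′(t) (central differences),
linearly interpolated at t = |x − rₖ|/c and summed with per-pixel solid-angle
weights wₖ(x) ∝ cos αₖ/dₖ² · Δs, normalized so Σwₖ = 1 exactly at the array
focus. The fixed normalization matters: renormalizing per pixel would hide
the amplitude deficit of pixels whose detection aperture is partially
missing. Default grid: 256×256 at 0.05 mm (12.8 mm field) centered on the
focus. Reconstructed point targets at the focus measure ≈ 129/107 μm FWHM
(x/y) at 0.9 fractional bandwidth on a 0.025 mm grid.

Two limited-view facts discovered while validating and worth recording:

* An isotropic *point* source on the open (−y) side does **not** reconstruct
  with measurably lower peak amplitude than its mirror — the ramp filter's
  t-weighting cancels the 1/(2πd) spreading in 2-D, and measured mirror
  ratios oscillate within ±5% of unity at all offsets. Points are always
  "visible".
* The faithful limited-view signature is the fading of *extended boundaries*
  whose normals never intersect the aperture: the lateral rim of a disk
  offset 25 mm to the open side reconstructs ≈ 21% weaker than the mirrored
  disk's rim. The test suite asserts this form.

Band-limited reconstructions are bipolar; `envelope` gives |·| (or the
analytic-signal magnitude along an axis), and `isotropic_envelope` gives the
monogenic (Riesz) magnitude, which demodulates the radial oscillation without
the rectification fringes of a plain absolute value. Segmentation and
unmixing operate on monogenic envelopes.

## Spectral unmixing

Per-pixel NNLS on y = E·c, y the envelope amplitudes. With three wavelengths
and four chromophores the system has a one-dimensional null space, so a
3-active pixel always admits a second nonnegative zero-residual vertex:
exact recovery is a property of the *composition*, not of sparsity alone.
With the bundled spectra, every composition class the phantom rasterizes
(HbO₂/HbR vessels; HbO₂+collagen+water walls, including the boosted
variants) is uniquely decodable and recovered to 1e-8; water *without*
collagen is spectrally ambiguous at these three wavelengths and is only
guaranteed an exact fit, not the original attribution. SO₂ is masked where
HbT falls below 5% of its 99th percentile.

Group contrasts (collagen scar-vs-edema, water edema-vs-scar) are evaluated
on a boundary-ridge band (±0.10 mm around the wall boundaries, vessels padded
by 0.35 mm): a band-limited system leaves homogeneous interiors signal-free,
so interior pixels contain only ringing with distorted spectra, while ridge
amplitude is proportional to the local absorption step and carries the wall's
true spectrum. On cohorts of default phantoms this yields collagen D/B ≈ 1.9
and water B/D ≈ 1.3.

## Morphometry

Segmentation: monogenic envelope → Gaussian smoothing (observer σ, default
0.10 mm) → Otsu threshold × observer factor → morphological closing (0.60 mm
radius, bridging the mid-wall envelope dip) → largest component = wall,
largest enclosed hole = lumen. Sixty-four radial spokes from the lumen
centroid then localize the boundaries:

* the wall run along each spoke is the merged set of threshold runs (≥
  0.15 mm thick, ≥ 35% of the robust ridge scale) within 3.2 mm of the first;
* the ridge amplitude scale is the 30th percentile of per-spoke run maxima,
  so bright vessels on a minority of spokes cannot inflate it;
* boundaries are the first/last envelope-ridge peaks (height ≥ 0.30, and
  prominence ≥ 0.08, of the ridge scale), with sidelobe skipping (a ≥2×
  higher ridge within 0.25 mm supersedes its flanking candidate) and
  parabolic sub-sample refinement — ridge peaks are unbiased boundary
  estimators for band-limited edges, unlike half-maximum crossings, which
  sit half a ridge-width outside;
* flat-top (non-band-limited) profiles fall back to half-maximum edges;
* the center is re-fit by a least-squares circle through the inner boundary
  points and the spokes recast (≤ 3 iterations), since a distorted threshold
  mask can put the hole centroid far off the lumen center;
* a circumferential consensus removes spokes > max(0.25 mm, 4 robust σ) from
  the median ring, and the accepted rings must be circumferentially
  consistent to within 0.15 mm robust spread (the resolution scale) — a
  segmentation that cannot meet this fails rather than returning distorted
  numbers, the synthetic analogue of excluding an unanalyzable animal.
  In practice roughly one group-C phantom in twenty fails (thick-wall,
  small-lumen draws whose lateral boundary ridges fall below threshold).

TWT is the 10%-trimmed circumferential mean of (outer − inner) spoke
distances; CSA is the pixel area of the refined inner polygon; SR uses an
explicit reference area. Observers are emulated by jittering the threshold
factor (±3%) and smoothing σ (±10%). The segmenter assumes ≈ 0.05 mm grid
spacing (≥ 3 pixels per resolution element); coarser grids alias the
envelope ridges.

Accuracy at default settings, measured over 20-phantom cohorts: cohort-mean
TWT within ≈ 0.01 mm (A/B/D) to ≈ 0.03 mm (C) of the generator truth, and
cohort-mean CSA within ≈ 2%.

## Statistics

Bland–Altman: bias = mean(x−y), the "95% CI" is the t-interval of the mean
difference (bias ± t₀.₉₇₅,ₙ₋₁·sd/√n), and the classical limits of agreement
(bias ± 1.96·sd) are reported separately since conventions differ.
Between-group comparisons use Welch's unpaired two-sample t — the groups are
distinct animals, so a paired test is not applicable — with significance
stars at 0.05/0.01/0.001/0.0001 and no multiple-testing correction. A paired
t on zero-variance differences returns p = 1 when the mean difference is
zero and a degenerate flag otherwise.

## Reproducibility

All randomness derives from a master seed through the counter scheme
`SeedSequence([master_seed, stage, group_index, item_index])` with stage ids
0 = phantom draw, 1 = acquisition noise, 2 = observer jitter, so every stage
is independently re-runnable. The experiment manifest stores a SHA-256 of
the canonical config and per-file *content* checksums (array data plus
metadata, rather than raw container bytes, which can differ between writes).

## Problem sizes

The validation suite uses 20 phantoms per group for cohort recovery, 8
respiratory phases, 3 phantom pairs for spectral contrasts, and a 0.025 mm
grid for the point-spread measurement; module tests use reduced element
counts (48–64) and fields of view where full angular sampling is not the
property under test.
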