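# tracheapat

Synthetic photoacoustic tomography (PAT) and multispectral optoacoustic
tomography (MSOT) of tracheal stenosis: digital trachea phantoms, band-limited
acoustic simulation on a concave 128-element arc, universal back-projection
reconstruction, three-wavelength chromophore unmixing, automated airway
morphometry, and observer-agreement / group-comparison statistics.

## The problem

Benign tracheal stenosis progresses through characteristic stages — mucosal
edema, granulomatous hyperplasia, cicatricial scarring — that change both the
airway geometry (wall thickness, lumen area) and the wall's optical
composition (water, blood, collagen). PAT/MSOT can image a tracheal
cross-section non-invasively in real time and, acquired at several laser
wavelengths, decompose the absorption into chromophore maps. Evaluating such
a pipeline needs ground truth that in-vivo experiments cannot provide, so
this package replaces the animal with a parametric digital phantom whose wall
thickness (TWT), lumen cross-sectional area (CSA) and stenosis rate (SR) are
known exactly, and asks whether the full simulate → reconstruct → segment →
measure chain returns the cohort statistics it was fed.

Four cohort archetypes are built in: **A** healthy control, **B** edema
(water × 1.5, thickened wall), **C** granulation (extra vessels, thickest
wall, smallest lumen), **D** scar (collagen × 2).

## The model

* **Source generation.** Per pixel, μₐ(λ) = Σᵢ εᵢ(λ)·cᵢ over the chromophores
  HbO₂, HbR, collagen and water (bundled extinction table at 760/840/910 nm),
  and the initial pressure is p₀ = Γ·μₐ·Φ with uniform fluence Φ by default.
* **Acoustics.** 2-D forward model for a 180°, 50 mm-radius, 128-element arc:
  each pixel contributes an impulse at its time of flight with 1/(2πd)
  cylindrical spreading, convolved with a derivative-of-Gaussian 5 MHz
  band-pass response (50 MHz sampling); per-frame white noise, 10× frame
  averaging.
* **Reconstruction.** Universal back-projection
  b(x) = Σₖ wₖ·[g(t) − t·g′(t)] at t = |x − rₖ|/c, with per-pixel solid-angle
  weights wₖ ∝ cos αₖ/dₖ normalized at the array focus. Point-target FWHM at
  0.9 fractional bandwidth is ≈ 107 μm.
* **Unmixing.** Per-pixel non-negative least squares c = argmin‖E·c − y‖²,
  c ≥ 0, on isotropic-envelope stacks; SO₂ = HbO₂/(HbO₂+HbR) masked at low
  HbT.
* **Morphometry.** Otsu segmentation of the envelope locates the wall annulus
  and enclosed lumen; 64 radial spokes localize the inner/outer boundaries at
  their envelope-ridge peaks with sub-pixel refinement and a circumferential
  consensus; TWT is the trimmed circumferential mean of spoke thicknesses,
  CSA the refined inner-polygon area, SR = (1 − CSA/CSA_ref)·100.
* **Statistics.** Pearson r, Bland–Altman bias with 95% CI of the mean
  difference and 1.96·SD limits of agreement, paired t-tests, and per-group
  mean ± SD tables with Welch comparisons and star annotations.

## Worked example

```python
from tracheapat import DEFAULT_GROUP_SPECS, make_phantom
from tracheapat.experiment import simulate_phantom_images
from tracheapat.morphometry import structural_image, measure_image
from tracheapat.config import ExperimentConfig

phantom = make_phantom(DEFAULT_GROUP_SPECS["A"], seed=7)
print(f"truth:    TWT {phantom.wall_thickness:.3f} mm, CSA {phantom.true_csa:.2f} mm^2")

images = simulate_phantom_images(phantom, ExperimentConfig(), noise_seed=7)
result = measure_image(structural_image(images), reference_csa=16.28)
print(f"measured: TWT {result.twt_mm:.3f} mm, CSA {result.csa_mm2:.2f} mm^2, SR {result.sr_pct:.1f}%")
```

prints

```
truth:    TWT 0.826 mm, CSA 16.28 mm^2
measured: TWT 0.820 mm, CSA 16.39 mm^2, SR -0.7%
```

i.e. this control phantom's wall thickness is recovered to 6 μm and its lumen
area to 0.7% after the full acoustic round trip; the slightly negative
stenosis rate says its lumen is marginally wider than the 16.28 mm² healthy
reference.

The command line mirrors the pipeline stage by stage
(`tracheapat phantom | simulate | reconstruct | unmix | measure | stats`),
and `tracheapat all --seed 7 --out run/` executes everything and writes a
manifest with per-file content checksums, so identical seeds give identical
manifests.

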