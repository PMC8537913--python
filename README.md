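# flimsep

Fluorescence-lifetime separation toolkit for live-cell imaging with
red/near-infrared dyes: TCSPC photon-counting simulation, fast-FLIM and
exponential decay fitting, phasor-plot analysis with fine lifetime
separation, τ-STED image enhancement, and microscope quality-control
metrology.

## The problem

Multiplexing several red/near-infrared dyes in a living cell often fails by
spectral overlap: two dyes excited by the same laser line and detected by the
same detector cannot be told apart by color. They *can* be told apart by
fluorescence lifetime τ — the mean nanosecond-scale delay between excitation
pulse and photon emission, an intrinsic property of each fluorophore and its
microenvironment. This package implements the lifetime-based separation
strategies used on modern confocal/FLIM/STED systems, exercisable end-to-end
on a built-in simulator so every stage can be validated against a known
ground truth without an instrument:

- **Coarse τ separation** — assigning each pixel's photons to an
  arrival-time band during acquisition (detector-style gating).
- **Decay fitting** — Poisson maximum-likelihood fits of the per-pixel or
  pooled TCSPC histogram with an IRF-convolved, period-wrapped
  mono/bi/tri-exponential model, reporting reduced Pearson χ².
- **Phasor analysis** — each pixel's decay maps to first-harmonic Fourier
  coordinates g = Σc·cos(ωt)/Σc, s = Σc·sin(ωt)/Σc. Mono-exponential decays
  lie on the universal circle (g−½)² + s² = ¼ with
  g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²); mixtures are photon-weighted means of
  their components. Circular ROIs on the calibrated phasor plot separate
  dyes whose lifetimes differ by only a few hundred ps.
- **τ-STED** — the STED depletion donut shortens lifetimes radially outward
  from each scanned position, so STED photons populate a line segment (the
  STED trajectory) in phasor space. Weighting each pixel by its position u
  along that trajectory (w = u^(strength/50)) suppresses poorly localized
  peripheral photons, removes off-trajectory background, and sharpens the
  image beyond raw STED resolution.
- **Metrology** — bead-based FWHM resolution (2.3548·σ of a fitted 2-D
  Gaussian), illumination-field uniformity (100·min/max after median
  smoothing), irradiance P/(πr²) with r = 0.61λ/NA, and laser-power
  stability statistics.

## Worked example

Two spectrally inseparable dyes — a cytoskeletal stain (τ = 1.845 ns) and a
mitochondrial stain (τ = 1.244 ns) — imaged in a single detection channel,
then separated by phasor ROIs and quantified by per-class pooled fits:

```python
import numpy as np
import flimsep as fs

optics = fs.OpticsConfig()          # 12.5 ns period, 256 bins, 120 ps IRF
specs = [
    fs.StructureSpec("actin", "filament", [(1.845, 1.0)], n=6),
    fs.StructureSpec("mito", "granule", [(1.244, 1.0)], n=25, radius=3.0),
]
phantom = fs.make_cell_phantom(128, specs, seed=7)
image = fs.simulate_confocal_tcspc(phantom, optics, photon_budget=300, seed=8)

# calibrate the phasor plot against a homogeneous 3.55 ns reference
reference = fs.simulate_confocal_tcspc(
    fs.Phantom(np.ones((48, 48), np.int32), {1: ((3.55, 1.0),)}, {1: 1.0}, {1: "ref"}),
    optics, photon_budget=200, seed=901,
)
field = fs.phasor_transform(image, harmonic=1, spatial_median=3)
field = fs.calibrate_phasor(field, reference, reference_tau=3.55)

rois = [
    fs.PhasorROI("actin", target_tau=1.845, tolerance=0.3),
    fs.PhasorROI("mito", target_tau=1.244, tolerance=0.3),
]
channels, assignment = fs.separate_by_roi(field, image.intensity(), rois)

irf = fs.make_irf(optics)
for idx, roi in enumerate(rois):
    fit = fs.fit_exponential(image, irf, mask=assignment == idx)
    acc = (assignment[phantom.label_map == idx + 1] == idx).mean()
    print(f"{roi.label}: tau = {fit.components[0][0]:.3f} ns "
          f"(chi2_red = {fit.chi2_reduced:.2f}, "
          f"{fit.n_photons_used} photons, assignment accuracy {100*acc:.1f}%)")
```

Output:

```
actin: tau = 1.836 ns (chi2_red = 1.02, 281955 photons, assignment accuracy 97.7%)
mito: tau = 1.273 ns (chi2_red = 1.09, 247388 photons, assignment accuracy 100.0%)
```

Both lifetimes are recovered within ~2% of the simulated ground truth, with
χ²_red ≈ 1 confirming the Poisson noise model, and ≥ 97% of pixels assigned
to the correct structure — the two dyes are cleanly separated although they
share one detection channel.

A command-line interface mirrors the library
(`flimsep simulate | fit | phasor | separate | coarse | tausted | metrology
| select`); `flimsep select` encodes the decision tree that picks a strategy
from the number of dyes, their spectral overlap, lifetime gap and STED
compatibility.

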