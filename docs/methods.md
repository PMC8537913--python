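# Methods

This note documents the models behind `flimsep`: what the simulator
generates, how each analysis is computed, the defaults that matter, the
numerical conventions, and what validation on synthetic data does and does
not establish about real acquisitions.

## TCSPC forward model

A pulsed laser with repetition period T (default 12.5 ns, an 80 MHz-class
supercontinuum source; the period is not a measured quantity here but a
typical value compatible with the longest simulated lifetime of 3.85 ns)
excites fluorophores whose emission delay is exponential with lifetime τ.
Detection timing jitter is modeled as a Gaussian instrument response
function (IRF, default FWHM 120 ps, peak at 1 ns into the period). Because
excitation is periodic, decays longer than a few ns wrap into the next
period; the wrapped density on [0, T) is exp(−t/τ)/(1 − e^(−T/τ)).

The per-bin photon probability is the circular convolution of the
bin-center-sampled IRF with the bin-center-sampled wrapped exponential
mixture (256 bins by default, bin centers at (k+½)·Δt). Per-pixel photon
totals are Poisson with mean = photon budget × PSF-blurred brightness map
(confocal PSF FWHM ≈ 0.51·λ_em/NA), and arrival bins are multinomial with
the pixel's mixture density. Fits use the same analytical forward model;
tests validate the sampled histograms against an independent direct-sum
convolution oracle, so the simulator and the fitter are checked against a
third computation rather than against each other.

The wrapped model matters: at T = 12.5 ns and τ = 3.85 ns about 4% of the
photons arrive in the following period; a truncated (non-wrapped) model
would bias pooled fits by roughly that order.

### STED acquisition model

The depletion donut is the scalar approximation D(r) = sin²(πr/d) capped at
its first maximum (D = 1 for r ≥ d/2), d = λ_dep/(2·NA), with an optional
residual center intensity. An emitter at radial offset r from the scanned
position decays at the enhanced rate 1/τ_eff = (1 + S·p·D(r))/τ, where p is
the depletion power fraction and S the saturation factor (default 30,
chosen so that 20% depletion power shrinks a 299 nm confocal spot to ~120 nm
at 775 nm depletion through NA 1.2 — the regime of a well-aligned
commercial system). The fluorescence yield is reduced by the survival
probability τ_eff/τ, which both sharpens the effective PSF and imprints the
radial lifetime gradient that τ-STED exploits. Offsets are grouped into
1-pixel radial annuli of the PSF kernel; each annulus is simulated with its
own effective decay (the discretization error is a fraction of a pixel in
r). Zero depletion power delegates to the confocal path, making the
confocal limit exact by construction.

Detector dead time is not simulated: at the photon budgets used
(100–10 000 photons/pixel spread over many excitation cycles) pile-up is
negligible. Spectral crosstalk, aberrations and 3-D effects are out of
scope.

## Phantoms

`make_cell_phantom` rasterizes blobs (nucleus-like, low-order Fourier
boundary perturbations), filaments (random-walk curves, ~3 px wide),
granules (disks) and rings (membrane outlines) onto a labeled grid; later
structures overwrite earlier ones where they overlap (`overlap="layer"`,
the documented precedence; `overlap="error"` refuses instead). Each label
carries decay components as (τ, photon-fraction) pairs and a relative
brightness multiplying the simulation photon budget. `make_bead_phantom`
places sub-diffraction disks at rejection-sampled centers with a pairwise
minimum separation, recording the sub-pixel centers for resolution oracles;
STED bead scenes default to 20 nm pixels.

## Lifetime estimation

**Fast FLIM** is the per-pixel first moment of the histogram minus the IRF
centroid — cheap, unbiased only for mono-exponential pixels, and the
initializer for fitting.

**Fitting** maximizes the Poisson (multinomial) likelihood of the
IRF-convolved wrapped model over log-lifetimes and logit fractions
(L-BFGS-B; bounded scalar minimization for the mono case). Initial values
come from the fast-FLIM moment (mono) or {0.5×, 2×} the moment (bi).
Goodness of fit is reduced Pearson χ² with model-based variance; bins with
expectation < 1 are merged tail-first. On true-model Poisson data at ≥ 10⁵
photons the reported χ²_red calibrates to [0.8, 1.2]. Per-pixel fits below
`min_photons` (default 25) are flagged absent rather than reported as
zero.

**Coarse separation** assigns each pixel's photons wholly to the half-open
arrival-time band [t_low, t_high) containing its mean arrival time,
mimicking during-acquisition detector gating in which per-pixel decay
curves are not retained; photons outside every band are discarded and
counted, which is also how flat dark counts (late mean arrival) are
suppressed.

## Phasor analysis

The transform uses bin centers (midpoint convention); the resulting
half-bin phase is absorbed by calibration. Calibration multiplies every
pixel by the complex factor mapping the pooled phasor of a homogeneous
single-lifetime reference onto the model point of its known lifetime. The
model point is the closed form of the midpoint-DFT of a bin-sampled wrapped
exponential, rescaled by cos(ω·Δt/2): the midpoint-DFT phasor of this
family satisfies Re(1/z) = cos(ω·Δt/2) exactly for every τ, so after
rescaling the whole mono-exponential family lies on the universal circle to
machine precision at any bin count, and the residual phase-lifetime bias of
the convention is below 0.05% at the lifetimes used here. A continuous-model
calibration target would instead leave an O(10⁻⁵) off-circle residual at
256 bins.

ROI separation classifies whole pixels by circle membership in priority
order; a `target_tau` ROI is centered on the model point of that lifetime
with a radius spanning τ ± tolerance along the circle. The default 3×3
median filter on (g, s) (never on photon counts) is what makes 100–300
photon pixels separable for sub-ns lifetime gaps; empty pixels are filled
with the pooled centroid before filtering so they do not drag neighbors
toward the origin. Unassigned pixels are discarded by default (background
suppression); the `nearest` policy conserves intensity exactly.
Two-component unmixing projects each pixel orthogonally onto the chord
between the component phasors; photon-fraction linearity of the phasor
makes this exact on noiseless input.

## τ-STED enhancement

Pipeline: time gate → phasor transform (+ 3×3 median) → calibration →
trajectory estimation → τ-strength weighting with background subtraction →
wavelet denoising.

The trajectory is a weighted principal axis fit to the phasor cloud of the
*bright* pixels (Otsu threshold on intensity): in sparse scenes uniform
dark counts can outweigh STED-correlated photons and would drag the axis
toward the background phasor. Endpoints are the 0.25/99.75 photon-weighted
percentiles of on-trajectory projections, ordered so the donut-center
endpoint has the longer phase lifetime. A pixel is classified as background
(uncorrelated with the STED process) when its perpendicular residual — or
its projection beyond the bright-cloud span — exceeds 3× the combined
robust cloud scale and its own shot-noise allowance ≈ 0.7/√(N_eff), with
N_eff counting the photons pooled by the median filter. The allowance term
is what keeps dim but legitimate halo pixels (pure shot noise) from being
discarded. Trajectory estimation and background classification run on the
full (ungated) decay: gating a flat background concentrates it into a
boxcar whose phasor masquerades as a long lifetime on the trajectory's
extension, whereas ungated it stays near the origin, 0.4–0.5 phasor units
off the trajectory, and is cleanly removed. The gate itself shapes the
intensity image being weighted.

The weighting law w(u) = u^(strength/50) (u = 0 at the periphery endpoint,
1 at the center) is this package's definition of the vendor-style 0–200
"strength" knob: 50/100/200 give square-root/linear/quadratic suppression
and 0 is exactly neutral (at strength 0 the pipeline returns the gated
intensity bit-exactly, skipping background subtraction too). The output is
rescaled to preserve the input maximum so before/after images are
comparable. All claims about this operator are orderings and invariants —
resolution improves, retained signal decreases monotonically in strength,
excessive strength (150–200) degrades bead-peak uniformity — never pixel
values of any external implementation, which is proprietary.

Denoising is sym4 wavelet shrinkage, 3 levels, soft thresholding at
(denoise/100) × σ·√(2 ln N) with σ the MAD estimate from the finest
diagonal band; denoise 0 is the identity and output is clipped at 0.

## Metrology

FWHM: 2-D elliptical Gaussian + offset least-squares fit in a window around
each peak (detected or supplied); FWHM = 2.3548·σ·pixel per axis, averaged;
fits with R² < 0.9 are excluded. The Gaussian fit (rather than half-maximum
interpolation) is what keeps the estimator unbiased to < 1% at 10–20 nm
pixels with sub-pixel bead centers. Uniformity: 100 × min/max after 3×3
median smoothing, one decimal. Irradiance: P/(πr²) with the Airy-radius
spot convention r = 0.61λ/NA — a declared convention; vendor QC software
uses an unspecified spot area, so irradiance is validated by its exact
linearity in power and its NA²/λ² scaling, never by matching printed
instrument readings. Power stability: mean, SD, min, max and
deviation % = 100·(max−min)/(2·mean).

## Study conditions used by the tests and the acceptance script

Homogeneous reference scenes: 128×128 pixels at 100 photons/pixel (the
standard FLIM-calibration budget). Cell phantoms: 128×128 at 300
photons/pixel over the structures (the regime reached with line
repetition). Bi-exponential recovery: ~10⁶ pooled photons, equal photon
fractions (the component fractions of the real stain are not published; an
equal split is the neutral choice). Bead fields: ten 40-nm beads, ≥ 900 nm
apart, 20 nm pixels, 10⁴ photons/pixel budget, depletion power fraction 0.2
(0.1 for trajectory-endpoint checks, where less center-pixel mixing makes
the undepleted endpoint interpretable). These sizes keep the full suite
under a minute while leaving every estimate's sampling error well inside
the tested tolerances.

## What passing these tests shows — and does not

The simulator emulates Poisson photon statistics, IRF convolution, decay
wrapping, diffraction blur, the STED lifetime gradient and flat dark
counts. It does not emulate detector dead time and afterpulsing, spectral
crosstalk, autofluorescence with its own lifetime distribution,
photobleaching during acquisition, refractive-index aberrations, or
scan-position jitter. Recovery within 2% on synthetic scenes therefore
demonstrates correctness of the estimators under their stated model, not
instrument-grade accuracy on real cells; on a real system the calibration
reference, IRF stability and background model dominate the error budget.

## Degenerate inputs and tie-breaks

Zero-photon pixels are NaN in every per-pixel product, never zero. Band
edges are half-open [lo, hi). Overlapping phantom structures follow list
order (later wins) unless overlap is declared an error. ROIs are
priority-ordered, first match wins. A pointlike phasor cloud (principal
extent < 0.05, as for a confocal acquisition) makes trajectory estimation
raise with advice to use the confocal pipeline rather than produce a
meaningless axis. The calibration rejects references with pooled modulation
≈ 0 (a flat histogram carries no phase information).
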