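# Methods

This note documents the models, numerical choices and limitations behind
`climargin`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Physics model

**Beta spectra.** Emission spectra use the allowed-transition shape
N(T) ∝ F(Z,T)·p·E_tot·(Q−T)² with the non-relativistic Coulomb factor
F = 2πη/(1−e^(−2πη)), η = ∓Zα/β (daughter-nucleus Z; repulsive sign for
positrons). This is adequate for yield *ratios* between isotopes; it is
not a nuclear-data-grade spectrum (no screening, no shape factors for
forbidden transitions). Spectra are tabulated on a uniform keV grid and
normalised to unit area by trapezoidal quadrature; the unit tests verify
the coarse-grid mean energy against a 10× finer grid.

**Cerenkov yield.** The Frank–Tamm photon number per unit path in a band
[λ₁, λ₂] is dN/dx = 2πα(1/λ₁−1/λ₂)(1−1/(β²n²)) for βn > 1, with a
non-dispersive refractive index (default n = 1.33, water; tissue is not
far from this and no value is established for prostate). Photons per
particle are the continuous-slowing-down integral
∫_{T_thr}^{T₀} (dN/dx)/S(T) dT using a 20-node table of the total
electron stopping power of water (10 keV–3 MeV, ESTAR-like values)
interpolated log-log — a smooth, positive interpolant; energies outside
the table are clamped to its ends, which only matters below 10 keV where
the particle is far below threshold anyway. Yield per *decay* multiplies
by the β branching fraction and averages over Monte-Carlo energies drawn
from the spectrum by inverse-CDF interpolation. The ⁶⁸Ga/¹⁸F ratio in
water over 400–800 nm computed this way lands near 30; the published
in-vitro comparison (≈22×) folds in an unreported detector spectral
response, so only order-of-magnitude agreement (the acceptance band
10–40) is claimed.

**Decay and tissue optics.** Decay is 2^(−t/T½) with T½(⁶⁸Ga) = 68 min —
the clinical-literature convention rather than the nuclear-data
67.71 min, because the study arithmetic being reproduced uses 68; the
registry value is user-editable. Tissue transmission is a single-
exponential e^(−μ_eff·d) per band with defaults μ_eff = 10 cm⁻¹ below
550 nm and 2 cm⁻¹ for 550–800 nm. These are order-of-magnitude
soft-tissue values and are explicitly configuration, not ground truth;
tests assert only the ordering (short wavelengths attenuate faster),
which is what the persistence rule relies on.

## Specimen phantom

Each of the six views (left/right, anterior/posterior, basal/apical) is
an independent 2-D field: a uniform benign surface radiance plus one
Gaussian lesion profile per configured lesion. A lesion of lateral sigma
σ_l, depth d and uptake ratio R contributes a Gaussian of sigma
√(σ_l² + σ_p²) whose peak is benign·(R−1)·σ_l²/(σ_l²+σ_p²)·e^(−μ_eff d):
convolving a Gaussian lesion with the positron-range blur keeps it
Gaussian while lowering the peak. The blur sigma is σ_p = r̄/√(π/2) so
that the mean radial displacement of the 2-D Gaussian equals the
isotope's tabulated mean positron range (2.8 mm for ⁶⁸Ga → σ_p ≈
2.23 mm). Benign tissue is treated as a surface source (no attenuation);
each band's signal scales with its share of the 1/λ² Cerenkov spectrum,
so the shortpass filter reduces the benign level to ≈ 55 % and a lesion's
to that times its depth attenuation.

The camera chain per frame is: Poisson photon counts per unbinned pixel
(expected value = radiance × exposure × system calibration), gain, dark
offset, Gaussian read noise, Poisson-counted gamma strikes at uniform
positions with exponential amplitudes truncated above 5× read noise,
defective pixels forced to full scale, rounding and clipping to the bit
depth, then binning by block summation and a final clip. Decay is applied
at frame start (not mid-exposure); for 150 s against a 68 min half-life
the approximation is < 2 %. Timestamps advance frame by frame by the
exposure time. One master seed drives a study; per-frame seeds are
`SeedSequence(entropy=master, spawn_key=(…, frame_index))`, making every
frame independently reproducible.

Default camera: 512×512 unbinned pixels at 117 µm pitch (so 2×2 binning
gives 234 µm, matching the protocol's stated binned pitch), read noise
5 counts, dark offset 100, strike rate 0.05 s⁻¹, strike amplitude mean
2000 counts, one defective pixel, 16-bit depth, calibration
10⁻⁵ counts·(p/s/cm²/sr)⁻¹·s⁻¹ per pixel. The real device's sensor size,
pitch and calibration are unpublished; these values are declared
plausible, not reproduced. Benign surface radiance defaults to
1500 p/s/cm²/sr at the 100 MBq reference activity, the order of the
activity-corrected radiances reported clinically, and the default
injection-to-imaging delay is 73 min (the cohort mean).

**What the phantom does not model:** 3-D specimen geometry (views are
independent flat fields), realistic prostate shape and curvature,
heterogeneous benign uptake, ambient-light leakage, optical scattering
point-spread, and camera nonlinearity. Passing tests therefore show that
the *pipeline* recovers what the stated noise and attenuation model
implies — not that the clinical device would.

## Processing chain

Gamma strikes are suppressed by a 3×3 median followed by a σ = 3 px
Gaussian. The order is a deliberate choice: impulses must be deleted
before linear smoothing spreads them; the alternative order is available
as an option. Both filters use reflecting boundaries to avoid dark rims
at frame edges. Background subtraction requires the empty-tray frame to
share exposure, binning and filter with the specimen frame — violating
that is a hard error, matching the acquisition procedure. Negative
differences are clamped to zero (radiance is physical); a signed
diagnostic mode exists. Counts become radiance via counts/(calibration ×
exposure) with calibration defaulting to 1 (arbitrary units): every
downstream decision is TBR-based and calibration-invariant. Non-divisible
binning crops trailing rows/columns. Rasters are row-major, origin
top-left, 0-based, pixel centres at half-integers.

## Quantification and margin call

ROI means are arithmetic means over boolean masks. Decay correction
references measurements to the injection time — the one timestamp
recorded for every patient. Activity normalisation rescales to a 100 MBq
reference (the nominal injection), keeping physical radiance units.
Cohort dispersion uses the population convention (divisor n), which is
the convention that reproduces the reported mean ± sd values the tests
assert; the sample convention is a flag away.

Hotspot detection thresholds at background mean + k·sd (default k = 3,
minimum area 4 binned pixels, 4-connectivity) with background statistics
from iterated 3σ clipping of the map. This is an explicit algorithmic
surrogate for the visual hotspot marking done clinically. Hotspot TBRs
are measured over the component's *core* — pixels at or above half the
peak excess over background — emulating the compact ROI a clinician
draws, rather than the full suprathreshold skirt whose faint tail would
dilute the ratio. A hotspot is *persistent* when its TBR on the
shortpass-filtered map (same core pixels) reaches τ = 2.0; the default
sits below the filtered TBRs observed for histopathology-confirmed
lesions (≥ 2.5) and above what a ≥ 3 mm-deep lesion can produce under
the attenuation defaults. A view is PSM-suspected iff it has a
persistent hotspot; the specimen verdict is the OR over views. Without a
filtered image the verdict falls back to the unfiltered TBR and is
flagged low-confidence — the ambiguity between visual and quantitative
persistence is exposed as a parameter, not silently decided. Evaluation
against ground truth counts views with tumour within 0.1 mm of the
surface ("CLOSE") separately: calling them PSM is clinically defensible
and is not tallied as a plain false positive.

## Benchmark study designs

**Persistence cohort** (`benchmarks.persistence_benchmark`): 20 studies,
one lesion per depth {0, 0.05, 3, 6} mm on distinct views (two views
lesion-free), uptake ratio 6:1, lateral sigma 6 mm, injected activities
drawn around 83 ± 19 MBq, imaged at 150 s / 8×8 with and without the
filter. The cohort camera uses a 10⁻⁴ calibration (10× baseline): the
protocol selected clinically produced clearly visible hotspots, and at
this signal level the 5 % filtered-contrast difference between a surface
lesion and one 0.05 mm deep is resolved above measurement noise, so the
depth ordering of the filtered/unfiltered contrast ratio is a stable
property. Contrast ratios are pooled (ratio of cohort-mean contrasts)
for the same reason.

**Protocol optimisation** (`benchmarks.protocol_tbr_benchmark`): the
noise-dominated phantom — 1024×1024 sensor, calibration 5.5×10⁻⁷, one
broad (σ = 10 mm) surface lesion per view — is imaged at exposures
30/60/150/300 s (8×8) and binnings 2/4/8 (150 s). The calibration places
the benign signal per binned pixel between ≈ 0.13× and ≈ 1.3× the
post-smoothing read-noise floor across that grid (the smoothing chain
attenuates white noise by a measured factor ≈ 0.10), i.e. the regime in
which acquisition settings visibly trade off against noise. The measured
TBR rises with collected signal because clamping negatives after
background subtraction biases the benign-ROI mean upward when noise
dominates; the bias shrinks as signal grows. Each setting is rendered as
its own session from the same post-injection time so settings are
compared at matched activity (inside one long session, later frames
would have decayed by up to two half-lives and confound the comparison),
and backgrounds are rendered per view so the six view-TBRs averaged per
replicate are independent. Problem sizes — 50 replicates, 20 cohort
studies, 2×10⁵ Monte-Carlo particles — were chosen so the complete
validation runs in a few minutes on one core while leaving the binomial
and Monte-Carlo margins comfortable.

## Known limitations

* Depth cannot be estimated, only the near-surface/deep dichotomy via
  the persistence rule; the 0.05 mm "CLOSE" cases are indistinguishable
  from true surface involvement, as the near-margin false positives of
  the clinical series illustrate.
* The attenuation coefficients, camera constants and benign radiance are
  plausible configuration values, so absolute radiances from the phantom
  are not calibrated predictions; only ratios and orderings are.
* The hotspot detector is a surrogate for expert visual assessment and
  its k·σ threshold has no clinical validation.
* Dosimetry divides published per-procedure doses by an annual limit;
  it does not model dose rate, distance or shielding. The 1 mSv default
  is the public limit, which is also the unique round limit consistent
  with both published extrapolations (62 and 200 procedures).
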