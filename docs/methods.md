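# Methods

This note documents the models implemented in `leafvcmax`, their
assumptions, the numerical choices, and what the synthetic-data fixtures
do and do not emulate.

## Leaf radiative transfer

Reflectance ρ and transmittance τ (400–2500 nm, 1 nm grid, both
endpoints included) follow the generalized plate model: the leaf is a
pile of *N* identical absorbing plates (N real-valued, 1–4), where the
top interface of the first plate sees a near-collimated 40° incidence
cone and all other interfaces see isotropic diffuse flux. Interface
transmissivities are unpolarized Fresnel transmittances averaged over the
incidence cone (Gauss–Legendre quadrature over angle, vectorized over
wavelength; the classic diffuse relations t21 = tav(90°, n)/n² and
r21 = 1 − t21 apply for the internal side). Diffuse flux transmission of
one plate interior is θ(k) = (1−k)e⁻ᵏ + k²E₁(k); the N-plate pile is
combined with the Stokes expressions, with two guarded limits: the
lossless case (r + t → 1), where the exact conservative N-plate limit is
used, and the opaque case (t → 0), where the sub-pile reflects like a
single interface.

Elementary-layer absorption is the linear mixture
k(λ) = [ΣᵢCᵢ·SACᵢ(λ) + Cx·SACx(λ)]/N. The xanthophyll de-epoxidation
parameter Cx scales a differential absorption band strictly confined to
500–570 nm, so Cx perturbs ρ and τ only there (asserted to 1e−12 in the
tests); the Cx term perturbs ρ and τ symmetrically, since it enters the
absorption budget like any other constituent.

### Fluorescence

Chlorophyll fluorescence (640–850 nm) is computed by a sublayer source
scheme. The leaf interior between its two air–leaf interfaces carries the
total absorber column (N·k elementary layers). Because the plate-model
mesophyll does not scatter volumetrically, the adding/doubling operator
products over thin sublayers collapse to closed-form geometric series of
bounces between the two interfaces; the implementation sums those series
analytically and discretizes only the source positions into 2^k
sublayers (`doubling_levels`, default k = 6, i.e. 64 sublayers — a
further doubling changes the emission by < 0.02%, comfortably inside the
0.1% convergence target). Within the slab, diffuse propagation uses the
two-stream diffusivity factor 2 (attenuation e^(−2K) for absorber column
K), consistent with the small-k limit of θ.

Per sublayer, the quanta absorbed by chlorophyll (fraction
Cab·SACab/k of total absorption) from the internally bouncing
excitation field (400–750 nm) are re-emitted isotropically with bulk
quantum efficiency η and spectral shape φ (unit integral), then
transported to both faces with reabsorption at the emission wavelengths
and the same interface bounce series. This construction makes the
emission exactly linear in η and guarantees the photon budget: quanta
leaving both faces never exceed η × quanta absorbed by chlorophyll
(verified against an independent dense integration in the tests).
Internal plate interfaces are ignored for the fluorescence transport
only; ρ and τ always use the full Stokes system. Forward/backward
asymmetry arises from the depth profile of absorption.

The incident spectrum argument makes the radiometric convention
explicit: the lamp spectrum defines the spectral shape, and each
protocol step rescales it so that its 400–700 nm quanta integral equals
the step's iPAR. Simulated ChlF therefore carries the same per-nm flux
units as the incident spectrum.

## Photosynthesis

Standard Farquhar kinetics at 25 °C (Γ* = 42.75 µmol mol⁻¹,
Kc = 404.9 µmol mol⁻¹, Ko = 278.4 mmol mol⁻¹, O = 210 mmol mol⁻¹,
configurable); no temperature-response functions are applied because the
emulated chamber protocol runs at a constant 25 °C. Electron transport
follows the Collatz form without Jmax: Je = 0.5·φpo·a·iPAR with leaf
absorptance a = 0.84 and dark-adapted photochemical yield
φpo = Kp/(Kp+Kf+Kd). The rate coefficients default to Kf = 0.05,
Kd = 0.95, Kp = 4, chosen so Kf + Kd = 1, which makes the NPQ rate
coefficient Kn numerically equal to PAM NPQ = (Fm−Fm′)/Fm′; all three
are configurable and the NPQ identity is kept exact for any values by
computing NPQ = Kn/(Kf+Kd).

The Rubisco- and light-limited rates are combined by a smoothed minimum
(quadratic with curvature θ = 0.98; θ → 1 recovers the hard minimum).
The smoothing keeps the inversion cost surfaces differentiable. The
A–gs–Ci loop (Ball–Berry gs = g0 + m·A·RH/Cs floored at the residual
conductance g0 = 0.01 mol m⁻² s⁻¹) is solved by damped fixed-point
iteration (damping 0.5, tolerance 1e−4 ppm on the undamped Ci update,
200 iterations). Near the CO₂ compensation point the conductance floor
makes the Ci map expansive and the damped iteration can cycle (this
occurs at the 50 ppm step of the CO₂ protocol); the fixed point is then
bracketed and resolved by Brent root finding on update(Ci) − Ci. The
solution is independent of the starting Ci to the solver tolerance.

Degenerate forcings are defined rather than rejected: at iPAR = 0 the
light-saturation measure x is 0 (dark-adapted; this makes Kn = 0 and
Fs = Fo exactly, hence ε = Fs/Fo = 1), and at Ci ≤ Γ* x is clamped to 1
with Ag ≤ 0 reported.

## Coupling

Cx = slope·NPQ (slope 0.3187, a previously calibrated coefficient,
configurable) and η = ς·ε (ς default 0.007, the dark-adapted
fluorescence quantum efficiency; ε = 1 in the dark by the identity
above, so the dark-adapted η equals ς). The relation uses
NPQ = (Fm−Fm′)/Fm′ rather than Kn so it stays well-defined under
non-default rate coefficients. Outputs are clipped to the valid
radiative-transfer ranges (Cx ≤ 1.5, η ≤ 0.2) with a logged warning, so
optimizer excursions cannot abort a fit. Static optical properties are
held fixed along a response curve; only Cx and η vary.

## Retrievals

All fits use the trust-region reflective bounded least-squares solver
(ftol 1e−8, xtol 1e−10, max 400 evaluations, deterministic given
inputs), with bounds and initial values: Vcmax ∈ [0,250] init 70;
Kn0 ∈ [2,6] init 2.48; β, γ ∈ [0,100] init 0.114/2.83 (method 2 only);
ς ∈ [0,0.2] init 0.007 (method 3 only). Each result records initials,
bounds, the cost trace, bound-hit and identifiability flags, and
parameter standard deviations from the solution Jacobian.

Method 2 normalizes measured Fs by the dark-adapted Fo (PAM information
lives in ratios) and concatenates the Fs/Fo and NPQ blocks with unit
weights.

Method 3 residuals use every 1 nm sample inside the fitting windows
(730–750 nm ChlF, 525–545 nm green ρ/τ, both inclusive) rather than band
means, preserving spectral shape information. In backward/both modes
both measured and simulated ρ are normalized by subtracting their value
at 565 nm, where the xanthophyll band has no effect, suppressing
specular offsets. Because fluorescence and transmittance enter a single
cost function with unstated relative weights, each block is divided by
the mean magnitude of its measured values so both contribute comparably;
the normalization constants are recorded on the problem object. β and γ
stay at their standard values in method 3. Each curve (light or CO₂) is
fitted separately; pooling is possible by concatenating datasets. The
static optics fit (7 parameters over the full 400–2500 nm range of
whichever reference spectra exist) runs once per leaf beforehand with
the valid ranges as bounds and standard values as initials.

## Diagnostics

Jacobians are central finite differences with step 1e−3 × span per
parameter (validated against a 10× finer secant in the tests, < 0.5%
elementwise); a parameter sitting on a bound triggers a one-sided
difference with a warning. Columns are normalized by multiplying with
the parameter span (UB − LB) to make sensitivities comparable. Noise
propagation is cov = (JᵀJ)⁻¹σr² with σp the square roots of the
diagonal; σr is a user-supplied scalar measurement SD (per residual
unit). Rank-deficient JᵀJ falls back to the pseudo-inverse and reports
the dominant parameter of each singular direction instead of raising.
R² is reported as the squared Pearson correlation (so anti-correlated
pairs also score 1); RRMSE = RMSE / mean(observed).

The Monte-Carlo validation of the error propagation uses additive
Gaussian noise of fixed SD on the fitted band values — the homoscedastic
noise model the covariance formula assumes — at 1% of the normalized
band magnitude, which keeps the problem inside the linearization regime.

## Synthetic data

The generator emulates the chamber protocol: a 10-step light curve (0,
50, 100, 150, 250, 350, 500, 700, 1000, 1300 µmol m⁻² s⁻¹ at 400 ppm)
and a 12-step CO₂ curve (400, 50, 100, 150, 250, 350, 500, 700, 900,
1200, 700, 400 ppm at 1000 µmol m⁻² s⁻¹), both at 25 °C and RH 0.6.
True Vcmax is drawn from U(50, 100) µmol m⁻² s⁻¹, the span the retrieval
is designed for; static optics are drawn from realistic ranges
(Cab 30–60 µg cm⁻², N 1.2–2, etc.). Default noise is multiplicative
Gaussian: 1% on spectra, 2% on assimilation and on PAM yields. A seed
fixes the whole dataset bit-for-bit.

The SAC fixture is a deterministic set of Gaussian absorption bands at
physically plausible positions (chlorophyll 430/680 nm, carotenoids
450–500 nm, anthocyanins ~540 nm, water 970/1200/1450/1940 nm, dry
matter SWIR features, a broad brown-pigment tail, xanthophyll band at
525 ± 12 nm hard-limited to 500–570 nm) with a double-Gaussian emission
shape peaking near 685 and 740 nm. The xanthophyll band amplitude (0.1)
is chosen so the NPQ-driven green-transmittance change along a light
curve is of order 10% relative — the order of magnitude seen in leaf
measurements. The lamp is a smooth 3200 K halogen-like curve in quanta
units; a 700 nm short-pass variant emulates the chamber filter for
preprocessing tests. Real coefficient tables can be supplied through the
SAC file loader.

Because the synthetic measurements come from the same forward model that
the retrievals invert, passing self-inversion and ensemble tests
demonstrates identifiability, numerical correctness and noise behaviour
of the inversion — not the representational adequacy of the model for
real leaves. Real-data effects deliberately not emulated: chamber
scattering and stray light, specular (non-Lambertian) reflection beyond
the ρ(565) offset, instrument dark current, small-leaf chamber
contamination, and any model-representation error.

## Preprocessing

Transmittance (or reflectance) is leaf radiance over white-reference
radiance, clipped to [0,1]. ChlF is the filtered leaf radiance minus the
leakage term (ρ or τ) × filtered incident radiance on 640–850 nm,
floored at zero; the leakage correction can be switched off. The
reference panel is treated as ideal (reflectance 1). PRI uses the
531/570 nm bands; ΔPRI and ΔF740 subtract the reference step (lowest
nonzero illumination for light curves, highest CO₂ step for CO₂ curves).
ΔPRI is invariant to a common rescaling of a curve's spectra (ratio
index); ΔF740 is not (absolute difference). ETR uses the PAM convention
ΦPSII·PAR·0.84·0.5 (absorptance 0.84, PSII fraction 0.5). LUE = A/iPAR
is undefined at the dark step, which is excluded.

## Known limitations

- The fluorescence transport ignores internal plate interfaces; at high
  N the forward/backward partition is approximate.
- The red ChlF peak (< 700 nm) overlaps the chamber filter cutoff in the
  emulated setup and is not used by the retrievals.
- The light-curve fluorescence RMSE profile, while having its global
  minimum exactly at the generating Vcmax, can carry a shallow secondary
  stationary point at high Vcmax: steady-state fluorescence is
  non-monotone in light saturation, so a single high-light step maps two
  Vcmax values to the same ChlF; the whole-curve fit resolves this, but
  a fixed-slice profile retains the imprint.
- C4 photosynthesis, temperature responses, mesophyll conductance and
  hysteretic or nonlinear Cx–NPQ relations are out of scope.
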