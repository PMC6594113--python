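# leafvcmax

Retrieval of leaf photosynthetic capacity from optical measurements, by
coupling a leaf radiative-transfer model to a Farquhar–Collatz
photosynthesis model.

## The problem

The maximum carboxylation capacity *V*<sub>cmax</sub> (µmol CO₂ m⁻² s⁻¹)
is the key parameter of Farquhar-type photosynthesis models: it sets the
light-saturated assimilation rate of a leaf. It is classically estimated
from gas-exchange response curves, which are slow and contact-based. Two
optical signals respond dynamically to photosynthesis and can be measured
remotely: chlorophyll fluorescence (ChlF, 640–850 nm, double-peaked near
685 and 740 nm) and the xanthophyll-cycle-driven darkening of green
reflectance/transmittance (the signal behind the photochemical
reflectance index, PRI). `leafvcmax` implements a fully coupled forward
model of both signals and three inversion routes for *V*<sub>cmax</sub>,
for plant ecophysiologists and remote-sensing scientists working at the
leaf level.

## The model

**Radiative transfer.** The leaf is a generalized plate model (Stokes
system of *N* absorbing plates): absorption of an elementary layer is

    k(λ) = [ Σᵢ Cᵢ·SACᵢ(λ) + Cx·SACx(λ) ] / N

over the constituents (chlorophyll C<sub>ab</sub>, carotenoids, anthocyanins,
water, dry matter, brown pigments) with their specific absorption
coefficients (SACs). The differential xanthophyll term, confined to
500–570 nm and scaled by the dynamic parameter *C*<sub>x</sub>, darkens the
green band. Fluorescence is emitted with bulk quantum efficiency *η* and
spectral shape *φ* (unit integral over 640–850 nm), transported to both
leaf faces by a sublayer scheme with the internal interface reflections
summed in closed form.

**Photosynthesis.** Net assimilation is the smoothed minimum of the
Rubisco-limited and electron-transport-limited rates (Collatz form, no
*J*<sub>max</sub>), closed with Ball–Berry stomatal conductance and a Ci
fixed point. The light-saturation measure *x* = 1 − *Ja*/*Je* drives the
empirical NPQ rate coefficient

    Kn = Kn0 · (1+β) · xᵞ / (β + xᵞ)

and the PAM fluorescence yields Fo, Fm, Fm′, Fs follow from the rate
coefficients (Kf, Kd, Kp, Kn), with NPQ = Kn/(Kf+Kd) and
ΦPSII = (Fm′−Fs)/Fm′.

**Coupling.** Two linear bridges connect the models per protocol step:
*C*<sub>x</sub> = 0.3187 · NPQ and *η* = ς · ε with ε = Fs/Fo and
ς = 0.007 (the dark-adapted fluorescence quantum efficiency).

**Inversions** (bounded trust-region least squares, Vcmax ∈ [0, 250],
initial 70):

1. **Gas exchange** — fit *V*<sub>cmax</sub> to the measured assimilation
   curve.
2. **PAM** — fit (*V*<sub>cmax</sub>, Kn0, β, γ) to Fs/Fo and NPQ curves.
3. **Spectra** — fit (*V*<sub>cmax</sub>, Kn0, ς) of the coupled model to
   the far-red ChlF band (730–750 nm) and green τ or ρ band (525–545 nm)
   of a whole response curve at once, after retrieving the static leaf
   optics once per leaf from a reference spectrum; reflectance is
   normalized by subtracting ρ(565 nm).

Diagnostics include span-normalized Jacobians, noise propagation to
parameter standard deviations via (JᵀJ)⁻¹σr², RMSE-vs-Vcmax profiles and
goodness-of-fit statistics.

## Worked example

Generate a synthetic light-response curve for a random leaf (true
*V*<sub>cmax</sub> drawn from U(50, 100), default measurement noise), then
retrieve *V*<sub>cmax</sub> from its spectra alone (method 3) and from gas
exchange (method 1):

```sh
$ leafvcmax synth --kind light --seed 42 --out demo
wrote light dataset (true Vcmax=98.78) to demo

$ leafvcmax retrieve demo --method 3 --mode forward
static optics: cab=53.33, ccar=9.384, cant=0.007281, cw=0.01788, cdm=0.01639, n_layers=1.276, cs=4.048e-23
method 3 (light curve):
  vcmax = 98.39 +/- 0.255
  kn0 = 2.469 +/- 0.00667
  sigma_scale = 0.006977 +/- 1.13e-05
  cost 0.04833 (initial 2.207), 24 evaluations

$ leafvcmax retrieve demo --method 1
method 1 (light curve):
  vcmax = 98.07 +/- 0.608
  cost 0.4863 (initial 128.9), 12 evaluations
```

The static leaf optics (pigments, water, dry matter, structure) are
first inverted from the dark-adapted reference spectra; the spectral
inversion then recovers the generating *V*<sub>cmax</sub> of 98.8 to within
0.4 µmol m⁻² s⁻¹ from the fluorescence and green-transmittance bands,
in agreement with the classical gas-exchange estimate. The `+/-` values
are the noise-propagated parameter standard deviations; `cost` is the sum
of squared band residuals before and after optimization.

Other entry points: `leafvcmax simulate` (coupled forward run along a
light or CO₂ protocol), `leafvcmax diagnose` (Jacobian norms, parameter
uncertainties and the RMSE-vs-Vcmax profile of each measurement block).

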