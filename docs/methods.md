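# Methods

## The assay

`vesiquant` determines the weight concentration of unilamellar lipid
vesicles (liposomes) from static light-scattering intensities measured on
the two samples that an extrusion preparation naturally produces: the main
extrudate (volume V₁, concentration C₁) and the rinse extrudate that
recovers the lipid left in the device (total remaining volume V_T − V₁,
concentration C₂).

In the dilute regime the excess scattered intensity of a vesicle
dispersion is I = k·M_w·C·P(q): instrument/contrast constant k,
weight-averaged molar mass M_w, weight concentration C, and form factor
P(q). Because both samples come from the same vesicle population (the DLS
module exists to verify this), k, M_w and P(q) are identical for the two
and cancel in the dilution-corrected intensity ratio

    γ = (I₁ d₁) / (I₂ d₂) = C₁ / C₂ .

Conservation of the weighed-in lipid mass M₀ closes the system,

    M₀ = C₁ V₁ + C₂ (V_T − V₁) ,

with the assumption that the dead volume trapped in the extruder holds the
rinse concentration C₂ (the spare lipid not incorporated in vesicles is
neglected). With α = M₀/V₁ and υ = (V_T − V₁)/V₁ the closed form is

    C₂ = α / (γ + υ) ,   C₁ = α γ / (γ + υ) .

Both the ratio identity C₁/C₂ = γ and the closure identity hold exactly
for every valid input; the test suite asserts them to 1e-12 relative over
randomized records.

Because only the intensity *ratio* enters, any detector that responds
linearly to scattered light works: a goniometer, a plate-reader-style size
analyzer, or a spectrofluorimeter reading the elastic Rayleigh band
(emission = excitation). The `spectra` module integrates that band and
feeds its area into the same solver.

### Uncertainties

Intensity replicates (triplicates in the reference protocol) are averaged
and SE = SD/√n. SEs propagate to (C₁, C₂) by the first-order delta
method with analytic gradients; M₀ and the volumes are treated as exact by
default (they are read off a balance and a syringe scale) but accept their
own SEs. The delta method was validated against 100,000-draw Monte-Carlo
simulations (agreement within 5% at intensity CVs ≤ 5%).

Two independent preparations A and B of the same nominal sample are
combined as their mean; the attributed uncertainty is the larger of the
combined measurement error ε_AB = √(ε_A² + ε_B²)/2 and the preparation
spread σ_AB = √(Δx_A² + Δx_B²), Δx = x − mean. The maximum guards
against propagated errors so small that discrepant preparations would
look inconsistent. `aggregate_values` isolates ε_AB so the alternative
convention √((ε_A²+ε_B²)/2) is a one-line change.

A caveat that matters in practice: when SEs are estimated from n = 3
replicates, the standardized error of C₁ has Student-t (ν ≈ 2–4) rather
than Gaussian tails. Seeded simulation at 2% intensity CV gives ±2 SE
coverage of ≈ 88–89% (not 95%) and ±3 SE coverage of ≈ 95%; the tests
assert these simulation-calibrated rates.

### Detection limit and the shell model

A unilamellar vesicle is modeled as an infinitely thin spherical shell:
M(D) = (2π·M_lip/ΔA_lip)·D² (both leaflets; default lipid POPC,
M_lip = 760.1 Da, head-group area ΔA_lip = 0.63 nm²). At a fixed
intensity threshold, I = k·M_w·C with M_w ∝ D² implies the minimum
detectable concentration scales as 1/D²: anchored at ~0.01 mg/mL for
50 nm vesicles, the floor is 4× lower at 100 nm and 16× lower at 200 nm.
The assay itself never uses M_w or P(q) — they cancel — so the shell
model affects only the detection-limit estimate and the synthetic
generator's realism.

### Standards shortcut

A preparation characterized once (concentration C_std, scattering
reading or Rayleigh ratio R_std at dilution d_std) serves as a standard
for later preparations of the same composition and size:
C = C_std·(d/d_std)·(R/R_std). The package requires the caller to assert
the match and recommends comparing the DLS size distributions.

## DLS characterization

Correlograms g²(t) are analysed two ways.

**Cumulants.** g²(t) = B + β·exp(−2Γ̄t)·(1 + (μ₂/2)t²)², fit over the
full lag range with uniform weights (order 1 pins μ₂ = 0). The baseline
start value is the mean of the last 10% of channels; Γ̄ starts from a
log-linear regression over the first decade of decay; μ₂ starts at 0.
Parameters are bounded (β > 0, Γ̄ > 0, μ₂ ≥ 0); SEs come from the fit
covariance. Data with intercept β < 0.05 are flagged rather than fit.
Γ̄ maps to the mean hydrodynamic diameter through Stokes–Einstein,
D̄ = k_B·T·q²/(3πηΓ̄) with q = (4πn₀/λ)·sin(θ/2); defaults are water at
20 °C (n₀ = 1.333, η = 1.002 mPa·s) and a 532 nm laser at 90°
(q = 22.3 μm⁻¹). The polydispersity index is PI = μ₂/Γ̄².

**Regularized inversion.** √(max(g²−B, 0)/β) ≈ Σᵢ G(Γᵢ)e^(−Γᵢt) is
solved by non-negative least squares on 80 log-spaced decay rates
spanning [0.1/t_max, 10/t_min], with a squared-second-difference
smoothness penalty λ. `reg_lambda="auto"` picks λ on the corner of the
L-curve over a 20-point λ grid; the corner is located by the normalized
maximum-chord-distance (triangle) criterion rather than pointwise
curvature, because the non-negativity constraint flattens the residual
branch of the curve and curvature detectors drift to the over-smoothed
end (where, on a 10×-separated bimodal test instance, the two modes merge
into one). The selected λ is reported. The intensity-weighted harmonic
mean diameter is D̄_harm = [Σᵢ Gᵢ/Dᵢ]⁻¹.

Numerical notes: weights are renormalized to sum 1 (asserted to 1e-9);
an all-zero solution raises; increasing λ never increases the number of
local maxima on the fixed test instances.

## Elastic-peak integration

The band at λ_em = λ_ex is integrated by the trapezoid rule over
λ_ex ± w (default w = 5 nm, configurable; the reference instrument uses
1 nm slits, so the default window comfortably covers the band). The
background is, by default, a straight line fit to the two flanking bands
of width w just outside the window — which also absorbs any constant
offset — or an explicit buffer spectrum. Net negative areas are clipped
to zero with a warning. Absolute areas depend on PMT voltage and slits;
the assay only consumes area ratios, so no correction is applied.

## Stewart assay (validation arm)

Absorbance at 485 nm of the phospholipid–ammonium-ferrothiocyanate
complex is linear in concentration over 0.005–0.050 mg/mL. The
calibration is a weighted (1/SE²) straight line with free intercept
(forced-origin optional), fit via weighted least squares; inverse
prediction is C = d·(A − intercept)/slope with the SE from the absorbance
SE plus the fit covariance. Predictions outside the standards' range are
flagged as extrapolation, not rejected. Matrix-specific curves (e.g.
pure-POPC vs mixed POPC/POPS/cholesterol) are separate curve objects
distinguished by a composition label; no reactivity correction is
applied.

## Synthetic data: what it emulates and what it does not

The generators produce every input with known truth: correlograms from a
decay-rate distribution (or directly from the cumulants model, for
truncation-free recovery tests), two-extrusion intensity records with
I = k·M_w·(C/d)·P(q) under the thin-shell form factor
P(q) = [sin(qD/2)/(qD/2)]², replicate triplets with multiplicative
Gaussian noise, Gaussian elastic bands of prescribed area, and Stewart
standards. All are deterministic under a fixed seed, and generated
extrusion records satisfy mass closure by construction.

Default study conditions: M₀ = 1 mg, V₁ = 0.8 mL, V_T = 1.8 mL,
dilutions 50× / 5×, residual mass fraction 0.1, intensity CV 2% in
triplicate, 90 nm vesicles. Correlogram noise is additive Gaussian
(σ = 1e-3 of the intercept scale in tests); cumulants-model correlograms
use multiplicative noise.

Not emulated: photon-counting (Poisson) statistics, afterpulsing and
correlator channel structure, multiple scattering, dust spikes,
inter-particle structure factors, dn/dC dispersion, and instrument
drift between the two samples. Passing tests therefore demonstrate the
correctness and calibration of the estimators under the stated noise
model, not robustness to every artifact of real instruments.

## Problem sizes

Stochastic checks use 500 seeded extrusion experiments (concentration
recovery and SE calibration), 100 correlograms of 200 channels (cumulants
bias and coverage), 10,000 randomized records (closure identity), and
100,000-draw Monte-Carlo oracles for the delta-method checks — sizes at
which the binomial/MC noise of each check is well below its tolerance.

## Known limitations

* The closure assumes the dead-volume lipid is all in vesicles at
  concentration C₂; heavy fouling of the membrane violates it.
* Equality of the two samples' size distributions is assumed, not
  enforced; verify with the DLS module before trusting γ.
* The inversion grid and penalty are standard but not unique; modal
  positions are resolved only to the grid step (~15% in Γ at the default
  80-point/5-decade grid).
* The thin-shell detection-limit anchor (0.01 mg/mL at 50 nm) is
  setup-specific; only the 1/D² scaling is general.
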