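# Methods

## Two-pool hyperpolarized kinetics

The forward model treats the injected hyperpolarized substrate and its
metabolic product as two longitudinal-magnetization pools with
unidirectional first-order exchange:

    dS/dt = −k·S − S/T₁ₛ − p·S
    dP/dt =  k·S − P/T₁ₚ − p·P,      p = (1 − cos pw)/TR

Assumptions: conversion is irreversible (no product→substrate flux over
the ~2-minute observation window), both pools see the same pulse train,
and RF sampling is well approximated as a continuous loss at rate p. The
pair is linear with closed-form solution S(t) = S₀e^(−at),
P(t) = P₀e^(−bt) + kS₀(e^(−at) − e^(−bt))/(b − a), a = k + 1/T₁ₛ + p,
b = 1/T₁ₚ + p; when |a − b| < 1e-10 s⁻¹ the degenerate limit
kS₀·t·e^(−at) is used (the switch point is far below any distinguishable
rate difference at these SNRs). `evolve_ode` integrates the same system
with LSODA at rtol 1e-10 and is used purely as a cross-check; the two
paths agree to better than 1e-8 peak-relative error across the tested
parameter space.

**Apparent vs true T1.** Fitting uses the apparent convention: p = 0 in
the model and the fitted T1s absorb the pulsing losses. This avoids the
strong pw–T1 interdependence at low SNR. True T1s follow from
1/T₁ = 1/T₁,app − (1 − cos pw)/TR, with an explicit error when the
apparent rate does not exceed the pulsing rate. The conversion uses the
*effective* flip angle, which B1 calibration typically puts below the
nominal console value (20°→~15°, 10°→~8°); `effective_flip_angle`
exposes a user-set calibration factor (default 0.78) and nothing is
calibrated automatically.

**Discrete-pulse oracle.** `simulate_discrete_pulses` evolves the pools
exactly between pulses (true T1s, p = 0), multiplies both by cos pw at
each pulse and records the pre-pulse value times sin pw. Against the
continuous apparent-T1 model, traces normalized as a pair to unit
substrate peak agree within 1% for pw ≤ 20°, TR ≤ 2 s, T1 ≥ 9 s over 120
scans; the residual discrepancy is the accumulation of −ln cos pw vs
(1 − cos pw) per pulse and is inherent to the first-order pulsing
approximation, not to the implementation.

## Estimation

`TwoPoolModel.fit` minimizes the joint weighted sum of squared residuals
of both traces with `scipy.optimize.least_squares` (trust-region
reflective, bounds k ∈ [0, 1e-2] s⁻¹, T1 ∈ [1, 120] s). Free parameters
default to {k, T₁ₛ,app, T₁ₚ,app, S₀} with P₀ fixed at 0 (no product at
injection); the mask is configurable. Initialization: T1 guesses 30/20 s,
k from the initial product slope over the substrate peak, S₀ from the
substrate peak; a 5-point multistart with log-normal jitter (fixed seed)
guards against local minima. Weighting defaults to per-trace
inverse-variance with the noise SD estimated robustly from first
differences — the two traces can sit orders of magnitude apart in
amplitude, and pooled-variance standard errors would otherwise overstate
the rate-constant uncertainty by the amplitude ratio. Standard errors
come from the Jacobian-based covariance at the optimum
(s²(JᵀJ)⁻¹, s² = SSR/dof); they quantify curvature of this objective
only, and no attempt is made to reproduce any externally reported ±
values whose provenance is unstated. Goodness of fit is the per-trace
R² = 1 − SS_res/SS_tot, undefined (explicit error) for a constant
observed trace. Fits are invariant to a common positive rescaling of
both traces.

The day-7 vs day-14 comparison uses a paired two-tailed t-test
(`scipy.stats.ttest_rel`; pairs = donors), with the zero-variance
degenerate case signalled rather than returning an unusable statistic.

## Spectra

Synthetic spectra are sums of Lorentzians on a descending ppm axis;
a doublet contributes two half-amplitude components at center ±
J/(2·f_MHz) ppm. Default ¹³C shifts: 208 ppm ([2-¹³C]pyruvate), 183.5 ppm
([1-¹³C]lactate, doublet J = 55 Hz when formed from uniformly labelled
glucose), 172 ppm (pyruvate hydrate; one source prints 171, the body-text
value is adopted), 162 ppm (bicarbonate), and a 92–98 ppm anomeric window
for glucose, which has no single printed shift. Spectrometer frequency
defaults to 125.77 MHz (¹³C at 11.7 T). Integration windows are half-open
[low, high) so adjacent windows partition cleanly; integration is
trapezoidal with optional linear baseline anchored at the window edges.
Noise is estimated as 1.4826 × MAD in a signal-free window (≥ 16 points,
rejected if it overlaps a peak window). Phasing, apodization and peak
picking are out of scope (vendor-software territory); only fixed windows
are supported.

**Summed-spectra fallback.** When dynamic fitting is impossible, the
first n (default 50) spectra are summed and each window integrated; a
peak is "quantifiable" when (window maximum)/(noise SD) ≥ 3. The
threshold is a package convention — the underlying observation ("could
not be quantified") comes without a printed criterion.

## Exometabolome quantification

Concentrations are referenced to DSS: the 500 µL sample + 100 µL buffer
mixing gives a 0.644×(100/600) = 0.1073 mM in-tube DSS concentration and
a 5/6 sample dilution; c_sample = (I/nH)/(I_DSS/9)·c_DSS,tube/(5/6).
Reported concentrations are in the original-supernatant frame (spent and
fresh medium are compared in that frame). The proton count under each
quantified peak is a configuration table — defaults cover the panel's
metabolites (lactate CH₃ = 3H, formate CH = 1H, …) and are overridable,
since peak selection is an analyst's choice. Consumption over a feed
interval is fresh − spent, with negative values flagged as production;
no cell-number normalization is applied. Replicates aggregate as
mean ± SD (N = 3). Spent samples without a same-day fresh partner are
reported as orphans, never imputed.

## Synthetic data

**Dynamic series.** A scenario is (truth, acquisition, noise). Noise is
additive Gaussian per trace with SD = `noise_sd_frac` × that trace's own
peak (default 1%): each integral window in the real experiment has its
own noise floor, far below the dissolution-enhanced substrate signal, so
per-trace scaling — not substrate-peak scaling — reproduces the observed
regime in which the product trace is fittable at all. Rendered spectra
add an absolute noise floor of `spectrum_noise_sd_frac` (default 1e-4) ×
substrate peak height, matching the ~10⁴ substrate SNR of dDNP.
Named presets pin the truths at the printed operating points (pyruvate
day-5: k = 10.7e-5 s⁻¹, T1app 30/16 s, 8° eff, TR 2 s; glucose day-5:
9.4e-5, 10/18 s, 15°; day 7: 5.278e-5 and day 14: 1.146e-5, both 9/17 s,
15°, TR 1 s). The day-21 pyruvate preset has no printed rate constant;
it uses the day-14 value divided by the reported eightfold day-14→21
flux drop as a clearly-labelled stand-in.

**Expansion panels.** Cells are diluted to 0.5×10⁶/mL every 2 days
(sampling days 3–21); between feeds they grow exponentially at a
phase rate (lag d1–3: 0.010 h⁻¹; ramp d3–10: 0.0289 h⁻¹, ~24 h doubling;
burst d10–12: 0.040 h⁻¹; decline d13–21: −0.005 h⁻¹), and each
metabolite changes by its per-cell rate times the analytic integral of
the growth curve (cell-hours), floored at 0 with a starvation flag.
Per-cell rates are derived from phase-level targets: glucose consumed
fractions (0.85, 0.88, 0.50, 0.13) across the four phases encode the
deep early consumption and the sharp day-10–12 metabolic shift;
amino-acid targets drop from ~0.6 to 0.05 after the shift; lactate
production (12, 15, 6, 0.4 mM per interval) mirrors aerobic glycolysis
switching off; succinate/fumarate release rises late. Fresh-medium
concentrations are formulation-typical (RPMI-1640 + GlutaMAX; glucose
11.1 mM) — no measured values exist for them, and they are fully
configurable. Measurement noise is mean-preserving multiplicative
log-normal with CV 3%; three replicates share the truth and differ only
in noise. The panel is emitted as integrals (inverse of the DSS
quantification at a fixed reference integral), so the quantification
stage runs on realistic units.

What the generator does *not* emulate: donor-to-donor variability beyond
noise, metabolite cross-talk (e.g. lactate inhibition of glycolysis),
intracellular pools, peak overlap or baseline distortions in real ¹H
spectra, and within-interval sampling. A green recovery test therefore
establishes estimator correctness under the stated noise model, not
robustness to spectral artefacts.

An idealized ¹H renderer (`render_h1_spectrum`) places one well-resolved
singlet per metabolite (real multiplets collapsed) with area
proportional to in-tube concentration × proton count plus the DSS
reference; identical linewidths and window half-widths everywhere make
the Lorentzian tail losses cancel in the DSS ratio, closing the
concentration → spectrum → integral → concentration loop to within 2%.

## Numerical conventions

- t = 0 is the first recorded scan; the ~9 s polarizer-to-magnet
  transfer is an optional acquisition offset that rescales S₀, never a
  fitted parameter. The sin pw factor on recorded signals and the
  polarization level are absorbed into S₀ (only relative amplitudes
  carry information).
- Interchange formats are plain text with 17-significant-digit floats;
  write → read round-trips are value-exact.
- Pipeline reports embed the config hash and package version; a failed
  stage leaves a MANIFEST marking the outputs incomplete.

## Known limitations

- The apparent↔true T1 conversion applied to heavily rounded inputs can
  disagree with values corrected from unrounded fits (e.g. an apparent
  9 s at 15°/TR 1 s maps to 13.0 s, not the 14 s obtainable from
  unrounded estimates); the package makes no attempt to reverse-engineer
  rounding.
- Strictly unidirectional two-pool topology; no multi-pool networks or
  backward flux, and no Bayesian posteriors or model selection.
- The effective flip angle must be supplied (or derived via the manual
  calibration factor); it is deliberately not estimated from data.
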