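# hypermet

Real-time metabolic kinetics from hyperpolarized ¹³C NMR, plus ¹H-NMR
exometabolomics of culture media, packaged for monitoring the metabolic
state of expanding immune-cell products (e.g. CAR T cells).

Dissolution dynamic nuclear polarization (dDNP) boosts the ¹³C signal of an
injected substrate — [1-¹³C]pyruvate or [U-¹³C,²H]glucose — by ~10⁴–10⁵,
so its enzymatic conversion to [1-¹³C]lactate can be watched scan-by-scan
for the ~2 minutes the hyperpolarization survives. `hypermet` implements
the two-pool kinetic model for such series, its estimation, and the
companion quantification of spent-medium metabolites against a DSS internal
standard across a 21-day expansion protocol. A synthetic-data module
generates both data streams with known ground truth, so the whole pipeline
is testable without access to raw spectrometer data.

## The model

Substrate signal S and product signal P obey

    dS/dt = −k·S − S/T₁ₛ − p·S
    dP/dt =  k·S − P/T₁ₚ − p·P,      p = (1 − cos pw)/TR

where k is the first-order conversion rate constant (the glycolytic-flux
readout), T₁ₛ, T₁ₚ the longitudinal relaxation times and p the loss rate
from sampling with flip angle pw every repetition time TR. Fits use the
*apparent-T1* convention: p is set to zero and the fitted T1s absorb the
pulsing losses (robust at low SNR, where pw and T1 are interdependent);
true T1s are recovered afterwards via 1/T₁ = 1/T₁,app − (1 − cos pw)/TR.
The pair is linear, so the closed form

    S(t) = S₀·e^(−a·t),   P(t) = k·S₀·(e^(−a·t) − e^(−b·t))/(b − a)

with a = k + 1/T₁ₛ + p, b = 1/T₁ₚ + p is fitted directly
(`TwoPoolModel.fit()` → `TwoPoolResults`, statsmodels-style). A
pulse-by-pulse simulator (`simulate_discrete_pulses`) serves as an
independent oracle for the apparent-T1 approximation.

For series too weak to fit dynamically, the first 50 spectra are summed
and quantified by window integration with an SNR ≥ 3 detectability rule.
Medium metabolites are quantified as
c = (I/nH)/(I_DSS/9) · c_DSS,tube / d, with d = 5/6 the sample dilution of
the 500 µL + 100 µL mixing scheme and c_DSS,tube = 0.644·(100/600) mM.

## Worked example

```python
import hypermet as hm

scenario = hm.get_preset("day7", seed=11)     # printed day-7 operating point
series = hm.generate_dynamic(scenario)        # noisy glucose->lactate traces
results = hm.fit_two_pool(series)
print(results.summary())
t1s, t1p = results.corrected_t1(scenario.acq)
print(f"corrected T1s: substrate {t1s:.1f} s, product {t1p:.1f} s")
print(f"fold change vs day-14 truth: {hm.fold_change(results.params.k_per_s, 1.146e-5):.2f}")
```

prints

```
Two-pool hyperpolarized kinetics fit (apparent-T1 convention)
==============================================================
traces: glucose -> lactate   n = 180 scans
converged: True   residual norm: 15.67

parameter             estimate     std err
------------------------------------------
k_per_s            5.23788e-05   2.948e-07
T1_substrate_s         8.92986     0.06486
T1_product_s           17.1569      0.1263
S0                     1.00655    0.005089
P0                           0       fixed
------------------------------------------
R^2 glucose: 0.9967   R^2 lactate: 0.9989

corrected T1s: substrate 12.8 s, product 41.3 s
fold change vs day-14 truth: 4.57
```

The simulation's true rate constant is 5.278×10⁻⁵ s⁻¹ with apparent T1s of
9 s (glucose) and 17 s (lactate) under a 15° effective flip angle at
TR = 1 s; the fit recovers k to ~0.8% and the T1 correction removes the
RF sampling losses (17 s apparent → ~41 s true for lactate). The ~4.6-fold
ratio against the day-14 rate constant is the kind of expansion-stage
contrast the method is built to detect.

The same objects drive the `hypermet` command line:

```sh
hypermet simulate --preset day7 --seed 1 --out day7.csv
hypermet fit day7.csv --out fit.json
hypermet correct-t1 28 --flip-angle 8 --tr 1
hypermet simulate --preset expansion_default --seed 2 --out panel.csv
hypermet quantify panel.csv --out profiles.csv
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from scratch, (a) the median fitted substrate apparent T1 over
100 simulated experiments at the pyruvate operating point (truth 30 s,
1% per-trace noise, full two-pool re-fit per seed) and (b) the Hz
separation of the maxima of a noiseless [1-¹³C]lactate doublet rendered
with the 55 Hz one-bond ¹³C–¹³C coupling, and writes both to the given
JSON path.

See `docs/methods.md` for model assumptions, parameter defaults, the
synthetic-data design and known limitations.
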