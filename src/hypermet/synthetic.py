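"""Synthetic data with embedded ground truth for every pipeline stage.

Two generators emulate the study's data streams:

* :func:`generate_dynamic` — hyperpolarized two-pool dynamic series (and
  optionally rendered spectrum series) under pulsed sampling with seeded
  Gaussian noise, for rate-constant recovery studies;
* :func:`generate_expansion` — 21-day supernatant panels from exponentially
  growing cells on a dilute-to-0.5e6/mL-every-2-days feed schedule with
  phase-dependent per-cell consumption/production rates, for the
  exometabolome stage.

Noise conventions: dynamic traces get additive Gaussian noise with SD
equal to ``noise_sd_frac`` times each trace's own peak (emulating the
per-window integration of spectra whose hyperpolarized SNR is ~1e5;
an identically-zero trace falls back to the substrate peak so a "no
conversion" scenario still carries a noise floor).  Supernatant
concentrations get multiplicative log-normal noise with a given CV.

Ground truth is embedded in every artifact so downstream tests compare
against it rather than re-derived constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .exometabolome import DEFAULT_PROTON_COUNTS, QuantReference
from .kinetics import (
    AcquisitionParams,
    DynamicSeries,
    KineticParams,
    evolve_closed_form,
    simulate_discrete_pulses,
)
from .spectra import (
    DEFAULT_C13_PEAKS,
    DEFAULT_FREQ_MHZ,
    PeakDefinition,
    SpectrumSeries,
    synthesize_spectrum,
)

__all__ = [
    "DDNPScenario",
    "ExpansionScenario",
    "ExpansionPanel",
    "generate_dynamic",
    "generate_expansion",
    "render_h1_spectrum",
    "preset_library",
    "get_preset",
    "H1_PEAK_PPM",
]


# ---------------------------------------------------------------------------
# hyperpolarized dynamic series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DDNPScenario:
    """A simulated dissolution-DNP experiment with known truth."""

    truth: KineticParams
    acq: AcquisitionParams
    noise_sd_frac: float = 0.01  # per-trace, relative to that trace's peak
    # spectral noise floor relative to the substrate peak height; dissolution
    # DNP boosts the substrate SNR to ~1e4, so the floor sits far below it
    spectrum_noise_sd_frac: float = 1e-4
    render_spectra: bool = False
    peaks: tuple[PeakDefinition, PeakDefinition] | None = None  # (substrate, product)
    use_discrete: bool = False  # pulse-by-pulse oracle instead of closed form
    labels: tuple[str, str] = ("substrate", "product")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")


def generate_dynamic(scenario: DDNPScenario):
    """Simulate a dynamic series (and optionally its spectrum series).

    Returns the noisy :class:`DynamicSeries` with the scenario embedded in
    ``meta['truth']``; with ``render_spectra`` a ``(series, spectra)``
    tuple, where each scan is a rendered spectrum with per-scan amplitudes
    taken from the clean traces plus additive spectral noise.
    """
    times = scenario.acq.scan_times()
    if scenario.use_discrete:
        clean = simulate_discrete_pulses(scenario.truth, scenario.acq)
    else:
        clean = evolve_closed_form(scenario.truth, scenario.acq, times, labels=scenario.labels)

    rng = np.random.default_rng(scenario.seed)
    s_peak = float(np.max(clean.substrate_signal))
    p_peak = float(np.max(clean.product_signal))
    sd_s = scenario.noise_sd_frac * (s_peak if s_peak > 0 else 1.0)
    sd_p = scenario.noise_sd_frac * (p_peak if p_peak > 0 else s_peak)
    noisy = DynamicSeries(
        times,
        clean.substrate_signal + rng.normal(0.0, sd_s, times.size) if sd_s > 0 else clean.substrate_signal.copy(),
        clean.product_signal + rng.normal(0.0, sd_p, times.size) if sd_p > 0 else clean.product_signal.copy(),
        labels=scenario.labels,
    )
    noisy.meta.update(
        truth=scenario.truth,
        acq=scenario.acq,
        noise_sd=(sd_s, sd_p),
        seed=scenario.seed,
    )
    if not scenario.render_spectra:
        return noisy

    sub_peak, prod_peak = scenario.peaks or (
        DEFAULT_C13_PEAKS["glucose_anomeric"],
        DEFAULT_C13_PEAKS["lactate_c1"],
    )
    lo = min(sub_peak.window_ppm[0], prod_peak.window_ppm[0]) - 2.0
    hi = max(sub_peak.window_ppm[1], prod_peak.window_ppm[1]) + 2.0
    axis = np.arange(hi, lo, -0.02)
    spec_noise = scenario.spectrum_noise_sd_frac * (s_peak if s_peak > 0 else 1.0)
    mat = np.empty((times.size, axis.size))
    for i in range(times.size):
        mat[i] = synthesize_spectrum(
            [sub_peak, prod_peak],
            axis,
            DEFAULT_FREQ_MHZ,
            noise_sd=spec_noise,
            seed=rng,
            amplitudes=[clean.substrate_signal[i], clean.product_signal[i]],
        )
    spectra = SpectrumSeries(axis, mat, DEFAULT_FREQ_MHZ, scan_times_s=times)
    spectra.meta.update(truth=scenario.truth, seed=scenario.seed)
    return noisy, spectra


# ---------------------------------------------------------------------------
# 21-day expansion supernatant panels
# ---------------------------------------------------------------------------

#: formulation-typical fresh-medium concentrations, mM (RPMI-1640 with a
#: GlutaMAX supplement; products carry trace baselines so consumed
#: fractions stay defined)
DEFAULT_FRESH_MEDIUM_MM: dict[str, float] = {
    "glucose": 11.1,
    "glutamax": 2.0,
    "glutamine": 0.5,
    "arginine": 1.15,
    "cysteine": 0.4,
    "histidine": 0.097,
    "isoleucine": 0.38,
    "leucine": 0.38,
    "phenylalanine": 0.091,
    "tyrosine": 0.11,
    "valine": 0.17,
    "lactate": 0.05,
    "pyruvate": 0.05,
    "formate": 0.02,
    "succinate": 0.01,
    "fumarate": 0.01,
}

#: expansion phases; an interval belongs to the phase of its end day
PHASES = ("lag", "ramp", "burst", "decline")

#: per-phase exponential growth rates, 1/h (lag d1-3, ramp d3-10,
#: burst d10-12 when proliferation peaks, decline d13-21)
DEFAULT_GROWTH_RATES: dict[str, float] = {
    "lag": 0.010,
    "ramp": 0.0289,  # ~24 h doubling
    "burst": 0.040,
    "decline": -0.005,
}

# consumed fraction of the freshly added amount per 2-day interval,
# per phase; negative = net production expressed as a fraction of fresh
_CONSUMED_FRACTION_TARGETS: dict[str, tuple[float, float, float, float]] = {
    "glucose": (0.85, 0.88, 0.50, 0.13),  # steep drop after the day 10-12 shift
    "glutamax": (0.95, 0.95, 0.90, 0.90),  # cleaved throughout
    "glutamine": (0.60, 0.40, -0.50, -0.80),  # consumed early, released late
    "arginine": (0.50, 0.60, 0.30, 0.05),
    "cysteine": (0.50, 0.60, 0.30, 0.05),
    "histidine": (0.40, 0.55, 0.25, 0.05),
    "isoleucine": (0.50, 0.65, 0.30, 0.05),
    "leucine": (0.50, 0.65, 0.30, 0.05),
    "phenylalanine": (0.40, 0.55, 0.25, 0.05),
    "tyrosine": (0.40, 0.55, 0.25, 0.05),
    "valine": (0.50, 0.65, 0.30, 0.05),
}

# net production in mM per 2-day interval, per phase
_PRODUCED_MM_TARGETS: dict[str, tuple[float, float, float, float]] = {
    "lactate": (12.0, 15.0, 6.0, 0.4),  # aerobic glycolysis early, then off
    "pyruvate": (0.15, 0.25, 0.30, 0.05),
    "formate": (0.10, 0.15, 0.05, 0.15),
    "succinate": (0.02, 0.03, 0.05, 0.30),  # TCA intermediates rise late
    "fumarate": (0.01, 0.02, 0.04, 0.20),
}


def _integrated_cell_hours(density0: float, growth_rate_per_h: float, hours: float) -> float:
    """Analytic integral of exponential growth, in (1e6 cells/mL) x h."""
    if abs(growth_rate_per_h) < 1e-12:
        return density0 * hours
    return density0 * (math.exp(growth_rate_per_h * hours) - 1.0) / growth_rate_per_h


def default_per_cell_rates(
    fresh_medium: Mapping[str, float] | None = None,
    growth_rates: Mapping[str, float] | None = None,
    seed_density: float = 0.5,
    interval_h: float = 48.0,
) -> dict[str, dict[str, float]]:
    """Phase -> metabolite -> rate table (mM per (1e6 cells/mL) per h).

    Positive rates consume, negative produce.  Rates are derived from the
    phase-level consumed-fraction / produced-amount targets above so the
    default scenario reproduces the qualitative expansion story (deep
    glucose consumption through day 10, the day 10-12 metabolic shift,
    late TCA-intermediate release) by construction.
    """
    fresh = dict(DEFAULT_FRESH_MEDIUM_MM if fresh_medium is None else fresh_medium)
    growth = dict(DEFAULT_GROWTH_RATES if growth_rates is None else growth_rates)
    hours = {ph: _integrated_cell_hours(seed_density, growth[ph], interval_h) for ph in PHASES}
    rates: dict[str, dict[str, float]] = {ph: {} for ph in PHASES}
    for met, targets in _CONSUMED_FRACTION_TARGETS.items():
        for ph, frac in zip(PHASES, targets):
            rates[ph][met] = frac * fresh[met] / hours[ph]
    for met, targets in _PRODUCED_MM_TARGETS.items():
        for ph, amount in zip(PHASES, targets):
            rates[ph][met] = -amount / hours[ph]
    return rates


@dataclass(frozen=True)
class ExpansionScenario:
    """Stated world of a 21-day expansion with 2-day feeds.

    Cells are diluted to ``target_density`` (1e6 cells/mL) at every feed;
    sampling days are the feed days 3, 5, ..., 21.  Between feeds cells
    grow exponentially at the phase rate and metabolites change by the
    per-cell rate times the integrated cell-hours of the interval,
    floored at zero (starvation) for consumed species.
    """

    sampling_days: tuple[int, ...] = tuple(range(3, 22, 2))
    target_density: float = 0.5  # 1e6 cells/mL after each dilution
    growth_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GROWTH_RATES))
    per_cell_rates: Mapping[str, Mapping[str, float]] | None = None
    fresh_medium: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRESH_MEDIUM_MM)
    )
    noise_cv: float = 0.03
    n_replicates: int = 3
    dss_integral: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.sampling_days) != sorted(set(self.sampling_days)):
            raise ValueError("sampling_days must be strictly increasing")
        if self.target_density <= 0:
            raise ValueError("target_density must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def rates(self) -> dict[str, dict[str, float]]:
        if self.per_cell_rates is not None:
            return {ph: dict(r) for ph, r in self.per_cell_rates.items()}
        return default_per_cell_rates(self.fresh_medium, self.growth_rates, self.target_density)


def phase_of_interval(end_day: float) -> str:
    """Expansion phase of the feed interval ending on ``end_day``."""
    if end_day <= 3:
        return "lag"
    if end_day <= 10:
        return "ramp"
    if end_day <= 12:
        return "burst"
    return "decline"


@dataclass
class ExpansionPanel:
    """Generated supernatant panel with its embedded ground truth."""

    panel: pd.DataFrame  # day, sample_type, metabolite, replicate, integral, dss_integral, n_protons
    truth: pd.DataFrame  # day, metabolite, fresh_mM, spent_mM, starved
    counts: pd.DataFrame  # day, density_1e6_per_mL (pre-dilution), phase
    scenario: ExpansionScenario = None


def generate_expansion(scenario: ExpansionScenario) -> ExpansionPanel:
    """Simulate the spent/fresh supernatant panel and the count trajectory."""
    rng = np.random.default_rng(scenario.seed)
    rates = scenario.rates()
    fresh = dict(scenario.fresh_medium)
    ref = QuantReference()
    sigma = math.sqrt(math.log(1.0 + scenario.noise_cv**2))

    def noisy(x: float) -> float:
        if scenario.noise_cv == 0 or x == 0:
            return x
        # mean-preserving multiplicative log-normal noise
        return x * math.exp(rng.normal(0.0, sigma) - 0.5 * sigma * sigma)

    def integral_of(conc_mM: float, met: str) -> float:
        n_h = DEFAULT_PROTON_COUNTS[met]
        tube = conc_mM * ref.sample_dilution
        return tube / ref.dss_tube_conc_mM * (n_h / ref.dss_protons) * scenario.dss_integral

    truth_rows, panel_rows, count_rows = [], [], []
    prev_day = scenario.sampling_days[0] - 2
    for day in scenario.sampling_days:
        phase = phase_of_interval(day)
        hours = (day - prev_day) * 24.0
        g = scenario.growth_rates[phase]
        cell_hours = _integrated_cell_hours(scenario.target_density, g, hours)
        density_end = scenario.target_density * math.exp(g * hours)
        count_rows.append({"day": day, "density_1e6_per_mL": density_end, "phase": phase})

        for met, fresh_conc in fresh.items():
            rate = rates[phase].get(met, 0.0)
            spent = fresh_conc - rate * cell_hours
            starved = False
            if spent < 0:
                spent, starved = 0.0, True  # depletion floor: starvation
            truth_rows.append(
                {"day": day, "metabolite": met, "fresh_mM": fresh_conc, "spent_mM": spent, "starved": starved}
            )
            for rep in range(1, scenario.n_replicates + 1):
                for sample_type, conc in (("spent", spent), ("fresh", fresh_conc)):
                    panel_rows.append(
                        {
                            "day": day,
                            "sample_type": sample_type,
                            "metabolite": met,
                            "replicate": rep,
                            "integral": integral_of(noisy(conc), met),
                            "dss_integral": scenario.dss_integral,
                            "n_protons": DEFAULT_PROTON_COUNTS[met],
                        }
                    )
        prev_day = day

    return ExpansionPanel(
        panel=pd.DataFrame(panel_rows),
        truth=pd.DataFrame(truth_rows),
        counts=pd.DataFrame(count_rows),
        scenario=scenario,
    )


# ---------------------------------------------------------------------------
# idealized 1H spectrum rendering (round-trip support)
# ---------------------------------------------------------------------------

#: idealized, well-resolved singlet positions (ppm) for the quantified peak
#: of each metabolite; real multiplets are collapsed to singlets, which is
#: all window integration needs
H1_PEAK_PPM: dict[str, float] = {
    "formate": 8.46,
    "histidine": 7.80,
    "phenylalanine": 7.37,
    "tyrosine": 6.90,
    "fumarate": 6.52,
    "glucose": 5.23,
    "arginine": 3.24,
    "cysteine": 3.04,
    "glutamax": 2.72,
    "succinate": 2.55,
    "glutamine": 2.45,
    "pyruvate": 2.37,
    "alanine": 1.48,
    "lactate": 1.33,
    "ethanol": 1.19,
    "valine": 1.10,
    "isoleucine": 1.01,
    "leucine": 0.90,
    "dss": 0.0,
}

H1_FREQ_MHZ = 500.13
_H1_WINDOW_HALF = 0.03  # ppm; identical everywhere so Lorentzian tail
_H1_LINEWIDTH_HZ = 1.2  # losses cancel in the DSS ratio


def h1_peak_definitions(metabolites) -> dict[str, PeakDefinition]:
    """Singlet peak definitions (incl. DSS) for the idealized 1H panel."""
    out = {}
    for met in list(metabolites) + ["dss"]:
        c = H1_PEAK_PPM[met]
        out[met] = PeakDefinition(
            met, c, (c - _H1_WINDOW_HALF, c + _H1_WINDOW_HALF), linewidth_Hz=_H1_LINEWIDTH_HZ
        )
    return out


def render_h1_spectrum(
    conc_mM: Mapping[str, float],
    ref: QuantReference = QuantReference(),
    proton_counts: Mapping[str, int] | None = None,
    axis: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, dict[str, PeakDefinition]]:
    """Render an idealized 1H spectrum of a mixed (sample+buffer) tube.

    Each metabolite contributes one singlet whose area is proportional to
    its in-tube concentration times its proton count; DSS is added at
    0 ppm from ``ref``.  Returns (axis, spectrum, peak definitions) so the
    concentrations can be recovered by window integration + quantify.
    """
    counts = dict(DEFAULT_PROTON_COUNTS)
    if proton_counts:
        counts.update(proton_counts)
    peaks = h1_peak_definitions(conc_mM.keys())
    if axis is None:
        axis = np.arange(9.5, -0.5, -0.0005)
    fwhm_ppm = _H1_LINEWIDTH_HZ / H1_FREQ_MHZ
    gamma = fwhm_ppm / 2.0

    defs, amps = [], []
    for met, conc in conc_mM.items():
        tube = conc * ref.sample_dilution
        area = tube * counts[met]  # arbitrary common scale
        defs.append(peaks[met])
        amps.append(area / (math.pi * gamma))
    defs.append(peaks["dss"])
    amps.append(ref.dss_tube_conc_mM * ref.dss_protons / (math.pi * gamma))
    spectrum = synthesize_spectrum(defs, axis, H1_FREQ_MHZ, noise_sd=noise_sd, seed=seed, amplitudes=amps)
    return axis, spectrum, peaks


# ---------------------------------------------------------------------------
# named presets at the study's printed operating points
# ---------------------------------------------------------------------------


def preset_library() -> dict[str, DDNPScenario | ExpansionScenario]:
    """Named scenarios at the printed truths of the study's experiments.

    Rate constants and apparent T1s are the fitted values reported for
    each experiment; flip angles are the *effective* ones (nominal 20 deg
    ~ 15 deg effective, nominal 10 deg ~ 8 deg).  The day-21 pyruvate
    preset has no printed rate constant; it uses the day-14 value divided
    by the reported eightfold day-14 -> day-21 flux drop as a stand-in.
    """
    return {
        "fig1a_pyruvate": DDNPScenario(
            truth=KineticParams(10.7e-5, 30.0, 16.0, "apparent", S0=1.0),
            acq=AcquisitionParams(8.0, 2.0, 120),
            labels=("pyruvate", "lactate"),
        ),
        "fig1b_glucose": DDNPScenario(
            truth=KineticParams(9.4e-5, 10.0, 18.0, "apparent", S0=1.0),
            acq=AcquisitionParams(15.0, 2.0, 120),
            labels=("glucose", "lactate"),
        ),
        "day7": DDNPScenario(
            truth=KineticParams(5.278e-5, 9.0, 17.0, "apparent", S0=1.0),
            acq=AcquisitionParams(15.0, 1.0, 180),
            labels=("glucose", "lactate"),
        ),
        "day14": DDNPScenario(
            truth=KineticParams(1.146e-5, 9.0, 17.0, "apparent", S0=1.0),
            acq=AcquisitionParams(15.0, 1.0, 180),
            labels=("glucose", "lactate"),
        ),
        "day21_pyruvate": DDNPScenario(
            truth=KineticParams(1.146e-5 / 8.0, 28.0, 15.0, "apparent", S0=1.0),
            acq=AcquisitionParams(8.0, 1.0, 180),
            labels=("pyruvate", "lactate"),
        ),
        "expansion_default": ExpansionScenario(),
    }


def get_preset(name: str, seed: int | None = None):
    """Look up a preset by name, optionally re-seeding it."""
    lib = preset_library()
    if name not in lib:
        raise KeyError(f"unknown preset {name!r}; valid presets: {sorted(lib)}")
    scenario = lib[name]
    if seed is not None:
        scenario = replace(scenario, seed=seed)
    return scenario
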