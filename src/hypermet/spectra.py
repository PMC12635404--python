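"""Lorentzian spectrum synthesis and reduction to dynamic traces.

Spectra are represented on a descending ppm axis (NMR convention) with a
scans x points intensity matrix.  Peaks are defined by fixed integration
windows; a doublet (e.g. [1-13C]lactate formed from uniformly 13C-labelled
glucose, split by the one-bond 13C-13C coupling of 55 Hz) is rendered as
two half-amplitude Lorentzian components at center +/- J/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .kinetics import DynamicSeries

__all__ = [
    "PeakDefinition",
    "SpectrumSeries",
    "synthesize_spectrum",
    "integrate_peak",
    "series_to_dynamic",
    "estimate_noise",
    "hz_to_ppm",
    "ppm_to_hz",
    "DEFAULT_C13_PEAKS",
    "DEFAULT_FREQ_MHZ",
]

#: 13C Larmor frequency on an 11.7 T (500 MHz 1H) instrument
DEFAULT_FREQ_MHZ = 125.77


def hz_to_ppm(hz: float, freq_MHz: float) -> float:
    """Convert a frequency difference in Hz to ppm at the given carrier."""
    if freq_MHz <= 0:
        raise ValueError("freq_MHz must be positive")
    return hz / freq_MHz


def ppm_to_hz(ppm: float, freq_MHz: float) -> float:
    if freq_MHz <= 0:
        raise ValueError("freq_MHz must be positive")
    return ppm * freq_MHz


@dataclass(frozen=True)
class PeakDefinition:
    """A named resonance with its fixed integration window.

    ``window_ppm`` is the half-open interval [low, high); half-open windows
    let adjacent windows partition the axis cleanly.  ``J_Hz`` (doublets
    only) is the scalar coupling splitting; ``amplitude`` is used only when
    generating synthetic spectra.
    """

    name: str
    center_ppm: float
    window_ppm: tuple[float, float]
    multiplicity: str = "singlet"
    J_Hz: float | None = None
    linewidth_Hz: float = 2.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        low, high = self.window_ppm
        if not low < high:
            raise ValueError(f"window_ppm must be (low, high) with low < high, got {self.window_ppm}")
        if not low <= self.center_ppm < high:
            raise ValueError(
                f"peak {self.name!r}: center {self.center_ppm} outside window {self.window_ppm}"
            )
        if self.multiplicity not in ("singlet", "doublet"):
            raise ValueError(f"multiplicity must be singlet or doublet, got {self.multiplicity!r}")
        if self.multiplicity == "doublet" and not (self.J_Hz and self.J_Hz > 0):
            raise ValueError(f"peak {self.name!r}: doublet requires J_Hz > 0")
        if self.linewidth_Hz <= 0:
            raise ValueError("linewidth_Hz must be positive")


#: default 13C chemical shifts observed after hyperpolarized glucose injection
DEFAULT_C13_PEAKS: dict[str, PeakDefinition] = {
    p.name: p
    for p in (
        PeakDefinition("pyruvate_c2", 208.0, (206.5, 209.5)),
        PeakDefinition("lactate_c1", 183.5, (182.0, 185.0), "doublet", J_Hz=55.0),
        PeakDefinition("pyruvate_hydrate", 172.0, (170.5, 173.5)),
        PeakDefinition("bicarbonate", 162.0, (160.5, 163.5)),
        # anomeric carbons; no single printed shift, window covers the region
        PeakDefinition("glucose_anomeric", 95.0, (92.0, 98.0), linewidth_Hz=4.0),
    )
}


@dataclass
class SpectrumSeries:
    """A stack of spectra over scans on a common descending ppm axis."""

    ppm_axis: np.ndarray
    intensities: np.ndarray
    spectrometer_freq_MHz: float = DEFAULT_FREQ_MHZ
    scan_times_s: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        d = np.diff(self.ppm_axis)
        if self.ppm_axis.size < 2 or not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm_axis must be strictly monotonic")
        if self.intensities.shape[1] != self.ppm_axis.size:
            raise ValueError("intensity matrix width must match ppm_axis length")
        if self.spectrometer_freq_MHz <= 0:
            raise ValueError("spectrometer_freq_MHz must be positive")
        if self.scan_times_s is not None:
            self.scan_times_s = np.asarray(self.scan_times_s, dtype=float)
            if self.scan_times_s.size != self.intensities.shape[0]:
                raise ValueError("scan_times_s length must match scan count")

    @property
    def n_scans(self) -> int:
        return int(self.intensities.shape[0])

    def summed(self, n_first: int | None = None) -> np.ndarray:
        """Element-wise sum of the first ``n_first`` spectra (all by default)."""
        n = self.n_scans if n_first is None else int(n_first)
        if not 1 <= n <= self.n_scans:
            raise ValueError(f"n_first must be in [1, {self.n_scans}], got {n}")
        return self.intensities[:n].sum(axis=0)

    # -- interchange: axis+matrix CSV plus a JSON sidecar -------------------
    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        np.savetxt(stem.with_suffix(".axis.csv"), self.ppm_axis, fmt="%.17g")
        np.savetxt(stem.with_suffix(".matrix.csv"), self.intensities, fmt="%.17g", delimiter=",")
        sidecar = {
            "spectrometer_freq_MHz": self.spectrometer_freq_MHz,
            "scan_times_s": None if self.scan_times_s is None else self.scan_times_s.tolist(),
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, stem: str | Path) -> "SpectrumSeries":
        stem = Path(stem)
        axis = np.loadtxt(stem.with_suffix(".axis.csv"))
        mat = np.loadtxt(stem.with_suffix(".matrix.csv"), delimiter=",")
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        times = sidecar.get("scan_times_s")
        return cls(
            axis,
            mat,
            spectrometer_freq_MHz=sidecar["spectrometer_freq_MHz"],
            scan_times_s=None if times is None else np.asarray(times),
        )


def _lorentzian(axis: np.ndarray, center_ppm: float, fwhm_ppm: float, amp: float) -> np.ndarray:
    g = fwhm_ppm / 2.0
    return amp * g * g / ((axis - center_ppm) ** 2 + g * g)


def synthesize_spectrum(
    peaks: Sequence[PeakDefinition],
    axis: np.ndarray,
    freq_MHz: float = DEFAULT_FREQ_MHZ,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    amplitudes: Sequence[float] | None = None,
) -> np.ndarray:
    """Render a sum of Lorentzian lines with optional additive Gaussian noise.

    A singlet of amplitude A peaks at A at its center; a doublet contributes
    two A/2 components at center +/- J/(2*freq) ppm.  ``amplitudes``
    overrides the per-peak ``amplitude`` fields (same order as ``peaks``).
    """
    axis = np.asarray(axis, dtype=float)
    lo, hi = axis.min(), axis.max()
    spectrum = np.zeros_like(axis)
    if amplitudes is not None and len(amplitudes) != len(peaks):
        raise ValueError("amplitudes must match peaks in length")
    for i, peak in enumerate(peaks):
        wlo, whi = peak.window_ppm
        if wlo < lo or whi > hi:
            raise ValueError(f"axis does not cover window of peak {peak.name!r}")
        amp = peak.amplitude if amplitudes is None else float(amplitudes[i])
        fwhm_ppm = hz_to_ppm(peak.linewidth_Hz, freq_MHz)
        if peak.multiplicity == "doublet":
            half = hz_to_ppm(peak.J_Hz, freq_MHz) / 2.0
            spectrum += _lorentzian(axis, peak.center_ppm - half, fwhm_ppm, amp / 2.0)
            spectrum += _lorentzian(axis, peak.center_ppm + half, fwhm_ppm, amp / 2.0)
        else:
            spectrum += _lorentzian(axis, peak.center_ppm, fwhm_ppm, amp)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        spectrum = spectrum + rng.normal(0.0, noise_sd, size=axis.size)
    return spectrum


def _window_mask(axis: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    low, high = window
    if not low < high:
        raise ValueError(f"window must be (low, high) with low < high, got {window}")
    return (axis >= low) & (axis < high)


def integrate_peak(
    spectrum: np.ndarray,
    axis: np.ndarray,
    window: tuple[float, float],
    baseline: bool = False,
) -> float:
    """Trapezoidal integral of ``spectrum`` over the half-open ppm window.

    With ``baseline=True`` a straight line anchored at the window-edge
    intensities is subtracted first (crude linear baseline correction).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    axis = np.asarray(axis, dtype=float)
    mask = _window_mask(axis, window)
    if mask.sum() < 2:
        raise ValueError(f"window {window} contains fewer than 2 axis points")
    x = axis[mask]
    y = spectrum[mask]
    order = np.argsort(x)
    x, y = x[order], y[order]
    if baseline:
        y = y - np.interp(x, [x[0], x[-1]], [y[0], y[-1]])
    return float(np.trapezoid(y, x))


def estimate_noise(
    spectrum: np.ndarray,
    axis: np.ndarray,
    signal_free_window: tuple[float, float],
    peaks: Sequence[PeakDefinition] = (),
) -> float:
    """Robust noise SD (1.4826 x MAD) in a signal-free region.

    When ``peaks`` are supplied, a window overlapping any peak window is
    rejected — a peak inside the "noise" region would inflate the estimate.
    """
    lo, hi = signal_free_window
    for peak in peaks:
        plo, phi = peak.window_ppm
        if lo < phi and plo < hi:
            raise ValueError(
                f"signal-free window {signal_free_window} overlaps peak {peak.name!r} window"
            )
    vals = np.asarray(spectrum, dtype=float)[_window_mask(np.asarray(axis, float), signal_free_window)]
    if vals.size < 16:
        raise ValueError("signal-free window must contain at least 16 points")
    return float(1.4826 * np.median(np.abs(vals - np.median(vals))))


def series_to_dynamic(
    spectra: SpectrumSeries,
    substrate_peak: PeakDefinition,
    product_peak: PeakDefinition,
    baseline: bool = False,
) -> DynamicSeries:
    """Per-scan window integration of both peaks -> substrate/product traces."""
    times = spectra.scan_times_s
    if times is None:
        times = np.arange(spectra.n_scans, dtype=float)
    sub = np.empty(spectra.n_scans)
    prod = np.empty(spectra.n_scans)
    for i in range(spectra.n_scans):
        sub[i] = integrate_peak(spectra.intensities[i], spectra.ppm_axis, substrate_peak.window_ppm, baseline)
        prod[i] = integrate_peak(spectra.intensities[i], spectra.ppm_axis, product_peak.window_ppm, baseline)
    series = DynamicSeries(times, sub, prod, labels=(substrate_peak.name, product_peak.name))
    slo, shi = substrate_peak.window_ppm
    plo, phi = product_peak.window_ppm
    if slo < phi and plo < shi:
        series.meta["warnings"] = [
            f"integration windows overlap: {substrate_peak.name} {substrate_peak.window_ppm} "
            f"vs {product_peak.name} {product_peak.window_ppm}"
        ]
    return series
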