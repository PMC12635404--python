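"""Estimation of the apparent conversion rate constant from dynamic traces.

The central object is :class:`TwoPoolModel`: built from a
:class:`~hypermet.kinetics.DynamicSeries`, its :meth:`~TwoPoolModel.fit`
minimizes the joint sum of squared residuals of the substrate and product
traces against the closed-form two-pool solution *with the pulsing term
set to zero* — the fitted T1s are therefore apparent values that fold in
the RF sampling losses.  This keeps the number of free parameters small
(k, T1_s_app, T1_p_app, S0 by default; P0 is fixed at 0 since no product
is present at injection) and is robust at low SNR, where flip angle and
T1 are strongly interdependent.  The sampling losses are removed
afterwards with :func:`~hypermet.kinetics.correct_t1_apparent`.

Also here: R² goodness of fit, summed-spectra quantification for series
too weak for dynamic fitting, fold changes, and the paired t-test used to
compare rate constants between expansion time points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .kinetics import (
    AcquisitionParams,
    DynamicSeries,
    KineticParams,
    correct_t1_apparent,
    evolve_closed_form,
)
from .spectra import PeakDefinition, SpectrumSeries, estimate_noise, integrate_peak

__all__ = [
    "FitConfig",
    "TwoPoolModel",
    "TwoPoolResults",
    "fit_two_pool",
    "r_squared",
    "fold_change",
    "paired_t_test",
    "summed_quantification",
    "BelowDetectionError",
]

#: a windowed peak is considered quantifiable when its SNR reaches this
SNR_DETECTION_THRESHOLD = 3.0


class BelowDetectionError(ValueError):
    """Raised when a trace carries no usable signal (flat / zero dynamic range)."""


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :class:`TwoPoolModel`.

    Bounds are generous and physics-motivated; the multistart (log-normal
    jitter around the initial guess, fixed seed) guards against local
    minima of the joint objective.
    """

    k_bounds: tuple[float, float] = (0.0, 1e-2)
    t1_bounds: tuple[float, float] = (1.0, 120.0)
    t1_substrate_guess_s: float = 30.0
    t1_product_guess_s: float = 20.0
    fit_p0: bool = False  # P0 fixed at 0 by default: no product at injection
    # per-trace inverse-variance (robust noise from first differences) keeps
    # the joint objective and the standard errors honest when the two traces
    # have very different noise floors; "uniform" is available for comparison
    weighting: str = "inverse-variance"
    n_starts: int = 5
    random_seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.k_bounds, self.t1_bounds):
            if not lo < hi:
                raise ValueError("bounds must be ordered (low < high)")
        if self.weighting not in ("uniform", "inverse-variance"):
            raise ValueError("weighting must be 'uniform' or 'inverse-variance'")
        if not (self.t1_bounds[0] <= self.t1_substrate_guess_s <= self.t1_bounds[1]):
            raise ValueError("substrate T1 guess outside bounds")
        if not (self.t1_bounds[0] <= self.t1_product_guess_s <= self.t1_bounds[1]):
            raise ValueError("product T1 guess outside bounds")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


def _robust_noise_sd(trace: np.ndarray) -> float:
    """Noise SD from first differences (robust to the smooth signal)."""
    d = np.diff(trace)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / math.sqrt(2.0))


class TwoPoolModel:
    """Joint least-squares model for a substrate/product dynamic series."""

    #: free parameters, in optimizer order
    PARAM_NAMES = ("k_per_s", "T1_substrate_s", "T1_product_s", "S0", "P0")

    def __init__(self, series: DynamicSeries, config: FitConfig | None = None):
        if len(series) < 8:
            raise ValueError("need at least 8 time points to fit the two-pool model")
        peak = float(np.max(series.substrate_signal))
        if peak <= 0:
            raise BelowDetectionError("substrate trace has no positive peak")
        span = peak - float(np.min(series.substrate_signal))
        if span <= 0:
            raise BelowDetectionError("substrate trace is flat (below detection)")
        self.series = series
        self.config = config or FitConfig()
        self._weights = self._make_weights()

    # -- internals ----------------------------------------------------------
    def _make_weights(self) -> tuple[float, float]:
        if self.config.weighting == "uniform":
            return 1.0, 1.0
        ws = _robust_noise_sd(self.series.substrate_signal)
        wp = _robust_noise_sd(self.series.product_signal)
        floor = 1e-12 * max(np.max(np.abs(self.series.substrate_signal)), 1.0)
        return 1.0 / max(ws, floor), 1.0 / max(wp, floor)

    def _unpack(self, theta: np.ndarray) -> KineticParams:
        p0 = theta[4] if self.config.fit_p0 else 0.0
        return KineticParams(
            k_per_s=float(theta[0]),
            T1_substrate_s=float(theta[1]),
            T1_product_s=float(theta[2]),
            T1_mode="apparent",
            S0=float(theta[3]),
            P0=float(p0),
        )

    def predict(self, params: KineticParams) -> DynamicSeries:
        """Forward model (pulsing folded into the apparent T1s)."""
        return evolve_closed_form(params, None, self.series.times_s, labels=self.series.labels)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        model = self.predict(self._unpack(theta))
        ws, wp = self._weights
        return np.concatenate(
            [
                ws * (model.substrate_signal - self.series.substrate_signal),
                wp * (model.product_signal - self.series.product_signal),
            ]
        )

    def _initial_guess(self) -> np.ndarray:
        s = self.series
        peak = float(np.max(s.substrate_signal))
        # k from the initial product build-up slope: dP/dt ~ k * S_peak
        n0 = max(3, len(s) // 10)
        dt = s.times_s[n0] - s.times_s[0]
        slope = (s.product_signal[n0] - s.product_signal[0]) / dt if dt > 0 else 0.0
        k0 = float(np.clip(slope / peak, *self.config.k_bounds))
        if k0 <= 0:
            k0 = math.sqrt(max(self.config.k_bounds[0], 1e-8) * self.config.k_bounds[1])
        return np.array(
            [
                k0,
                self.config.t1_substrate_guess_s,
                self.config.t1_product_guess_s,
                peak,
                0.0,
            ]
        )

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        peak = float(np.max(self.series.substrate_signal))
        lo = np.array([self.config.k_bounds[0], self.config.t1_bounds[0], self.config.t1_bounds[0], 0.0, 0.0])
        hi = np.array(
            [
                self.config.k_bounds[1],
                self.config.t1_bounds[1],
                self.config.t1_bounds[1],
                10.0 * peak,
                10.0 * peak,
            ]
        )
        return lo, hi

    # -- fitting ------------------------------------------------------------
    def fit(self) -> "TwoPoolResults":
        """Multistart trust-region least squares; returns a results object."""
        cfg = self.config
        n_free = 5 if cfg.fit_p0 else 4
        guess = self._initial_guess()[:n_free]
        lo, hi = (b[:n_free] for b in self._bounds())
        guess = np.clip(guess, lo + 1e-12, hi - 1e-12)
        rng = np.random.default_rng(cfg.random_seed)
        x_scale = np.maximum(np.abs(guess), [1e-6, 1.0, 1.0, 1e-3, 1e-3][:n_free])

        best = None
        for start in range(cfg.n_starts):
            if start == 0:
                x0 = guess
            else:
                x0 = np.clip(guess * np.exp(rng.normal(0.0, 0.5, size=n_free)), lo + 1e-12, hi - 1e-12)
            try:
                res = least_squares(
                    lambda th: self._residuals(np.append(th, 0.0) if n_free == 4 else th),
                    x0,
                    bounds=(lo, hi),
                    x_scale=x_scale,
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("all optimizer starts failed")

        theta = np.append(best.x, 0.0) if n_free == 4 else best.x
        params_hat = self._unpack(theta)
        fitted = self.predict(params_hat)

        # standard errors from the Jacobian-based covariance at the optimum
        n_obs = 2 * len(self.series)
        dof = max(n_obs - n_free, 1)
        s2 = 2.0 * best.cost / dof
        J = best.jac
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            cov = np.full((n_free, n_free), np.nan)
            se = np.full(n_free, np.nan)
        bse = dict(zip(self.PARAM_NAMES[:n_free], se))

        return TwoPoolResults(
            model=self,
            params=params_hat,
            bse=bse,
            rsquared_substrate=r_squared(self.series.substrate_signal, fitted.substrate_signal),
            rsquared_product=_r_squared_or_nan(self.series.product_signal, fitted.product_signal),
            residual_norm=float(np.sqrt(2.0 * best.cost)),
            converged=bool(best.success),
            n_points=len(self.series),
            cov=cov,
        )


@dataclass
class TwoPoolResults:
    """Estimates, uncertainties and diagnostics of a two-pool fit."""

    model: TwoPoolModel
    params: KineticParams  # apparent-mode estimates
    bse: dict[str, float]
    rsquared_substrate: float
    rsquared_product: float
    residual_norm: float
    converged: bool
    n_points: int
    cov: np.ndarray | None = None

    @property
    def fittedvalues(self) -> DynamicSeries:
        return self.model.predict(self.params)

    def corrected_t1(self, acq: AcquisitionParams) -> tuple[float, float]:
        """True (substrate, product) T1s after removing RF sampling losses."""
        return (
            correct_t1_apparent(self.params.T1_substrate_s, acq),
            correct_t1_apparent(self.params.T1_product_s, acq),
        )

    def summary(self) -> str:
        lab_s, lab_p = self.model.series.labels
        lines = [
            "Two-pool hyperpolarized kinetics fit (apparent-T1 convention)",
            "=" * 62,
            f"traces: {lab_s} -> {lab_p}   n = {self.n_points} scans",
            f"converged: {self.converged}   residual norm: {self.residual_norm:.4g}",
            "",
            f"{'parameter':<16}{'estimate':>14}{'std err':>12}",
            "-" * 42,
        ]
        est = {
            "k_per_s": self.params.k_per_s,
            "T1_substrate_s": self.params.T1_substrate_s,
            "T1_product_s": self.params.T1_product_s,
            "S0": self.params.S0,
            "P0": self.params.P0,
        }
        for name, value in est.items():
            se = self.bse.get(name)
            se_txt = f"{se:>12.4g}" if se is not None and np.isfinite(se) else f"{'fixed':>12}"
            lines.append(f"{name:<16}{value:>14.6g}{se_txt}")
        lines += [
            "-" * 42,
            f"R^2 {lab_s}: {self.rsquared_substrate:.4f}   R^2 {lab_p}: {self.rsquared_product:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "k_per_s": self.params.k_per_s,
            "T1_substrate_apparent_s": self.params.T1_substrate_s,
            "T1_product_apparent_s": self.params.T1_product_s,
            "S0": self.params.S0,
            "P0": self.params.P0,
            "bse": {k: float(v) for k, v in self.bse.items()},
            "r2_substrate": self.rsquared_substrate,
            "r2_product": self.rsquared_product,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "n_points": self.n_points,
        }

    def plot(self, ax=None):
        """Observed points and fitted curves on one axis (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        f = self.fittedvalues
        lab_s, lab_p = s.labels
        ax.plot(s.times_s, s.substrate_signal, ".", label=f"{lab_s} (obs)")
        ax.plot(s.times_s, s.product_signal, ".", label=f"{lab_p} (obs)")
        ax.plot(f.times_s, f.substrate_signal, "-", label=f"{lab_s} (fit)")
        ax.plot(f.times_s, f.product_signal, "-", label=f"{lab_p} (fit)")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("signal (a.u.)")
        ax.legend()
        return ax


def fit_two_pool(series: DynamicSeries, config: FitConfig | None = None) -> TwoPoolResults:
    """Convenience wrapper: ``TwoPoolModel(series, config).fit()``."""
    return TwoPoolModel(series, config).fit()


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.size != fitted.size:
        raise ValueError("observed and fitted must have equal length")
    if observed.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for a constant observed vector")
    ss_res = float(np.sum((observed - fitted) ** 2))
    return 1.0 - ss_res / ss_tot


def _r_squared_or_nan(observed: np.ndarray, fitted: np.ndarray) -> float:
    try:
        return r_squared(observed, fitted)
    except ValueError:
        return float("nan")


def fold_change(value_a: float, value_b: float) -> float:
    """Plain ratio value_a / value_b (b must be positive)."""
    if value_b <= 0:
        raise ZeroDivisionError("fold_change denominator must be positive")
    return value_a / value_b


def paired_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Paired two-tailed t-test; returns (t statistic, p value).

    Pairs must be matched (same donor measured at both time points).  A
    zero-variance difference vector makes t infinite and is signalled.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired groups must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        raise ValueError("zero-variance differences: t statistic is infinite")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# summed-spectra quantification (low-flux fallback)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakQuant:
    name: str
    integral: float
    snr: float
    quantifiable: bool


def summed_quantification(
    spectra: SpectrumSeries,
    peaks: Sequence[PeakDefinition],
    n_first: int = 50,
    noise_window: tuple[float, float] | None = None,
    snr_threshold: float = SNR_DETECTION_THRESHOLD,
) -> list[PeakQuant]:
    """Sum the first ``n_first`` spectra and integrate each peak window.

    When a time series is too weak for dynamic fitting, summing the first
    scans trades time resolution for SNR.  Each peak gets a window
    integral and an SNR estimate (peak maximum over the robust noise SD of
    a signal-free region); peaks with SNR below ``snr_threshold`` are
    flagged not quantifiable.
    """
    n = int(n_first)
    if not 1 <= n <= spectra.n_scans:
        raise ValueError(f"n_first must be in [1, {spectra.n_scans}], got {n}")
    summed = spectra.summed(n)
    axis = spectra.ppm_axis
    if noise_window is None:
        # widest stretch of axis clear of every peak window
        lo, hi = float(axis.min()), float(axis.max())
        edges = sorted([(max(lo, w[0]), min(hi, w[1])) for w in (p.window_ppm for p in peaks)])
        gaps = []
        cursor = lo
        for wlo, whi in edges:
            if wlo > cursor:
                gaps.append((cursor, wlo))
            cursor = max(cursor, whi)
        if hi > cursor:
            gaps.append((cursor, hi))
        if not gaps:
            raise ValueError("no signal-free region available; pass noise_window explicitly")
        noise_window = max(gaps, key=lambda g: g[1] - g[0])
    sd = estimate_noise(summed, axis, noise_window, peaks=peaks)
    out = []
    for peak in peaks:
        integral = integrate_peak(summed, axis, peak.window_ppm)
        mask = (axis >= peak.window_ppm[0]) & (axis < peak.window_ppm[1])
        height = float(np.max(summed[mask]))
        snr = math.inf if sd == 0 else height / sd
        out.append(PeakQuant(peak.name, integral, snr, snr >= snr_threshold))
    return out
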