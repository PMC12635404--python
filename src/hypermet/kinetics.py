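"""Two-pool hyperpolarized signal evolution.

An injected hyperpolarized substrate S (e.g. [1-13C]pyruvate or
[U-13C,2H]glucose) is converted irreversibly to a product P (e.g.
[1-13C]lactate) while both signals decay through longitudinal relaxation
(T1) and through RF sampling (each excitation pulse of angle ``pw``
destroys a fraction ``1 - cos(pw)`` of the longitudinal magnetization
every repetition time ``TR``):

    dS/dt = -k*S - S/T1_s - p*S
    dP/dt =  k*S - P/T1_p - p*P,      p = (1 - cos pw) / TR

The pair is linear and has a closed-form solution, implemented in
:func:`evolve_closed_form`; :func:`evolve_ode` integrates the same system
numerically and serves as an internal cross-check.  In the *apparent*
convention the pulsing loss is folded into the T1 values (p is set to 0
and the fitted T1s are "apparent"); :func:`correct_t1_apparent` /
:func:`apparent_from_true_t1` convert between the apparent and true time
constants.  :func:`simulate_discrete_pulses` is a brute-force pulse-by-
pulse simulator used as an independent oracle for the continuous
apparent-T1 approximation.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "AcquisitionParams",
    "KineticParams",
    "DynamicSeries",
    "evolve_closed_form",
    "evolve_ode",
    "simulate_discrete_pulses",
    "apparent_from_true_t1",
    "correct_t1_apparent",
    "pulsing_rate",
]

#: closed-form solution switches to the degenerate (a == b) branch below this
DEGENERATE_RATE_TOL = 1e-10  # s^-1


@dataclass(frozen=True)
class AcquisitionParams:
    """Pulsed-acquisition settings governing RF sampling losses.

    Parameters
    ----------
    flip_angle_deg : float
        Effective excitation pulse angle ``pw`` in degrees, ``0 <= pw < 90``.
        Note the effective angle may be smaller than the nominal one set at
        the console; see :func:`effective_flip_angle`.
    repetition_time_s : float
        Delay TR between consecutive pulses, seconds.
    n_scans : int
        Number of recorded scans (>= 2).
    t0_offset_s : float
        Time of the first scan relative to injection (default 0; the
        polarizer-to-magnet transfer delay may be recorded here).
    """

    flip_angle_deg: float
    repetition_time_s: float
    n_scans: int = 120
    t0_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_angle_deg < 90.0:
            raise ValueError(
                f"flip_angle_deg must be in [0, 90), got {self.flip_angle_deg}"
            )
        if self.repetition_time_s <= 0:
            raise ValueError("repetition_time_s must be positive")
        if self.n_scans < 2:
            raise ValueError("n_scans must be >= 2")
        if self.t0_offset_s < 0:
            raise ValueError("t0_offset_s must be >= 0")

    @property
    def pulsing_rate_per_s(self) -> float:
        """Sampling-loss rate p = (1 - cos pw)/TR in 1/s."""
        return pulsing_rate(self.flip_angle_deg, self.repetition_time_s)

    def scan_times(self) -> np.ndarray:
        """Scan time grid t_i = t0 + i*TR, seconds."""
        return self.t0_offset_s + np.arange(self.n_scans) * self.repetition_time_s


def pulsing_rate(flip_angle_deg: float, repetition_time_s: float) -> float:
    """RF sampling-loss rate (1 - cos pw)/TR in 1/s."""
    return (1.0 - math.cos(math.radians(flip_angle_deg))) / repetition_time_s


def effective_flip_angle(nominal_deg: float, calibration: float = 0.78) -> float:
    """Map a nominal console flip angle to the effective in-sample angle.

    B1 inhomogeneity and calibration on dissolution samples typically make
    the effective angle smaller than nominal (e.g. 20 deg nominal ~ 15 deg
    effective, 10 deg ~ 8 deg).  ``calibration`` is a user-set factor, not
    fitted.
    """
    if not 0 < calibration <= 1:
        raise ValueError("calibration must be in (0, 1]")
    return nominal_deg * calibration


@dataclass(frozen=True)
class KineticParams:
    """State of the two-pool conversion model.

    ``T1_mode`` records whether the T1 values are *apparent* (RF sampling
    losses folded in, the convention used when fitting) or *true*
    (relaxation only; pulsing must then be modelled explicitly).
    """

    k_per_s: float
    T1_substrate_s: float
    T1_product_s: float
    T1_mode: Literal["apparent", "true"] = "apparent"
    S0: float = 1.0
    P0: float = 0.0

    def __post_init__(self) -> None:
        if self.k_per_s < 0:
            raise ValueError("k_per_s must be >= 0")
        if not (self.T1_substrate_s > 0 and self.T1_product_s > 0):
            raise ValueError("T1 values must be positive")
        if self.S0 < 0 or self.P0 < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.T1_mode not in ("apparent", "true"):
            raise ValueError(f"unknown T1_mode {self.T1_mode!r}")


@dataclass
class DynamicSeries:
    """Time-stamped substrate/product signal traces (arbitrary units)."""

    times_s: np.ndarray
    substrate_signal: np.ndarray
    product_signal: np.ndarray
    labels: tuple[str, str] = ("substrate", "product")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.substrate_signal = np.asarray(self.substrate_signal, dtype=float)
        self.product_signal = np.asarray(self.product_signal, dtype=float)
        n = self.times_s.size
        if self.substrate_signal.size != n or self.product_signal.size != n:
            raise ValueError("times, substrate and product must have equal length")
        if n > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")
        for name, arr in (
            ("times_s", self.times_s),
            ("substrate_signal", self.substrate_signal),
            ("product_signal", self.product_signal),
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    def __len__(self) -> int:
        return int(self.times_s.size)

    # -- interchange: plain CSV, header `time_s,substrate,product` ---------
    def to_csv(self, path_or_buf) -> None:
        """Write the series as CSV (bit-stable %.17g text formatting)."""
        lines = ["time_s,substrate,product"]
        for t, s, p in zip(self.times_s, self.substrate_signal, self.product_signal):
            lines.append(f"{t:.17g},{s:.17g},{p:.17g}")
        text = "\n".join(lines) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf, labels=("substrate", "product")) -> "DynamicSeries":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise ValueError("empty DynamicSeries CSV")
        header = [c.strip() for c in lines[0].split(",")]
        required = {"time_s", "substrate", "product"}
        if not required.issubset(header):
            raise ValueError(
                f"DynamicSeries CSV header must contain {sorted(required)}, got {header}"
            )
        idx = {name: header.index(name) for name in required}
        rows = []
        for lineno, ln in enumerate(lines[1:], start=2):
            cells = ln.split(",")
            if len(cells) < len(header):
                raise ValueError(f"line {lineno}: expected {len(header)} columns, got {len(cells)}")
            try:
                rows.append(
                    (
                        float(cells[idx["time_s"]]),
                        float(cells[idx["substrate"]]),
                        float(cells[idx["product"]]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
        arr = np.array(rows, dtype=float)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], labels=tuple(labels))


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------


def _rates(params: KineticParams, acq: AcquisitionParams | None) -> tuple[float, float]:
    """Effective decay rates (a, b) for the substrate and product pools.

    Apparent mode: pulsing already folded into the T1s, p = 0 (``acq`` may
    be None).  True mode: p = (1 - cos pw)/TR from ``acq``.
    """
    if params.T1_mode == "apparent":
        p = 0.0
    else:
        if acq is None:
            raise ValueError("true-T1 mode requires AcquisitionParams for the pulsing rate")
        p = acq.pulsing_rate_per_s
    a = params.k_per_s + 1.0 / params.T1_substrate_s + p
    b = 1.0 / params.T1_product_s + p
    return a, b


def _transfer(a: float, b: float, tau: np.ndarray) -> np.ndarray:
    """(exp(-a t) - exp(-b t)) / (b - a), with the L'Hopital limit t*exp(-a t)."""
    if abs(b - a) < DEGENERATE_RATE_TOL:
        return tau * np.exp(-a * tau)
    return (np.exp(-a * tau) - np.exp(-b * tau)) / (b - a)


def evolve_closed_form(
    params: KineticParams,
    acq: AcquisitionParams | None,
    times: np.ndarray,
    labels: tuple[str, str] = ("substrate", "product"),
) -> DynamicSeries:
    """Analytic solution of the two-pool system on ``times``.

    ``times`` must be strictly increasing; t = times[0] is the first
    recorded scan, where S = S0 and P = P0.

        S(t) = S0 exp(-a t)
        P(t) = P0 exp(-b t) + k S0 (exp(-a t) - exp(-b t)) / (b - a)

    with a = k + 1/T1_s + p and b = 1/T1_p + p.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    a, b = _rates(params, acq)
    tau = times - times[0]
    S = params.S0 * np.exp(-a * tau)
    P = params.P0 * np.exp(-b * tau) + params.k_per_s * params.S0 * _transfer(a, b, tau)
    return DynamicSeries(times, S, P, labels=labels)


def evolve_ode(
    params: KineticParams,
    acq: AcquisitionParams | None,
    times: np.ndarray,
    rel_tol: float = 1e-10,
) -> DynamicSeries:
    """Numerical integration of the same ODE pair (cross-check path)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    a, b = _rates(params, acq)
    k = params.k_per_s

    if times.size == 1:
        return DynamicSeries(times, [params.S0], [params.P0])

    def rhs(_t, y):
        S, P = y
        return [-a * S, k * S - b * P]

    scale = max(params.S0, params.P0, 1.0)
    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        [params.S0, params.P0],
        t_eval=times,
        method="LSODA",
        rtol=rel_tol,
        atol=rel_tol * scale * 1e-3,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return DynamicSeries(times, sol.y[0], sol.y[1])


def simulate_discrete_pulses(
    true_params: KineticParams, acq: AcquisitionParams
) -> DynamicSeries:
    """Pulse-by-pulse oracle for the apparent-T1 approximation.

    Between pulses the longitudinal magnetizations evolve with the *true*
    T1s (p = 0); each pulse scales both pools by cos(pw) and records the
    pre-pulse longitudinal value times sin(pw).  Returns the recorded
    per-scan signals at t_i = t0 + i*TR.
    """
    if true_params.T1_mode != "true":
        raise ValueError("simulate_discrete_pulses requires T1_mode='true'")
    pw = math.radians(acq.flip_angle_deg)
    cos_pw, sin_pw = math.cos(pw), math.sin(pw)
    # free evolution uses the true relaxation rates only
    free = replace(true_params, T1_mode="apparent")
    a, b = _rates(free, None)
    k = true_params.k_per_s
    TR = acq.repetition_time_s
    ea, step_transfer = math.exp(-a * TR), float(_transfer(a, b, np.array([TR]))[0])
    eb = math.exp(-b * TR)

    S, P = true_params.S0, true_params.P0
    rec_S = np.empty(acq.n_scans)
    rec_P = np.empty(acq.n_scans)
    for i in range(acq.n_scans):
        rec_S[i] = S * sin_pw
        rec_P[i] = P * sin_pw
        S, P = S * cos_pw, P * cos_pw  # post-pulse longitudinal state
        S, P = S * ea, P * eb + k * S * step_transfer  # exact step over TR
    series = DynamicSeries(acq.scan_times(), rec_S, rec_P)
    series.meta["longitudinal_final"] = (S, P)
    return series


# ---------------------------------------------------------------------------
# apparent <-> true T1
# ---------------------------------------------------------------------------


def apparent_from_true_t1(T1_true_s: float, acq: AcquisitionParams) -> float:
    """Fold RF sampling losses into a true T1: 1/T1_app = 1/T1_true + p."""
    if T1_true_s <= 0:
        raise ValueError("T1_true_s must be positive")
    return 1.0 / (1.0 / T1_true_s + acq.pulsing_rate_per_s)


def correct_t1_apparent(T1_apparent_s: float, acq: AcquisitionParams) -> float:
    """Remove RF sampling losses from an apparent T1: 1/T1 = 1/T1_app - p.

    Raises ``ValueError`` when the apparent decay is slower than the
    pulsing loss alone (the implied true T1 would be non-positive).
    """
    if T1_apparent_s <= 0:
        raise ValueError("T1_apparent_s must be positive")
    p = acq.pulsing_rate_per_s
    rate = 1.0 / T1_apparent_s - p
    if rate <= 0:
        raise ValueError(
            "apparent relaxation rate 1/T1_app = "
            f"{1.0 / T1_apparent_s:.6g} /s does not exceed the pulsing rate "
            f"p = {p:.6g} /s; true T1 is undefined"
        )
    return 1.0 / rate
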