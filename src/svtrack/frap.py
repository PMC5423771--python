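"""FRAP recovery fitting and stimulation-destaining sigmoid fitting.

Fluorescence recovery after photobleaching (FRAP) reports vesicle-pool
mobility independently of single-particle tracking: a region of interest
(ROI) is bleached and the normalized intensity recovers as unbleached
mobile fluorophores diffuse in. A single-exponential recovery

    I(t) = I0 + A * (1 - exp(-k * t)),   t measured from the bleach,

yields the half-time T1/2 = ln(2)/k and the mobile fraction
A / (I_pre - I0); the effective diffusion coefficient follows from the
classic uniform-disk approximation D = 0.224 * omega**2 / T1/2, where
omega is the characteristic half-width (radius) of the bleached ROI.

Destaining during sustained stimulation is fitted with a Boltzmann
sigmoid I(t) = A2 + (A1 - A2) / (1 + exp((t - t0)/s)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FRAPRecord",
    "FRAPFit",
    "DestainingFit",
    "fit_recovery",
    "frap_diffusion",
    "fit_destaining",
]


@dataclass
class FRAPRecord:
    """Normalized ROI intensity time series around a bleach event."""

    times: np.ndarray            # s
    intensity: np.ndarray        # dimensionless, pre-bleach mean ~ 1
    bleach_index: int
    omega: float                 # µm, ROI characteristic half-width
    region_type: str = "swelling"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.times.shape != self.intensity.shape:
            raise ValueError("times and intensity must have the same length")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be >= 0")


@dataclass(frozen=True)
class FRAPFit:
    """Fitted recovery: mobile fraction, half-time, rate and diffusion."""

    mobile_fraction: float
    t_half: float       # s
    d: float            # µm²/s via the 0.224 disk approximation
    k: float            # 1/s
    i0: float           # bleach floor
    i_pre: float        # pre-bleach plateau


@dataclass(frozen=True)
class DestainingFit:
    """Boltzmann sigmoid fit of a destaining trace."""

    a1: float
    a2: float
    t0: float
    slope: float
    percent_destaining: float


def _recovery_model(t: np.ndarray, i0: float, a: float, k: float) -> np.ndarray:
    return i0 + a * (1.0 - np.exp(-k * t))


def fit_recovery(record: FRAPRecord) -> FRAPFit:
    """Least-squares single-exponential fit of the post-bleach recovery.

    The pre-bleach plateau is the mean intensity before ``bleach_index``;
    the fit runs on post-bleach samples with time measured from the bleach.
    Raises ``RuntimeError`` with diagnostics if the optimizer fails.
    """
    post_t = record.times[record.bleach_index:] - record.times[record.bleach_index]
    post_i = record.intensity[record.bleach_index:]
    if len(post_t) < 5:
        raise ValueError("need at least 5 post-bleach points to fit recovery")
    i_pre = float(record.intensity[:record.bleach_index].mean()) if record.bleach_index > 0 else 1.0

    i0_guess = float(post_i[0])
    a_guess = max(float(post_i[-1] - post_i[0]), 1e-6)
    span = max(float(post_t[-1]), 1.0)
    try:
        popt, _ = curve_fit(
            _recovery_model, post_t, post_i,
            p0=[i0_guess, a_guess, 2.0 / span],
            bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"FRAP recovery fit failed to converge: {exc}; "
            f"n={len(post_t)}, floor~{i0_guess:.3f}, pre~{i_pre:.3f}"
        ) from exc
    i0, a, k = popt
    denom = i_pre - i0
    mobile = float(a / denom) if denom > 1e-12 else 0.0
    mobile = float(np.clip(mobile, 0.0, 1.0))
    t_half = float(np.log(2.0) / k)
    return FRAPFit(
        mobile_fraction=mobile,
        t_half=t_half,
        d=frap_diffusion(record.omega, t_half),
        k=float(k),
        i0=float(i0),
        i_pre=i_pre,
    )


def frap_diffusion(omega: float, t_half: float) -> float:
    """Diffusion coefficient from ROI half-width and recovery half-time.

    D = 0.224 * omega**2 / T1/2 (uniform-disk bleach approximation).
    """
    if omega <= 0 or t_half <= 0:
        raise ValueError("omega and t_half must be > 0")
    return 0.224 * omega**2 / t_half


def _boltzmann(t: np.ndarray, a1: float, a2: float, t0: float, s: float) -> np.ndarray:
    return a2 + (a1 - a2) / (1.0 + np.exp((t - t0) / s))


def fit_destaining(times: np.ndarray, intensity: np.ndarray) -> DestainingFit:
    """Fit a Boltzmann sigmoid to a destaining intensity trace.

    Percent destaining is (A1 - A2) / A1 * 100, the fractional intensity
    loss between the initial and final plateaus. A monotone-increasing
    trace is fitted anyway but triggers a warning, since destaining should
    reduce intensity.
    """
    t = np.asarray(times, float)
    y = np.asarray(intensity, float)
    if len(t) < 5:
        raise ValueError("need at least 5 points to fit destaining")
    if y[-1] > y[0]:
        warnings.warn("trace increases over time; not a destaining profile", stacklevel=2)

    span = max(float(t[-1] - t[0]), 1.0)
    p0 = [float(y[:3].mean()), float(y[-3:].mean()), float(t[len(t) // 2]), span / 10.0]
    popt, _ = curve_fit(_boltzmann, t, y, p0=p0, maxfev=20000)
    a1, a2, t0, s = (float(v) for v in popt)
    pct = (a1 - a2) / a1 * 100.0 if a1 != 0 else float("nan")
    return DestainingFit(a1=a1, a2=a2, t0=t0, slope=s, percent_destaining=pct)
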