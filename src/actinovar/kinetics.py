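"""Hemolysis kinetics analytics.

Hemolysis of a red-cell suspension is followed as decreasing turbidity (A700).
A lysing trace is sigmoidal: a lag phase during which toxin binds,
oligomerizes and inserts, followed by a descent whose maximum slope is the
maximum velocity of hemolysis (υ_max). This module extracts lag time and
υ_max from traces, fits the power-law dependence of lag time on toxin
concentration (lag = τ·c⁻ˣ), converts endpoint absorbances to percent
hemolysis, and fits the Hill dose–response curve for HC50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class HemolysisTrace:
    """One turbidity time course; time in s, absorbance dimensionless."""

    time: np.ndarray
    absorbance: np.ndarray
    toxin_conc: float | None = None  # nM

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.size != a.size or t.size < 10:
            raise ValueError("trace needs ≥10 (time, absorbance) samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "absorbance", a)


@dataclass(frozen=True)
class KineticsResult:
    lag_time: float | None  # s; None when no lysis detected
    vmax: float | None      # s⁻¹, max of −d(A/A0)/dt
    lysed: bool
    baseline: float = 1.0   # normalized starting level
    t_at_vmax: float | None = None


@dataclass(frozen=True)
class PowerLawFit:
    tau: float
    x: float
    residuals: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class HillFit:
    hc50: float
    hill_n: float
    plateau: float
    extrapolated: bool = False


def _moving_average(y: np.ndarray, window: int = 5) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    # linear-extrapolation padding keeps edge slopes unbiased, so a trace
    # already descending at t=0 keeps its steepest tangent at the boundary
    k = min(window, y.size - 1)
    s0 = (y[k] - y[0]) / k
    s1 = (y[-1] - y[-1 - k]) / k
    left = y[0] - s0 * np.arange(pad, 0, -1)
    right = y[-1] + s1 * np.arange(1, pad + 1)
    ypad = np.concatenate([left, y, right])
    return np.convolve(ypad, kernel, mode="valid")[: y.size]


def analyze_trace(trace: HemolysisTrace, smooth_window: int = 5,
                  min_drop: float = 0.05) -> KineticsResult:
    """Lag time and maximum lysis velocity of one turbidity trace.

    The trace is lightly smoothed (moving average), normalized to its initial
    level A0, and differentiated. υ_max is the maximum descent rate of A/A0;
    the lag time is where the tangent at the steepest descent intersects the
    initial baseline. Traces whose total drop is below ``min_drop`` (fraction
    of A0) are reported as non-lysing rather than raising.
    """
    t = trace.time
    y = _moving_average(trace.absorbance.astype(float), smooth_window)
    a0 = float(np.mean(y[: max(3, y.size // 50)]))
    if a0 == 0:
        raise ValueError("zero initial absorbance")
    yn = y / a0
    if (yn.max() - yn.min()) < min_drop or (yn[0] - yn[-1]) < min_drop:
        return KineticsResult(lag_time=None, vmax=None, lysed=False)
    dy = np.gradient(yn, t)
    i = int(np.argmin(dy))
    vmax = float(-dy[i])
    # baseline = mean of the leading run still within 2% of the initial level,
    # so a trace already descending at t=0 keeps its first point as baseline
    drop = yn[0] - yn.min()
    stable = np.nonzero(yn < yn[0] - 0.02 * drop)[0]
    n_stable = int(stable[0]) if stable.size else yn.size
    baseline = float(np.mean(yn[: max(1, n_stable)]))
    # tangent through (t_i, yn_i) with slope dy_i meets the baseline level
    lag = t[i] + (baseline - yn[i]) / dy[i]
    lag = max(float(lag), 0.0)
    return KineticsResult(lag_time=lag, vmax=vmax, lysed=True,
                          baseline=baseline, t_at_vmax=float(t[i]))


def fit_power_law(points: list[tuple[float, float]]) -> PowerLawFit:
    """Fit lag = τ·c⁻ˣ by least squares on log(lag) vs log(c).

    The log-log linearization makes the fit deterministic and weights relative
    errors, matching how a single reaction-order exponent is reported.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (conc, lag) points")
    c, lag = pts[:, 0], pts[:, 1]
    if np.any(c <= 0) or np.any(lag <= 0):
        raise ValueError("concentrations and lag times must be positive")
    slope, intercept = np.polyfit(np.log(c), np.log(lag), 1)
    tau = float(np.exp(intercept))
    x = float(-slope)
    resid = np.log(lag) - (intercept + slope * np.log(c))
    return PowerLawFit(tau=tau, x=x, residuals=resid)


def hemolysis_percent(a412: float | np.ndarray, a_fin: float, a_max: float,
                      flag_bounds: tuple[float, float] = (-5.0, 105.0)):
    """Percent hemolysis from endpoint absorbance and the 0 %/100 % controls.

    Hemolysis (%) = (A412 − A_fin) / (A_max − A_fin) × 100. Values are not
    clipped — measurement noise may push them slightly outside [0, 100] — but
    a warning is emitted outside ``flag_bounds``.
    """
    if a_max == a_fin:
        raise ValueError("degenerate controls: A_max == A_fin")
    pct = (np.asarray(a412, dtype=float) - a_fin) / (a_max - a_fin) * 100.0
    lo, hi = flag_bounds
    if np.any(pct < lo) or np.any(pct > hi):
        warnings.warn(f"hemolysis percent outside [{lo}, {hi}]", stacklevel=2)
    return float(pct) if np.isscalar(a412) else pct


def _hill(c, hc50, n, plateau):
    return plateau * c ** n / (hc50 ** n + c ** n)


def fit_hill(points: list[tuple[float, float]], fix_plateau: float | None = 100.0) -> HillFit:
    """Fit the Hill dose–response H(c) = plateau·cⁿ/(HC50ⁿ + cⁿ).

    The plateau is fixed at 100 % by default (controls define full lysis);
    pass ``fix_plateau=None`` to fit it. Initial HC50 is the concentration
    whose response is nearest 50 %, initial n = 1. If the data never cross
    50 % the fit proceeds but is flagged as extrapolated.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (conc, pct) points")
    c, h = pts[:, 0], pts[:, 1]
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    extrapolated = not (h.min() <= 50.0 <= h.max())
    if extrapolated:
        warnings.warn("responses do not cross 50%; HC50 is extrapolated", stacklevel=2)
    hc0 = float(c[np.argmin(np.abs(h - 50.0))])
    if fix_plateau is not None:
        popt, _ = curve_fit(lambda cc, k, n: _hill(cc, k, n, fix_plateau),
                            c, h, p0=[hc0, 1.0], maxfev=10000,
                            bounds=([1e-9, 1e-3], [np.inf, np.inf]))
        hc50, n = popt
        plateau = fix_plateau
    else:
        popt, _ = curve_fit(_hill, c, h, p0=[hc0, 1.0, max(h.max(), 50.0)],
                            maxfev=10000,
                            bounds=([1e-9, 1e-3, 1e-3], [np.inf, np.inf, np.inf]))
        hc50, n, plateau = popt
    if hc50 <= 0 or n <= 0:
        raise RuntimeError("Hill fit converged to non-physical parameters")
    return HillFit(hc50=float(hc50), hill_n=float(n), plateau=float(plateau),
                   extrapolated=extrapolated)
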