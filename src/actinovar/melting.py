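"""Melting-temperature extraction from thermal unfolding curves.

A circular-dichroism melt (ellipticity vs temperature) is normalized to a
0–100 % unfolding scale between its pre- and post-transition baselines,
smoothed by block averaging (group reduction), differentiated, and the
melting temperature taken as the maximum of the first derivative, refined by
a three-point parabola.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class MeltingCurve:
    """Temperature (°C, strictly increasing) vs spectroscopic signal."""

    temperature: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.size != s.size or t.size < 20:
            raise ValueError("melting curve needs ≥20 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature must be strictly increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class TmResult:
    tm: float | None            # °C; None when no transition found
    window: int
    derivative_t: np.ndarray = field(repr=False, default=None)
    derivative: np.ndarray = field(repr=False, default=None)
    transition: bool = True


def group_reduce(x: np.ndarray, y: np.ndarray, window: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Block-average consecutive non-overlapping groups of ``window`` points.

    Each block of `window` points is replaced by its (mean x, mean y); a
    trailing partial block is averaged as-is. A linear series stays exactly
    linear, and the mean of y is preserved for window-divisible lengths.
    """
    if window < 1:
        raise ValueError("window must be ≥1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < window:
        raise ValueError("series shorter than window")
    n_full = x.size // window
    xs, ys = [], []
    for i in range(n_full):
        sl = slice(i * window, (i + 1) * window)
        xs.append(x[sl].mean())
        ys.append(y[sl].mean())
    if x.size % window:
        xs.append(x[n_full * window:].mean())
        ys.append(y[n_full * window:].mean())
    return np.array(xs), np.array(ys)


def percent_change(curve: MeltingCurve, baseline_frac: float = 0.10) -> np.ndarray:
    """Normalize the signal to 0–100 % between pre- and post-transition levels.

    Baselines are the means of the first and last ``baseline_frac`` of points.
    Orientation is auto-detected, so a sign-flipped signal normalizes to the
    same curve.
    """
    s = curve.signal
    if np.ptp(s) == 0:
        raise ValueError("constant signal cannot be normalized")
    k = max(2, int(round(baseline_frac * s.size)))
    pre, post = s[:k].mean(), s[-k:].mean()
    if pre == post:
        raise ValueError("identical pre/post baselines; no net transition")
    return (s - pre) / (post - pre) * 100.0


def melting_temperature(curve: MeltingCurve, window: int = 10,
                        baseline_frac: float = 0.10,
                        peak_prominence: float = 3.0) -> TmResult:
    """Melting temperature as the maximum of the first derivative.

    Pipeline: percent-change normalization → group reduction (block averages
    of ``window`` points) → central-difference derivative → parabolic
    interpolation around the maximum. A curve whose derivative peak does not
    stand out from the median derivative by ``peak_prominence``× (e.g. a bare
    linear baseline) is reported as having no transition.
    """
    pct = percent_change(curve, baseline_frac)
    tr, yr = group_reduce(curve.temperature, pct, window)
    if tr.size < 3:
        raise ValueError("too few points after group reduction")
    deriv = np.gradient(yr, tr)
    i = int(np.argmax(deriv))
    med = float(np.median(np.abs(deriv)))
    if med > 0 and deriv[i] < peak_prominence * med:
        return TmResult(tm=None, window=window, derivative_t=tr,
                        derivative=deriv, transition=False)
    if 0 < i < tr.size - 1:
        # 3-point parabola de-quantizes the reduced grid
        y0, y1, y2 = deriv[i - 1], deriv[i], deriv[i + 1]
        denom = y0 - 2 * y1 + y2
        offset = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        offset = float(np.clip(offset, -1.0, 1.0))
        tm = tr[i] + offset * (tr[min(i + 1, tr.size - 1)] - tr[max(i - 1, 0)]) / 2.0
    else:
        tm = tr[i]
    return TmResult(tm=float(tm), window=window, derivative_t=tr,
                    derivative=deriv, transition=True)
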