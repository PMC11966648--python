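"""Peak-based period/amplitude extraction shared by ODE and PDE metrics."""

from __future__ import annotations

import numpy as np

__all__ = ["peak_metrics"]


def peak_metrics(t: np.ndarray, y: np.ndarray, min_peaks: int = 4,
                 period_tol: float = 1e-3):
    """Estimate oscillation period and amplitude from a sampled signal.

    Discrete maxima are refined by fitting a quadratic through the three
    samples around each one; the period is the mean of successive
    refined peak times and the amplitude is max - min of the signal over
    the retained window.

    Returns ``(period, amplitude, converged, peak_times)``.  ``converged``
    requires at least ``min_peaks`` peaks and relative spread
    (max - min)/mean of the inter-peak intervals below ``period_tol``.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if len(t) < 3:
        return np.nan, np.nan, False, np.array([])
    span = y.max() - y.min()
    peak_times = []
    for i in range(1, len(y) - 1):
        if y[i] >= y[i - 1] and y[i] > y[i + 1] and y[i] > y.min() + 0.5 * span:
            # quadratic through (t[i-1..i+1], y[i-1..i+1]); vertex location
            denom = (y[i - 1] - 2 * y[i] + y[i + 1])
            if denom == 0:
                peak_times.append(t[i])
                continue
            dt = 0.5 * (y[i - 1] - y[i + 1]) / denom
            h = t[i + 1] - t[i]
            peak_times.append(t[i] + np.clip(dt, -1, 1) * h)
    peak_times = np.asarray(peak_times)
    if len(peak_times) < min_peaks:
        return np.nan, span, False, peak_times
    intervals = np.diff(peak_times)
    period = float(intervals.mean())
    spread = (intervals.max() - intervals.min()) / period if period > 0 else np.inf
    converged = bool(len(peak_times) >= min_peaks and spread < period_tol)
    return period, float(span), converged, peak_times
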