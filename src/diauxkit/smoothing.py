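"""Centered local-linear (moving regression) smoothing.

A single smoothing primitive is shared by the growth-kinetics and
reporter-dynamics modules so that smoothed OD traces, specific growth
rates, and dGFP/dt derivatives are all computed the same way: an
ordinary least-squares line is fitted to ``window`` consecutive readouts
centered on each point, and either the fitted value or the fitted slope
at the center is returned.  Near the ends of the series the window is
truncated (it always keeps at least two points), so the output has the
same length as the input.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError


def _check(t: np.ndarray, y: np.ndarray, window: int) -> None:
    if window < 2:
        raise ParameterError(f"smoothing window must be >= 2, got {window}")
    if len(t) != len(y):
        raise ParameterError("time and value arrays differ in length")
    if len(t) < 2:
        raise ParameterError("need at least two points to smooth")


def local_linear(t, y, window: int = 5, deriv: bool = False) -> np.ndarray:
    """Local-linear estimate of ``y`` (or ``dy/dt``) on its own grid.

    Parameters
    ----------
    t, y : array-like
        Sample locations (strictly increasing) and values.
    window : int
        Number of consecutive readouts per local fit (default 5, i.e.
        50 min at the standard 10-min plate-reader sampling).
    deriv : bool
        If True return the local slope instead of the fitted value.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    _check(t, y, window)
    n = len(t)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        tw = t[lo:hi] - t[i]
        yw = y[lo:hi]
        # closed-form simple linear regression on the window
        tm = tw.mean()
        ym = yw.mean()
        sxx = float(np.sum((tw - tm) ** 2))
        if sxx == 0.0:
            out[i] = 0.0 if deriv else ym
            continue
        slope = float(np.sum((tw - tm) * (yw - ym))) / sxx
        out[i] = slope if deriv else ym - slope * tm
    return out


def specific_growth_rate(time_h, od, window: int = 5) -> np.ndarray:
    """Smoothed specific growth rate d(ln OD)/dt in h^-1."""
    od = np.asarray(od, dtype=float)
    if np.any(od <= 0):
        raise ParameterError("OD must be strictly positive to take logs")
    return local_linear(time_h, np.log(od), window=window, deriv=True)
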