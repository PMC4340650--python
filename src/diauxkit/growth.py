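"""Growth-curve kinetics: rates, yields, diauxie calls and shift durations.

The exponential growth rate is the OLS slope of ln(OD) against time
restricted to calibrated OD 0.05-0.35; the yield is the (smoothed)
maximum OD.  Diauxic growth is detected by comparing that primary slope
with a second slope fitted over the extended range OD 0.05 to 90% of
the maximum OD: a genuine second, slower growth phase drags the
extended slope down, and a one-sided slope-equality test classifies the
curve.  The diauxic-shift duration is the growth-arrest interval
between the glucose and acetate phases, located by threshold crossings
of the smoothed specific growth rate and refined by intersecting the
flanking exponential regression lines with the arrest plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

import numpy as np
from scipy import stats as sps
from scipy.optimize import least_squares

from . import io as _io
from .errors import ParameterError, ShiftUnresolvedError, WindowError
from .smoothing import local_linear, specific_growth_rate

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "DiauxicCall",
    "ShiftEstimate",
    "read_plate_table",
    "calibrate_od",
    "fit_growth_rate",
    "yield_max_od",
    "detect_diauxie",
    "estimate_shift",
]

#: plate-reader OD -> 1-cm-path spectrophotometer OD
DEFAULT_CALIBRATION = 2.2
#: minimum readouts per regression window
MIN_WINDOW_POINTS = 5


@dataclass
class GrowthCurve:
    """Calibrated OD time series for one well."""

    time_h: np.ndarray
    od: np.ndarray
    well: str = ""
    strain: str = ""
    calibration_factor: float = 1.0

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if len(self.time_h) != len(self.od) or len(self.od) < 2:
            raise ParameterError("curve needs >= 2 matching (time, od) points")
        if np.any(np.diff(self.time_h) <= 0):
            raise ParameterError("time must be strictly increasing")
        if np.any(self.od <= 0):
            raise ParameterError("OD values must be strictly positive")

    def calibrate(self, factor: float = DEFAULT_CALIBRATION) -> "GrowthCurve":
        """Return a copy with OD multiplied by ``factor`` (recorded)."""
        return replace(self, od=calibrate_od(self.od, factor),
                       calibration_factor=self.calibration_factor * factor)


@dataclass(frozen=True)
class GrowthFit:
    """OLS fit of ln(OD) on time over one OD window."""

    mu: float
    intercept: float
    se_mu: float
    r2: float
    n_points: int
    od_window: tuple[float, float]
    index_range: tuple[int, int]  # [start, stop) into the curve


@dataclass(frozen=True)
class DiauxicCall:
    slope_primary: float
    slope_extended: float
    p_value: float
    is_diauxic: bool
    alpha: float
    fit_primary: GrowthFit
    fit_extended: GrowthFit
    quality_flag: str | None = None


@dataclass(frozen=True)
class ShiftEstimate:
    duration_h: float
    t_start: float
    t_end: float
    threshold_mu: float


def calibrate_od(raw, factor: float = DEFAULT_CALIBRATION) -> np.ndarray:
    """Scale raw plate-reader OD readouts by a calibration factor."""
    if factor <= 0:
        raise ParameterError("calibration factor must be positive")
    return np.asarray(raw, dtype=float) * factor


def read_plate_table(path, well_map=None, calibrate: bool = False,
                     factor: float = DEFAULT_CALIBRATION
                     ) -> dict[str, GrowthCurve]:
    """Read a long-format plate CSV into one GrowthCurve per mapped well.

    With ``calibrate=True`` the plate-reader calibration factor is
    applied on read.  If a well map is supplied, every well in the file
    must appear in it (strain labels are taken from the map).
    """
    df, wmap = _io.read_plate_long(path, well_map)
    wells = (list(wmap) if wmap is not None
             else list(dict.fromkeys(df["well"])))
    curves: dict[str, GrowthCurve] = {}
    for well in wells:
        if wmap is not None and well not in set(df["well"]):
            continue
        t, od = _io.well_series(df, well, "OD")
        strain = ""
        if wmap is not None:
            meta = wmap.get(well) or {}
            strain = meta.get("strain", "") if isinstance(meta, dict) else ""
        curve = GrowthCurve(t, od, well=well, strain=strain)
        curves[well] = curve.calibrate(factor) if calibrate else curve
    return curves


def _first_contiguous_window(od: np.ndarray, od_lo: float, od_hi: float,
                             min_points: int = 1) -> tuple[int, int]:
    """[start, stop) of the first contiguous run with od in [od_lo, od_hi]
    holding at least ``min_points`` readouts.

    Stray shorter runs (a single noisy readout dipping into the window
    before the real crossing) are skipped; if no run is long enough the
    longest one is reported in the error.
    """
    inside = (od >= od_lo) & (od <= od_hi)
    if not inside.any():
        raise WindowError(
            f"no points with OD in [{od_lo}, {od_hi}] "
            f"(curve spans {od.min():.4g}-{od.max():.4g})")
    best = 0
    i, n = 0, len(od)
    while i < n:
        if not inside[i]:
            i += 1
            continue
        j = i
        while j < n and inside[j]:
            j += 1
        if j - i >= min_points:
            return i, j
        best = max(best, j - i)
        i = j
    raise WindowError(
        f"window OD [{od_lo}, {od_hi}] holds {best} contiguous points; "
        f"need >= {min_points}")


def fit_growth_rate(curve: GrowthCurve, od_lo: float = 0.05,
                    od_hi: float = 0.35,
                    min_points: int = MIN_WINDOW_POINTS) -> GrowthFit:
    """Exponential growth rate over the first contiguous OD window.

    OLS of ln(OD) on time restricted to the first contiguous run of
    readouts with calibrated OD inside ``[od_lo, od_hi]`` (inclusive;
    no interpolation to the exact bounds).
    """
    if od_lo <= 0 or od_hi <= od_lo:
        raise ParameterError("need 0 < od_lo < od_hi")
    start, stop = _first_contiguous_window(curve.od, od_lo, od_hi,
                                           min_points)
    n = stop - start
    t = curve.time_h[start:stop]
    y = np.log(curve.od[start:stop])
    res = sps.linregress(t, y)
    return GrowthFit(mu=float(res.slope), intercept=float(res.intercept),
                     se_mu=float(res.stderr), r2=float(res.rvalue ** 2),
                     n_points=n, od_window=(od_lo, od_hi),
                     index_range=(start, stop))


def yield_max_od(curve: GrowthCurve, smooth_window: int = 5) -> float:
    """Growth yield as the maximum of the locally smoothed OD trace.

    Local-linear smoothing over ``smooth_window`` readouts suppresses
    single-readout spikes before taking the maximum.
    """
    if len(curve.od) < smooth_window:
        return float(np.max(curve.od))
    smoothed = local_linear(curve.time_h, curve.od, window=smooth_window)
    return float(np.max(smoothed))


def detect_diauxie(curve: GrowthCurve, alpha: float = 0.05,
                   od_lo: float = 0.05, od_hi: float = 0.35,
                   extended_frac: float = 0.9,
                   min_points: int = MIN_WINDOW_POINTS) -> DiauxicCall:
    """Two-slope diauxic-growth test.

    Fits the primary exponential window (OD ``od_lo``-``od_hi``) and an
    extended window (OD ``od_lo`` to ``extended_frac`` x max OD)
    independently, then applies a one-sided Welch t test for the
    extended slope being lower than the primary one.  A second, slower
    growth phase inside the extended window lowers its slope; a
    single-phase curve gives statistically indistinguishable slopes.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    fit1 = fit_growth_rate(curve, od_lo, od_hi, min_points)
    max_od = yield_max_od(curve)
    hi_ext = extended_frac * max_od
    if hi_ext <= od_lo:
        raise WindowError("extended window collapses: max OD too low")
    fit2 = fit_growth_rate(curve, od_lo, hi_ext, min_points)

    diff = fit1.mu - fit2.mu
    se = math.hypot(fit1.se_mu, fit2.se_mu)
    if se == 0.0:
        p = 1.0 if abs(diff) <= 1e-12 else (0.0 if diff > 0 else 1.0)
        p_hi = 0.0 if diff < -1e-12 else 1.0
    else:
        tstat = diff / se
        df1, df2 = fit1.n_points - 2, fit2.n_points - 2
        num = (fit1.se_mu ** 2 + fit2.se_mu ** 2) ** 2
        den = (fit1.se_mu ** 4 / df1 if df1 > 0 else math.inf) + \
              (fit2.se_mu ** 4 / df2 if df2 > 0 else math.inf)
        dof = num / den if den > 0 else df1 + df2
        p = float(sps.t.sf(tstat, dof))          # H1: extended < primary
        p_hi = float(sps.t.sf(-tstat, dof))      # extended > primary
    flag = "extended_slope_higher" if p_hi <= alpha else None
    is_diauxic = (p <= alpha) and (fit2.mu < fit1.mu)
    return DiauxicCall(slope_primary=fit1.mu, slope_extended=fit2.mu,
                       p_value=p, is_diauxic=is_diauxic, alpha=alpha,
                       fit_primary=fit1, fit_extended=fit2,
                       quality_flag=flag)


def _cross_time(t: np.ndarray, y: np.ndarray, i: int, thr: float) -> float:
    """Linear interpolation of the crossing of ``thr`` between i-1 and i."""
    if y[i] == y[i - 1]:
        return float(t[i])
    w = (thr - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + w * (t[i] - t[i - 1]))


def _line_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = sps.linregress(t, y)
    return float(res.slope), float(res.intercept)


def _find_arrest(rate: np.ndarray, start: int, thr: float) -> int | None:
    """First debounced downcross: rate below ``thr`` for two readouts."""
    for i in range(max(start, 1), len(rate)):
        if rate[i] < thr <= rate[i - 1]:
            if i + 1 >= len(rate) or rate[i + 1] < thr:
                return i
    return None


def estimate_shift(curve: GrowthCurve, call: DiauxicCall | None = None,
                   mu_threshold: float = 0.1,
                   smooth_window: int = 5,
                   rise_margin: float = 0.05) -> ShiftEstimate:
    """Diauxic-shift duration: the growth-arrest interval between phases.

    The smoothed specific growth rate d(ln OD)/dt is scanned after the
    primary exponential window for its first sustained fall below
    ``mu_threshold`` (growth arrest).  The arrest-plateau ln(OD) level
    is then averaged, resumption is located where the smoothed ln(OD)
    climbs ``rise_margin`` above that plateau, and the two boundary
    times are refined as the intersections of the glucose- and
    acetate-phase exponential regression lines with the plateau level
    (threshold crossings of the noisy derivative only localize the
    arrest; the level-based refinement is what is reported).

    Requires an upstream diauxic classification; raises
    :class:`ShiftUnresolvedError` when growth never recovers (the
    culture entered stationary phase instead of a second phase).
    """
    if call is not None and not call.is_diauxic:
        raise ParameterError("curve was classified single-phase; "
                             "no diauxic shift to estimate")
    if mu_threshold <= 0:
        raise ParameterError("mu_threshold must be positive")
    t = curve.time_h
    lnod = np.log(curve.od)
    rate = specific_growth_rate(t, curve.od, window=smooth_window)
    sm = local_linear(t, lnod, window=smooth_window)

    if call is not None:
        search_from = call.fit_primary.index_range[1]
    else:
        search_from = int(np.argmax(rate))
    down = _find_arrest(rate, search_from, mu_threshold)
    if down is None and smooth_window > 3:
        # a short lag can be blurred away by the full window; retry sharper
        rate = specific_growth_rate(t, curve.od, window=3)
        down = _find_arrest(rate, search_from, mu_threshold)
    if down is None:
        raise ShiftUnresolvedError("growth rate never fell below threshold")
    t_down = _cross_time(t, rate, down, mu_threshold)

    # arrest-plateau level: run of readouts whose smoothed ln OD stays near
    # the level right after the arrest (fixed reference; no drifting mean)
    ln_p0 = float(np.median(sm[down:min(down + 3, len(t))]))
    plateau_end = down
    for j in range(down, len(t)):
        if sm[j] > ln_p0 + max(rise_margin * 0.8, 0.04) or sm[j] < ln_p0 - 0.08:
            break
        plateau_end = j
    # the trailing readouts of the run may already sit on the resumption
    # ramp (smoothing lag); trim them before averaging the raw level
    core_end = max(down, plateau_end - 2)
    ln_p = float(lnod[down:core_end + 1].mean())

    after = np.arange(down + 1, len(t))
    risen = after[sm[after] >= ln_p + rise_margin]
    if len(risen) == 0:
        raise ShiftUnresolvedError(
            "ln OD never rose above the arrest plateau; no second phase")
    # final-plateau level: average the raw readouts sitting near the top of
    # the smoothed trace (a plain max would be biased high by noise)
    sm_top = float(np.max(sm[after]))
    top = after[sm[after] >= sm_top - 0.02]
    ln_f = float(lnod[top].mean())
    rise = ln_f - ln_p

    # glucose-phase line: readouts on the approach to the plateau
    pre = np.arange(0, down + 1)
    pre = pre[(sm[pre] <= ln_p - rise_margin)
              & (sm[pre] >= ln_p - 0.8) & (t[pre] <= t_down)]
    t_start = t_down
    if len(pre) >= 3:
        m1, b1 = _line_fit(t[pre], lnod[pre])
        if m1 > 0:
            t_start = (ln_p - b1) / m1

    # resumption boundary: fit plateau -> exponential ramp -> plateau to
    # every readout after the arrest (no hard point selection, so single
    # noisy readouts cannot derail the fit); the free parameters are the
    # resumption time and the second-phase rate
    i_up = int(risen[0])
    t_up = float(t[i_up])
    seg = np.arange(down, len(t))
    tt, yy = t[seg], lnod[seg]
    t_end = t_up
    if len(seg) >= 4 and rise > 0:
        def resid(theta):
            t_end_c, m, rise_c = theta
            return ln_p + np.clip(m * (tt - t_end_c), 0.0, rise_c) - yy

        # resumption means growth at or above the detection threshold, so
        # the rate is bounded below by it; multi-start guards against the
        # flat change-point likelihood
        best = None
        for m0 in (mu_threshold, 0.2, 0.4):
            sol = least_squares(
                resid,
                x0=(max(t_up - rise_margin / m0, float(t[down]) - 0.4),
                    m0, rise),
                bounds=((float(t[down]) - 0.6, mu_threshold, 0.7 * rise),
                        (float(t[-1]), 20.0, 1.3 * rise)))
            sse = float(sol.fun @ sol.fun)
            if best is None or sse < best[0]:
                best = (sse, float(sol.x[0]))
        cand = best[1]
        if t_down - 0.6 <= cand <= t_up + 0.5:
            t_end = cand

    if t_end < t_start:  # pathological noise: fall back to coarse bounds
        t_start, t_end = t_down, t_up
    return ShiftEstimate(duration_h=t_end - t_start, t_start=t_start,
                         t_end=t_end, threshold_mu=mu_threshold)
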