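"""Substrate yields and specific uptake/secretion rates.

The yield of a compound is the OLS slope of its extracellular
concentration against biomass (OD) over an exponential-phase window
with at least five points; the specific rate is |yield| x growth rate,
with the slope sign deciding the role: concentration falling as biomass
rises means uptake, rising means secretion.  A co-utilization call
requires simultaneous uptake of glucose and acetate above a minimum
rate on the same glucose-present window.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, ParameterError, WindowError

__all__ = [
    "SubstrateSeries",
    "YieldEstimate",
    "RateEstimate",
    "CometabolismCall",
    "substrate_yield",
    "specific_rate",
    "classify_cometabolism",
]

MIN_REGRESSION_POINTS = 5


@dataclass
class SubstrateSeries:
    """Concentration and biomass time courses for one culture."""

    time_h: np.ndarray
    od: np.ndarray
    concentrations: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if np.any(np.diff(self.time_h) <= 0):
            raise ParameterError("time must be strictly increasing")
        conc = {}
        for name, c in self.concentrations.items():
            c = np.asarray(c, dtype=float)
            if len(c) != len(self.time_h):
                raise ParameterError(
                    f"compound {name!r} length mismatches the time grid")
            if np.any(c < -1e-9):
                raise ParameterError(f"compound {name!r} has negative values")
            conc[name] = c
        self.concentrations = conc


@dataclass(frozen=True)
class YieldEstimate:
    """Signed slope of concentration vs biomass, g/l per OD unit."""

    compound: str
    slope: float
    se: float
    n_points: int
    window: tuple[float, float]
    r2: float


@dataclass(frozen=True)
class RateEstimate:
    """Specific rate |yield| x mu with the role carried separately."""

    compound: str
    yield_slope: float
    specific_rate: float
    role: str  # "uptake" | "secretion"
    se: float
    n_points: int
    window: tuple[float, float]


@dataclass(frozen=True)
class CometabolismCall:
    verdict: str  # "co-utilization" | "no-co-utilization" | "indeterminate"
    glucose: RateEstimate
    acetate: RateEstimate
    min_rate: float


def substrate_yield(series: SubstrateSeries, compound: str,
                    window: tuple[float, float],
                    min_points: int = MIN_REGRESSION_POINTS) -> YieldEstimate:
    """Yield by linear regression of concentration against biomass.

    ``window`` is the exponential-phase time range (hours, inclusive)
    over which the regression runs; at least five points are required.
    """
    if compound not in series.concentrations:
        raise ParameterError(f"no concentration trace for {compound!r}")
    t0, t1 = window
    mask = (series.time_h >= t0) & (series.time_h <= t1)
    n = int(mask.sum())
    if n < min_points:
        raise WindowError(
            f"window [{t0}, {t1}] h holds {n} points; need >= {min_points}")
    od = series.od[mask]
    conc = series.concentrations[compound][mask]
    if np.ptp(od) == 0:
        raise DegenerateDataError("OD has zero variance inside the window")
    res = sps.linregress(od, conc)
    return YieldEstimate(compound=compound, slope=float(res.slope),
                         se=float(res.stderr), n_points=n,
                         window=(float(t0), float(t1)),
                         r2=float(res.rvalue ** 2))


def specific_rate(yld: YieldEstimate | float, mu: float,
                  se_mu: float = 0.0,
                  compound: str = "") -> RateEstimate:
    """Specific rate = |yield| x growth rate; role from the yield sign.

    The standard error combines both inputs to first order:
    se^2 = (mu * se_yield)^2 + (yield * se_mu)^2.
    """
    if mu < 0:
        raise ParameterError("growth rate must be nonnegative")
    if isinstance(yld, YieldEstimate):
        slope, se_y, n, window = yld.slope, yld.se, yld.n_points, yld.window
        compound = compound or yld.compound
    else:
        slope, se_y, n, window = float(yld), 0.0, 0, (math.nan, math.nan)
    role = "uptake" if slope < 0 else "secretion"
    rate = abs(slope) * mu
    se = math.hypot(mu * se_y, slope * se_mu)
    return RateEstimate(compound=compound, yield_slope=slope,
                        specific_rate=rate, role=role, se=se,
                        n_points=n, window=window)


def classify_cometabolism(glc: RateEstimate, ace: RateEstimate,
                          min_rate: float = 0.01) -> CometabolismCall:
    """Co-utilization call from paired glucose and acetate rate estimates.

    Co-utilizer iff both compounds are taken up at >= ``min_rate`` on
    the same glucose-present window; both rates below the threshold is
    indeterminate.
    """
    if (not any(math.isnan(v) for v in (*glc.window, *ace.window))
            and glc.window != ace.window):
        raise ParameterError(
            f"rate estimates use different windows: "
            f"{glc.window} vs {ace.window}")
    both_small = (glc.specific_rate < min_rate
                  and ace.specific_rate < min_rate)
    if both_small:
        verdict = "indeterminate"
    elif (glc.role == "uptake" and ace.role == "uptake"
          and glc.specific_rate >= min_rate
          and ace.specific_rate >= min_rate):
        verdict = "co-utilization"
    else:
        verdict = "no-co-utilization"
    return CometabolismCall(verdict=verdict, glucose=glc, acetate=ace,
                            min_rate=min_rate)
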