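"""Promoter-reporter dynamics: GFP/OD, dGFP/dt/OD and derived statistics.

Transcriptional activity is the pointwise ratio GFP/OD (a per-cell
expression proxy); promoter activity is the time derivative of GFP
divided by OD (a synthesis-rate proxy).  Exponential-phase expression
is summarized by averaging either activity over the growth window
OD 0.1-0.3 per replicate, then combining replicates into a mean with a
t-based 95% confidence interval.  The CRP-activity statistic is the
ratio of the CRP-binding-site hybrid-promoter (epd-CBS) transcription
to that of the constitutive epd promoter measured in the same
condition.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy import stats as sps

from . import io as _io
from .errors import ParameterError, WindowError
from .smoothing import local_linear

__all__ = [
    "ReporterCurve",
    "ActivityTrajectory",
    "ExpressionSummary",
    "CrpActivity",
    "read_reporter_table",
    "transcriptional_activity",
    "promoter_activity",
    "summarize_window",
    "crp_activity",
    "percent_change",
    "round_half_away",
]

DEFAULT_OD_FLOOR = 0.02


@dataclass
class ReporterCurve:
    """Paired OD and GFP time series for one reporter well."""

    time_h: np.ndarray
    od: np.ndarray
    gfp: np.ndarray
    well: str = ""
    strain: str = ""
    promoter: str = ""

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        if not (len(self.time_h) == len(self.od) == len(self.gfp)):
            raise ParameterError("time, od and gfp must have equal lengths")
        if len(self.time_h) < 2:
            raise ParameterError("need >= 2 readouts")
        if np.any(np.diff(self.time_h) <= 0):
            raise ParameterError("time must be strictly increasing")


@dataclass
class ActivityTrajectory:
    """Time-resolved activity trace (one component filled per operation)."""

    time_h: np.ndarray
    od: np.ndarray
    transcriptional: np.ndarray | None = None
    promoter: np.ndarray | None = None
    n_dropped: int = 0

    def component(self, name: str) -> np.ndarray:
        vals = getattr(self, name)
        if vals is None:
            raise ParameterError(f"trajectory has no {name!r} component")
        return vals


@dataclass(frozen=True)
class ExpressionSummary:
    """Across-replicate mean and 95% CI of windowed activity."""

    mean: float
    ci95: float
    n_runs: int
    window: tuple[float, float]
    per_replicate: tuple[float, ...] = ()


@dataclass(frozen=True)
class CrpActivity:
    value: float
    ci95: float
    numerator: ExpressionSummary
    denominator: ExpressionSummary


def read_reporter_table(path, well_map=None) -> dict[str, ReporterCurve]:
    """Read wells carrying both OD and GFP channels from a plate CSV."""
    df, wmap = _io.read_plate_long(path, well_map)
    curves: dict[str, ReporterCurve] = {}
    for well in dict.fromkeys(df["well"]):
        t, od = _io.well_series(df, well, "OD")
        tg, gfp = _io.well_series(df, well, "GFP")
        if len(tg) != len(t) or np.any(tg != t):
            raise ParameterError(
                f"well {well!r}: OD and GFP grids do not match")
        strain = promoter = ""
        if wmap is not None and isinstance(wmap.get(well), dict):
            strain = wmap[well].get("strain", "")
            promoter = wmap[well].get("reporter", "")
        curves[well] = ReporterCurve(t, od, gfp, well=well,
                                     strain=strain, promoter=promoter)
    return curves


def transcriptional_activity(rc: ReporterCurve,
                             od_floor: float = DEFAULT_OD_FLOOR
                             ) -> ActivityTrajectory:
    """Pointwise GFP/OD, dropping readouts below the OD floor.

    Below ``od_floor`` the quotient is dominated by readout noise; such
    points are removed and counted in ``n_dropped``.
    """
    keep = rc.od >= od_floor
    if not keep.any():
        raise WindowError(f"all readouts below the OD floor {od_floor}")
    return ActivityTrajectory(
        time_h=rc.time_h[keep], od=rc.od[keep],
        transcriptional=rc.gfp[keep] / rc.od[keep],
        n_dropped=int((~keep).sum()))


def promoter_activity(rc: ReporterCurve, smooth_window: int = 5,
                      od_floor: float = DEFAULT_OD_FLOOR
                      ) -> ActivityTrajectory:
    """dGFP/dt estimated by local-linear regression, divided by OD.

    The derivative is taken on interior points where the full centered
    ``smooth_window`` fits; readouts below the OD floor are dropped.
    """
    n = len(rc.time_h)
    if smooth_window > n:
        raise WindowError(
            f"smoothing window {smooth_window} exceeds series length {n}")
    dgfp = local_linear(rc.time_h, rc.gfp, window=smooth_window, deriv=True)
    half = smooth_window // 2
    interior = np.zeros(n, dtype=bool)
    interior[half:n - half] = True
    keep = interior & (rc.od >= od_floor)
    if not keep.any():
        raise WindowError("no interior readouts above the OD floor")
    return ActivityTrajectory(
        time_h=rc.time_h[keep], od=rc.od[keep],
        promoter=dgfp[keep] / rc.od[keep],
        n_dropped=int((interior & ~keep).sum()))


def _window_mean(traj: ActivityTrajectory, component: str,
                 od_lo: float, od_hi: float, label: str) -> float:
    vals = traj.component(component)
    inside = (traj.od >= od_lo) & (traj.od <= od_hi)
    if not inside.any():
        raise WindowError(
            f"replicate {label}: no points with OD in [{od_lo}, {od_hi}]")
    start = int(np.argmax(inside))
    stop = start
    while stop < len(vals) and inside[stop]:
        stop += 1
    return float(vals[start:stop].mean())


def summarize_window(replicates, od_lo: float = 0.1, od_hi: float = 0.3,
                     component: str = "transcriptional") -> ExpressionSummary:
    """Exponential-phase expression summary across replicate trajectories.

    Each replicate is averaged over the first contiguous run of points
    with OD in ``[od_lo, od_hi]``; replicate means are combined into an
    across-replicate mean with a t-based 95% CI half-width (zero for a
    single replicate).
    """
    trajs = list(replicates)
    if not trajs:
        raise ParameterError("need at least one replicate trajectory")
    means = [
        _window_mean(tr, component, od_lo, od_hi, str(i + 1))
        for i, tr in enumerate(trajs)
    ]
    n = len(means)
    mean = float(np.mean(means))
    if n == 1:
        ci = 0.0
    else:
        sd = float(np.std(means, ddof=1))
        ci = float(sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
    return ExpressionSummary(mean=mean, ci95=ci, n_runs=n,
                             window=(od_lo, od_hi),
                             per_replicate=tuple(means))


def crp_activity(num: ExpressionSummary,
                 den: ExpressionSummary) -> CrpActivity:
    """CRP activity: epd-CBS hybrid-promoter transcription over epd.

    The 95% CI half-width is propagated to first order from the two
    summaries' half-widths (relative errors added in quadrature).
    """
    if den.mean <= 0:
        raise ParameterError("denominator (epd) mean must be positive")
    value = num.mean / den.mean
    rel = math.hypot(num.ci95 / num.mean if num.mean else 0.0,
                     den.ci95 / den.mean)
    return CrpActivity(value=value, ci95=value * rel,
                       numerator=num, denominator=den)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed tables)."""
    scale = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def percent_change(test: ExpressionSummary | float,
                   reference: ExpressionSummary | float,
                   decimals: int | None = 0) -> float:
    """Signed percent change of ``test`` relative to ``reference``.

    By default rounded half-away-from-zero to the nearest integer (the
    formatting of printed results); pass ``decimals=None`` for the raw
    value.
    """
    tv = test.mean if isinstance(test, ExpressionSummary) else float(test)
    rv = (reference.mean if isinstance(reference, ExpressionSummary)
          else float(reference))
    if rv <= 0:
        raise ParameterError("reference mean must be positive")
    pct = 100.0 * (tv - rv) / rv
    return pct if decimals is None else round_half_away(pct, decimals)
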