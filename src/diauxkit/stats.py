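"""Serial-passage accounting, competition trajectories and cohort statistics.

Covers the bookkeeping of serial-transfer evolution experiments
(doublings per passage, total generations), frequency trajectories from
flow-cytometry counts with Wilson binomial intervals, coexistence /
exclusion calls on competition trajectories, and the cohort statistics
used to compare evolved isolates: an exact one-sided Fisher test on a
2x2 diauxie contingency, one-way and nested ANOVA on growth-rate
cohorts, coefficients of variation, and Pearson/Spearman correlation.

The Fisher tail is evaluated exactly through log-factorials
(``gammaln``) rather than delegated, because the hypergeometric tail in
a stated direction is the quantity of interest; ``scipy`` serves as an
independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateDataError, ParameterError

__all__ = [
    "CompetitionTrajectory",
    "DiauxieContingency",
    "FisherResult",
    "AnovaResult",
    "NestedAnovaResult",
    "FrequencyFromCounts",
    "CoexistenceCall",
    "generations_per_passage",
    "total_generations",
    "frequency_from_counts",
    "coexistence_call",
    "fisher_exact_one_sided",
    "one_way_anova",
    "nested_anova",
    "coefficient_of_variation",
    "correlate",
]


# --------------------------------------------------------------------------
# domain containers

@dataclass
class CompetitionTrajectory:
    """Focal-genotype frequency over serial passages.

    ``counts`` holds (focal, total) cytometer counts per passage when
    counting was simulated/recorded, else None.  ``gens_per_passage``
    follows from the dilution factor: each passage the culture must
    regrow by the dilution factor, i.e. log2(dilution) doublings.
    """

    passages: np.ndarray
    focal_fraction: np.ndarray
    counts: np.ndarray | None
    dilution: float
    incomplete_regrowth: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.focal_fraction, dtype=float)
        if np.any(f < 0) or np.any(f > 1):
            raise ParameterError("fractions must lie in [0, 1]")
        self.focal_fraction = f

    @property
    def gens_per_passage(self) -> float:
        return generations_per_passage(self.dilution)


@dataclass(frozen=True)
class DiauxieContingency:
    """2x2 table of isolates with/without diauxic growth in two groups."""

    groups: tuple[str, str]
    with_diauxie: tuple[int, int]
    without_diauxie: tuple[int, int]

    def __post_init__(self) -> None:
        cells = [*self.with_diauxie, *self.without_diauxie]
        if any(c < 0 for c in cells):
            raise ParameterError("contingency counts must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.with_diauxie[0], self.without_diauxie[0]],
                         [self.with_diauxie[1], self.without_diauxie[1]]])


@dataclass(frozen=True)
class FisherResult:
    p_one_sided: float
    p_greater: float
    p_less: float
    p_two_sided: float
    direction: str
    degenerate: bool = False


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int


@dataclass(frozen=True)
class NestedAnovaResult:
    f: float
    p: float
    df_group: int
    df_isolate: int
    ms_group: float
    ms_isolate: float
    degenerate: bool = False


@dataclass(frozen=True)
class FrequencyFromCounts:
    fraction: float
    ci_low: float
    ci_high: float
    focal: int
    total: int
    low_counts: bool


@dataclass(frozen=True)
class CoexistenceCall:
    verdict: str          # "coexistence" | "exclusion" | "undecided"
    level: float | None   # tail-mean focal fraction for coexistence
    tail_range: float | None


# --------------------------------------------------------------------------
# generation accounting

def generations_per_passage(dilution: float) -> float:
    """Doublings needed to regrow a ``dilution``-fold diluted culture."""
    if dilution < 1:
        raise ParameterError("dilution must be >= 1")
    return math.log2(dilution)


def total_generations(n_passages: int, dilution: float) -> float:
    """Total doublings over ``n_passages`` serial transfers."""
    if n_passages < 0:
        raise ParameterError("n_passages must be >= 0")
    return n_passages * generations_per_passage(dilution)


# --------------------------------------------------------------------------
# frequencies and competition outcomes

def frequency_from_counts(focal: int, total: int,
                          min_total: int = 45000) -> FrequencyFromCounts:
    """Focal fraction with a 95% Wilson binomial interval.

    A quality flag is raised when fewer than ``min_total`` cells were
    counted (the cytometry protocol requires at least 45000).
    """
    if total <= 0:
        raise ParameterError("total count must be positive")
    if not 0 <= focal <= total:
        raise ParameterError("need 0 <= focal <= total")
    lo, hi = proportion_confint(focal, total, alpha=0.05, method="wilson")
    return FrequencyFromCounts(
        fraction=focal / total, ci_low=max(float(lo), 0.0),
        ci_high=min(float(hi), 1.0),
        focal=focal, total=total, low_counts=total < min_total)


def coexistence_call(traj: CompetitionTrajectory,
                     tail_passages: int = 3,
                     band: float = 0.10,
                     floor: float = 0.01) -> CoexistenceCall:
    """Classify a competition trajectory.

    Coexistence: every tail fraction lies inside [floor, 1-floor] and
    the tail spans no more than ``band`` (the trajectory has settled).
    Exclusion: the final fraction fell below ``floor`` (or above
    1-floor, symmetrically).  Anything else, or a trajectory shorter
    than ``tail_passages``, is undecided.
    """
    f = traj.focal_fraction
    if len(f) < tail_passages:
        return CoexistenceCall("undecided", None, None)
    tail = f[-tail_passages:]
    if f[-1] < floor or f[-1] > 1 - floor:
        return CoexistenceCall("exclusion", None, float(np.ptp(tail)))
    inside = np.all((tail >= floor) & (tail <= 1 - floor))
    settled = np.ptp(tail) <= band
    if inside and settled:
        return CoexistenceCall("coexistence", float(tail.mean()),
                               float(np.ptp(tail)))
    return CoexistenceCall("undecided", None, float(np.ptp(tail)))


# --------------------------------------------------------------------------
# exact Fisher test

def _log_hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    return (gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
            + gammaln(N - K + 1) - gammaln(n - k + 1)
            - gammaln(N - K - n + k + 1)
            - gammaln(N + 1) + gammaln(n + 1) + gammaln(N - n + 1))


def fisher_exact_one_sided(table) -> FisherResult:
    """Exact Fisher test on a 2x2 table, one-sided in the observed direction.

    With both margins fixed, the top-left cell follows a hypergeometric
    distribution; tail probabilities are accumulated from log-factorial
    point masses.  The reported one-sided p is the tail on the side of
    the observed deviation from the conditional expectation; both
    directed tails and a two-sided p (sum of point masses not exceeding
    the observed one) are exposed as well.
    """
    if isinstance(table, DiauxieContingency):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ParameterError("need a nonnegative 2x2 table")
    a = int(arr[0, 0])
    N = int(arr.sum())
    K = int(arr[0].sum())       # row-1 margin
    n = int(arr[:, 0].sum())    # column-1 margin
    if K == 0 or n == 0 or K == N or n == N:
        return FisherResult(1.0, 1.0, 1.0, 1.0, "degenerate", degenerate=True)

    k_lo, k_hi = max(0, K + n - N), min(K, n)
    ks = np.arange(k_lo, k_hi + 1)
    logp = np.array([_log_hypergeom_pmf(k, N, K, n) for k in ks])
    pmf = np.exp(logp)
    pmf /= pmf.sum()  # guard rounding; exact masses already sum to 1
    idx = a - k_lo
    p_greater = float(pmf[idx:].sum())
    p_less = float(pmf[:idx + 1].sum())
    expected = K * n / N
    direction = "greater" if a >= expected else "less"
    p_one = p_greater if direction == "greater" else p_less
    p_two = float(pmf[pmf <= pmf[idx] * (1 + 1e-12)].sum())
    return FisherResult(min(p_one, 1.0), min(p_greater, 1.0),
                        min(p_less, 1.0), min(p_two, 1.0), direction)


# --------------------------------------------------------------------------
# ANOVA

def one_way_anova(groups) -> AnovaResult:
    """Standard one-way fixed-effects ANOVA across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ParameterError("need >= 2 groups with >= 2 values each")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        raise DegenerateDataError("all values identical; no variance to test")
    f, p = sps.f_oneway(*groups)
    k = len(groups)
    return AnovaResult(float(f), float(p), k - 1, len(allv) - k)


def nested_anova(table: pd.DataFrame,
                 group_col: str = "population",
                 isolate_col: str = "isolate",
                 value_col: str = "value") -> NestedAnovaResult:
    """One-way nested ANOVA: isolates nested within groups.

    Tests the group (population) effect against the isolate-within-
    group mean square, the correct error stratum when replicate
    measurements of one isolate are pseudo-replicates of that isolate.
    Unbalanced designs are handled by sequential (Type-I) sums of
    squares with groups entered before isolates.
    """
    df = table[[group_col, isolate_col, value_col]].dropna()
    groups = df.groupby(group_col, sort=False)
    if groups.ngroups < 2:
        raise ParameterError("need >= 2 groups")
    for g, sub in groups:
        iso = sub.groupby(isolate_col, sort=False).size()
        if len(iso) < 2:
            raise ParameterError(f"group {g!r} has < 2 isolates")
        if (iso < 2).any():
            raise ParameterError(
                f"group {g!r} has isolates with < 2 replicates")
    y = df[value_col].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return NestedAnovaResult(math.nan, 1.0, groups.ngroups - 1, 0,
                                 0.0, 0.0, degenerate=True)
    grand = y.mean()
    ss_group = 0.0
    ss_isolate = 0.0
    n_isolates = 0
    for _, sub in groups:
        gv = sub[value_col].to_numpy(dtype=float)
        ss_group += len(gv) * (gv.mean() - grand) ** 2
        for _, isub in sub.groupby(isolate_col, sort=False):
            iv = isub[value_col].to_numpy(dtype=float)
            ss_isolate += len(iv) * (iv.mean() - gv.mean()) ** 2
            n_isolates += 1
    df_group = groups.ngroups - 1
    df_isolate = n_isolates - groups.ngroups
    if df_isolate <= 0:
        raise ParameterError("no isolate-level degrees of freedom")
    ms_group = ss_group / df_group
    ms_isolate = ss_isolate / df_isolate
    if ms_isolate == 0:
        return NestedAnovaResult(math.inf, 0.0, df_group, df_isolate,
                                 ms_group, ms_isolate, degenerate=True)
    f = ms_group / ms_isolate
    p = float(sps.f.sf(f, df_group, df_isolate))
    return NestedAnovaResult(float(f), p, df_group, df_isolate,
                             ms_group, ms_isolate)


# --------------------------------------------------------------------------
# simple cohort statistics

def coefficient_of_variation(values) -> float:
    """Sample coefficient of variation as a percentage: 100*sd/mean."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ParameterError("need >= 2 values")
    m = v.mean()
    if m <= 0:
        raise ParameterError("mean must be positive for a CV")
    return 100.0 * v.std(ddof=1) / m


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with its two-sided p-value.

    Pearson uses the standard t-approximation.  Spearman p-values are
    exact (full permutation enumeration over pairings) for n <= 8 and
    switch to the usual t-approximation for larger samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ParameterError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in an input")
    if method == "pearson":
        r = sps.pearsonr(x, y)
        return float(r.statistic), float(r.pvalue)
    if method == "spearman":
        rho = float(sps.spearmanr(x, y).statistic)
        if len(x) <= 8:
            res = sps.permutation_test(
                (x, y),
                lambda a, b: sps.spearmanr(a, b).statistic,
                permutation_type="pairings", n_resamples=math.inf,
                alternative="two-sided")
            return rho, float(res.pvalue)
        return rho, float(sps.spearmanr(x, y).pvalue)
    raise ParameterError(f"unknown correlation method {method!r}")
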