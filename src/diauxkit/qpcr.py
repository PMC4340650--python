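"""qPCR quantification: 2^ddCt relative expression and allele frequencies.

Relative expression follows the comparative-Ct method: for each
condition dCt = mean Ct(target) - mean Ct(reference gene), the
between-condition difference ddCt = dCt(control) - dCt(test), and the
fold change is 2^ddCt (100% amplification efficiency assumed).

Allele frequencies come from a mixture standard curve built from
defined genomic-DNA ratios amplified with an allele-specific primer.
Two log-linear conventions are available; the default places the
fraction (percent) linearly on log10(Ct) — frequency inversely related
to the logarithm of Ct — and the conventional dilution-series
alternative (Ct linear in log10 of template fraction) sits behind the
same ``form`` flag.  Zero-percent standards carry no template for the
allele-specific primer and are censored ("no amplification", NaN Ct);
censored points never enter curve fits.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, ParameterError

__all__ = [
    "QpcrSample",
    "FoldChange",
    "AlleleStandardCurve",
    "FrequencyEstimate",
    "delta_delta_ct",
    "fit_allele_standard_curve",
    "estimate_allele_frequency",
]


@dataclass
class QpcrSample:
    """Replicate Ct values for one (sample, gene) pair; NaN = censored."""

    sample: str
    gene: str
    ct: np.ndarray

    def __post_init__(self) -> None:
        self.ct = np.atleast_1d(np.asarray(self.ct, dtype=float))
        if len(self.ct) < 1:
            raise ParameterError("need at least one Ct replicate")
        finite = self.ct[np.isfinite(self.ct)]
        if np.any(finite <= 0):
            raise ParameterError("Ct values must be positive")

    @property
    def censored(self) -> bool:
        return bool(np.isnan(self.ct).any())

    @property
    def mean_ct(self) -> float:
        return float(self.ct.mean())


@dataclass(frozen=True)
class FoldChange:
    value: float            # 2^ddCt
    delta_delta_ct: float
    ci95: float             # half-width on the fold scale
    ci_low: float
    ci_high: float
    n_replicates: int


@dataclass(frozen=True)
class AlleleStandardCurve:
    points: tuple[tuple[float, float], ...]  # (known fraction %, mean Ct)
    slope: float
    intercept: float
    r2: float
    form: str
    #: OLS parameter covariance (intercept, slope) for CI propagation
    var_intercept: float = 0.0
    var_slope: float = 0.0
    cov_intercept_slope: float = 0.0

    def invert(self, ct: float) -> float:
        """Unclamped fraction (percent) implied by one Ct value."""
        if self.form == "fraction_on_log_ct":
            return self.intercept + self.slope * math.log10(ct)
        return 10.0 ** ((ct - self.intercept) / self.slope)

    def prediction_var(self, ct: float) -> float:
        """Variance of the inverted fraction due to curve-fit uncertainty."""
        u = math.log10(ct)
        var_line = (self.var_intercept + u * u * self.var_slope
                    + 2.0 * u * self.cov_intercept_slope)
        if self.form == "fraction_on_log_ct":
            return var_line
        # ct_on_log_fraction: f = 10**((ct - a)/b); delta method
        f = self.invert(ct)
        dfd_a = -f * math.log(10.0) / self.slope
        dfd_b = -f * math.log(10.0) * (ct - self.intercept) / self.slope ** 2
        return (dfd_a ** 2 * self.var_intercept
                + dfd_b ** 2 * self.var_slope
                + 2.0 * dfd_a * dfd_b * self.cov_intercept_slope)


@dataclass(frozen=True)
class FrequencyEstimate:
    fraction: float   # percent in [0, 100]
    ci95: float
    clamped: bool
    censored: bool
    n_replicates: int


def _paired_replicates(*samples: QpcrSample) -> int:
    ns = {len(s.ct) for s in samples}
    if len(ns) != 1:
        raise ParameterError(
            "replicate counts differ across samples; ddCt replicates are "
            "paired by index and need equal counts")
    return ns.pop()


def delta_delta_ct(target_test: QpcrSample, ref_test: QpcrSample,
                   target_ctrl: QpcrSample, ref_ctrl: QpcrSample
                   ) -> FoldChange:
    """Relative expression of the test condition vs the control, 2^ddCt.

    dCt is formed per condition from mean Ct(target) - mean Ct(ref);
    ddCt = dCt(control) - dCt(test).  The CI comes from the spread of
    per-replicate ddCt values (replicates paired by index) propagated
    onto the fold scale.
    """
    for s in (target_test, ref_test, target_ctrl, ref_ctrl):
        if s.censored:
            raise ParameterError(
                f"sample {s.sample!r}/{s.gene!r} has censored Ct values")
    if target_test.gene != target_ctrl.gene:
        raise ParameterError("target gene labels differ between conditions")
    if ref_test.gene != ref_ctrl.gene:
        raise ParameterError("reference gene labels differ between conditions")

    ddct = ((target_ctrl.mean_ct - ref_ctrl.mean_ct)
            - (target_test.mean_ct - ref_test.mean_ct))
    n = _paired_replicates(target_test, ref_test, target_ctrl, ref_ctrl)
    per_rep = ((target_ctrl.ct - ref_ctrl.ct)
               - (target_test.ct - ref_test.ct))
    if n > 1:
        sd = float(np.std(per_rep, ddof=1))
        half = float(sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
    else:
        half = 0.0
    value = 2.0 ** ddct
    lo, hi = 2.0 ** (ddct - half), 2.0 ** (ddct + half)
    return FoldChange(value=value, delta_delta_ct=float(ddct),
                      ci95=(hi - lo) / 2.0, ci_low=lo, ci_high=hi,
                      n_replicates=n)


def fit_allele_standard_curve(mixtures,
                              form: str = "fraction_on_log_ct"
                              ) -> AlleleStandardCurve:
    """Fit the allele-frequency standard curve from defined mixtures.

    ``mixtures`` is a sequence of (fraction_percent, ct_replicates)
    pairs, e.g. the protocol ratios 0, 5, 10, 20, 40, 60, 100%.
    Zero-percent and fully censored points are excluded (no template
    for the allele-specific primer).  At least three usable points over
    two distinct fractions are required, and the fitted relation must
    be decreasing (frequency falls as Ct rises).
    """
    if form not in ("fraction_on_log_ct", "ct_on_log_fraction"):
        raise ParameterError(f"unknown standard-curve form {form!r}")
    fractions, mean_cts = [], []
    for frac, cts in mixtures:
        cts = np.atleast_1d(np.asarray(cts, dtype=float))
        usable = cts[np.isfinite(cts)]
        if frac == 0.0 or len(usable) == 0:
            continue  # censored: below the allele-specific detection limit
        if frac < 0 or frac > 100:
            raise ParameterError("fractions are percentages in [0, 100]")
        fractions.append(float(frac))
        mean_cts.append(float(usable.mean()))
    if len(fractions) < 3:
        raise ParameterError(
            f"only {len(fractions)} usable mixture points; need >= 3")
    fractions = np.asarray(fractions)
    mean_cts = np.asarray(mean_cts)
    if len(np.unique(fractions)) < 2:
        raise ParameterError("mixtures span fewer than 2 distinct fractions")
    if np.ptp(mean_cts) == 0:
        raise DegenerateDataError(
            "identical mean Ct across distinct fractions; slope degenerate")

    if form == "fraction_on_log_ct":
        x, y = np.log10(mean_cts), fractions
    else:
        x, y = np.log10(fractions), mean_cts
    res = sps.linregress(x, y)
    if res.slope >= 0:
        raise DegenerateDataError(
            "fitted slope is nonnegative; frequency must fall as Ct rises")
    n = len(x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    resid = y - (res.intercept + res.slope * x)
    s2 = float(resid @ resid) / (n - 2) if n > 2 else 0.0
    return AlleleStandardCurve(
        points=tuple(zip(fractions.tolist(), mean_cts.tolist())),
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue ** 2), form=form,
        var_intercept=s2 * (1.0 / n + x.mean() ** 2 / sxx),
        var_slope=s2 / sxx,
        cov_intercept_slope=-s2 * float(x.mean()) / sxx)


def estimate_allele_frequency(curve: AlleleStandardCurve,
                              cts) -> FrequencyEstimate:
    """Invert the standard curve at measured Ct replicates.

    Per-replicate Ct values are inverted individually; their mean is
    the point estimate (clamped into [0, 100] with a flag when the raw
    inversion fell outside).  The 95% CI combines the replicate spread
    with the standard curve's own fit uncertainty propagated through
    the inversion.  A fully censored measurement ("no amplification")
    returns frequency 0 with the censored flag set.
    """
    cts = np.atleast_1d(np.asarray(cts, dtype=float))
    usable = cts[np.isfinite(cts)]
    if len(usable) == 0:
        return FrequencyEstimate(fraction=0.0, ci95=0.0, clamped=False,
                                 censored=True, n_replicates=0)
    if np.any(usable <= 0):
        raise ParameterError("Ct values must be positive")
    per_rep = np.array([curve.invert(ct) for ct in usable])
    raw = float(per_rep.mean())
    n = len(per_rep)
    var_curve = curve.prediction_var(float(usable.mean()))
    if n > 1:
        var_rep = float(np.var(per_rep, ddof=1)) / n
        half = float(sps.t.ppf(0.975, n - 1)
                     * math.sqrt(var_rep + var_curve))
    else:
        half = float(1.96 * math.sqrt(var_curve))
    clamped = raw < 0.0 or raw > 100.0
    return FrequencyEstimate(fraction=min(max(raw, 0.0), 100.0),
                             ci95=half, clamped=clamped, censored=False,
                             n_replicates=n)
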