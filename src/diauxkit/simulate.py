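"""Synthetic batch-culture generator with known ground truth.

Emulates the data-generating process of a glucose-fed *E. coli* batch
culture followed on a microplate reader: a diauxic genotype grows
exponentially on glucose while secreting acetate, arrests for a
diauxic-shift lag once glucose is exhausted, then resumes growth on the
accumulated acetate; a co-utilizing genotype (a *ptsG*-mutant-like
phenotype) consumes glucose and acetate simultaneously in a single
phase with essentially no acetate secretion.  A GFP promoter reporter
is integrated alongside biomass with a phase-dependent synthesis rate
(low during glucose exponential growth, surging at the shift).

The generator also provides serial-passage competitions between
genotypes sharing the same substrate pools (so acetate secreted by one
is available to the other) and qPCR cycle-threshold values for
allele-frequency mixture standards.

Dynamics are integrated with a fixed 1-min internal step using exact
exponential growth factors per step, then down-sampled to the 10-min
readout grid, so each growth phase is exactly exponential in the
noise-free limit.  All randomness flows from one integer master seed
via ``numpy.random.SeedSequence`` spawning, and zero-noise output is
bit-identical regardless of seed.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError
from .stats import CompetitionTrajectory

__all__ = [
    "GenotypeParams",
    "ReporterParams",
    "NoiseModel",
    "BatchSimResult",
    "simulate_batch",
    "fast_secretor",
    "slow_coutilizer",
    "coutilization_revertant",
    "simulate_serial_passages",
    "simulate_qpcr",
    "write_plate_csv",
    "spawn_seeds",
]

#: glucose (or acetate) is declared exhausted below this concentration, g/l.
EXHAUSTION_EPS = 1e-6


def spawn_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Spawn ``n`` independent child seed sequences from one master seed."""
    return np.random.SeedSequence(master_seed).spawn(n)


@dataclass(frozen=True)
class GenotypeParams:
    """Physiological parameters of one genotype.

    Defaults describe a ZED-like ancestor (glycolysis-only *E. coli*):
    glucose growth rate 0.56 h^-1 and a 3.47 h diauxic shift, with
    biomass yields and overflow acetate secretion typical of aerobic
    glucose batch culture.

    Attributes
    ----------
    mu_glc : float
        Specific growth rate on glucose, h^-1.
    mu_ace : float
        Specific growth rate on acetate (post-shift phase), h^-1.
    lag_h : float
        Diauxic-shift duration (growth arrest after glucose runs out), h.
    y_x_glc : float
        Biomass yield on glucose: OD units produced per g/l consumed.
    q_ace_sec : float
        Overflow acetate secretion: g/l acetate per OD unit of biomass
        produced during the glucose phase.
    y_x_ace : float
        Biomass yield on acetate: OD units per g/l consumed.
    coutilizer : bool
        Single-phase mode consuming glucose and acetate simultaneously
        (forces ``lag_h = 0`` and ``q_ace_sec = 0``).
    mu_co : float
        Growth rate in co-utilization mode, h^-1.
    """

    mu_glc: float = 0.56
    mu_ace: float = 0.17
    lag_h: float = 3.47
    y_x_glc: float = 0.45
    q_ace_sec: float = 0.70
    y_x_ace: float = 0.30
    coutilizer: bool = False
    mu_co: float = 0.35

    def __post_init__(self) -> None:
        for name in ("mu_glc", "mu_ace", "lag_h", "y_x_glc",
                     "q_ace_sec", "y_x_ace", "mu_co"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if self.coutilizer:
            # co-utilizers show a single growth phase with minimal secretion
            object.__setattr__(self, "lag_h", 0.0)
            object.__setattr__(self, "q_ace_sec", 0.0)


def fast_secretor() -> GenotypeParams:
    """An evolved fast-growing, acetate-secreting (FG-like) genotype.

    Glucose growth rate at the top of the evolved range, a shortened
    diauxic shift, and elevated overflow acetate secretion — the
    cross-feeding donor in heterogeneous populations.
    """
    return GenotypeParams(mu_glc=1.0, mu_ace=0.25, lag_h=1.0, q_ace_sec=0.8)


def slow_coutilizer() -> GenotypeParams:
    """A slow-growing glucose/acetate co-utilizing (SG-like) genotype.

    Single-phase growth with minimal acetate secretion; its combined
    dual-substrate rate trails the fast secretor's glucose rate, so it
    persists only by scavenging cross-fed acetate.  Competed against
    :func:`fast_secretor` it settles at a low stable frequency.
    """
    return GenotypeParams(coutilizer=True, mu_co=0.82)


def coutilization_revertant() -> GenotypeParams:
    """The co-utilizer with its transporter allele reverted.

    Faster on glucose than the co-utilizer's combined rate but diauxic
    again, with a long shift and restored acetate secretion; against
    :func:`fast_secretor` it is driven extinct within a few passages.
    """
    return GenotypeParams(mu_glc=0.86, mu_ace=0.25, lag_h=3.47,
                          q_ace_sec=0.7)


@dataclass(frozen=True)
class ReporterParams:
    """Phenomenological GFP synthesis parameters.

    ``alpha_exp`` applies during glucose exponential growth and
    ``alpha_shift`` from the diauxic shift onward, reproducing the low
    exponential-phase activity and the surge coinciding with the shift.
    Units: fluorescence per OD per hour.
    """

    alpha_exp: float = 1800.0
    alpha_shift: float = 9000.0
    gfp0: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha_exp < 0 or self.alpha_shift < 0:
            raise ParameterError("GFP synthesis rates must be nonnegative")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model applied per readout after the dynamics.

    od_cv : multiplicative lognormal coefficient of variation on OD.
    gfp_sd : additive Gaussian standard deviation on GFP.
    ct_sd : Gaussian standard deviation on simulated Ct values.
    """

    od_cv: float = 0.02
    gfp_sd: float = 10.0
    ct_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.od_cv < 0 or self.gfp_sd < 0 or self.ct_sd < 0:
            raise ParameterError("noise magnitudes must be nonnegative")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(od_cv=0.0, gfp_sd=0.0, ct_sd=0.0)


@dataclass
class BatchSimResult:
    """One simulated well: readout grid, traces and the embedded truth."""

    time_h: np.ndarray
    od: np.ndarray
    gfp: np.ndarray | None
    glucose_gl: np.ndarray
    acetate_gl: np.ndarray
    genotype: GenotypeParams
    reporter: ReporterParams | None
    noise: NoiseModel
    #: time at which glucose fell below the exhaustion threshold (h), or None
    t_glucose_exhausted: float | None = None


class _GenotypeState:
    """Mutable per-genotype integrator state (phase machine)."""

    __slots__ = ("p", "x", "phase", "t_resume", "t_exhaust")

    GLUCOSE, LAG, ACETATE, STATIONARY, CO = range(5)

    def __init__(self, params: GenotypeParams, x0: float):
        self.p = params
        self.x = x0
        self.phase = self.CO if params.coutilizer else self.GLUCOSE
        self.t_resume: float | None = None
        self.t_exhaust: float | None = None

    @property
    def alpha_is_shift(self) -> bool:
        return self.phase in (self.LAG, self.ACETATE, self.STATIONARY)

    def demand(self, t: float, dt: float, glc: float, ace: float):
        """Desired (dX, glucose_use, acetate_use, acetate_secretion)."""
        p = self.p
        if self.phase == self.CO:
            pool = glc + ace
            if pool <= EXHAUSTION_EPS:
                return 0.0, 0.0, 0.0, 0.0
            dx = self.x * math.expm1(p.mu_co * dt)
            w_glc = glc / pool
            use_g = w_glc * dx / p.y_x_glc if p.y_x_glc > 0 else 0.0
            use_a = (1.0 - w_glc) * dx / p.y_x_ace if p.y_x_ace > 0 else 0.0
            return dx, use_g, use_a, 0.0
        if self.phase == self.GLUCOSE:
            if glc <= EXHAUSTION_EPS:
                return 0.0, 0.0, 0.0, 0.0
            dx = self.x * math.expm1(p.mu_glc * dt)
            use_g = dx / p.y_x_glc if p.y_x_glc > 0 else 0.0
            return dx, use_g, 0.0, p.q_ace_sec * dx
        if self.phase == self.ACETATE:
            if ace <= EXHAUSTION_EPS:
                return 0.0, 0.0, 0.0, 0.0
            dx = self.x * math.expm1(p.mu_ace * dt)
            use_a = dx / p.y_x_ace if p.y_x_ace > 0 else 0.0
            return dx, 0.0, use_a, 0.0
        return 0.0, 0.0, 0.0, 0.0

    def advance_phase(self, t_next: float, glc: float, ace: float) -> None:
        if self.phase == self.GLUCOSE and glc <= EXHAUSTION_EPS:
            self.t_exhaust = t_next
            if self.p.lag_h > 0:
                self.phase = self.LAG
                self.t_resume = t_next + self.p.lag_h
            else:
                self.phase = self.ACETATE
        elif self.phase == self.LAG and t_next >= self.t_resume - 1e-12:
            self.phase = self.ACETATE
        elif self.phase == self.ACETATE and ace <= EXHAUSTION_EPS:
            self.phase = self.STATIONARY
        elif self.phase == self.CO and glc + ace <= EXHAUSTION_EPS:
            self.phase = self.STATIONARY


def _integrate(states: list[_GenotypeState], glucose0: float, acetate0: float,
               horizon_h: float, step_min: float,
               reporter: ReporterParams | None):
    """Shared fixed-step integrator for one or more genotypes in one pool.

    Returns (times, per-genotype X traces, glucose trace, acetate trace,
    per-genotype GFP traces) sampled at every internal step.
    """
    if horizon_h <= 0:
        raise ParameterError("horizon_h must be positive")
    if step_min <= 0:
        raise ParameterError("step_min must be positive")
    dt = step_min / 60.0
    n_steps = int(round(horizon_h / dt))
    if abs(n_steps * dt - horizon_h) > 1e-9:
        raise ParameterError("internal step must divide the horizon")
    glc, ace = float(glucose0), float(acetate0)
    if glc < 0 or ace < 0:
        raise ParameterError("initial substrate concentrations must be >= 0")

    m = len(states)
    times = np.empty(n_steps + 1)
    xs = np.empty((m, n_steps + 1))
    gl = np.empty(n_steps + 1)
    ac = np.empty(n_steps + 1)
    gfp = np.zeros((m, n_steps + 1)) if reporter is not None else None
    times[0] = 0.0
    gl[0], ac[0] = glc, ace
    for k, s in enumerate(states):
        xs[k, 0] = s.x
        if gfp is not None:
            gfp[k, 0] = reporter.gfp0

    for i in range(1, n_steps + 1):
        t = times[i - 1]
        demands = [s.demand(t, dt, glc, ace) for s in states]
        tot_g = sum(d[1] for d in demands)
        tot_a = sum(d[2] for d in demands)
        s_g = min(1.0, glc / tot_g) if tot_g > glc and tot_g > 0 else 1.0
        s_a = min(1.0, ace / tot_a) if tot_a > ace and tot_a > 0 else 1.0
        sec_total = 0.0
        for k, (s, (dx, ug, ua, sec)) in enumerate(zip(states, demands)):
            # scale growth by the scarcest pool this genotype draws on
            scale = 1.0
            if ug > 0:
                scale = min(scale, s_g)
            if ua > 0:
                scale = min(scale, s_a)
            dx, ug, ua, sec = dx * scale, ug * scale, ua * scale, sec * scale
            if gfp is not None:
                alpha = (reporter.alpha_shift if s.alpha_is_shift
                         else reporter.alpha_exp)
                gfp[k, i] = gfp[k, i - 1] + alpha * s.x * dt
            s.x += dx
            glc -= ug
            ace -= ua
            sec_total += sec
            xs[k, i] = s.x
        ace += sec_total
        glc = max(glc, 0.0)
        ace = max(ace, 0.0)
        t_next = i * dt
        times[i] = t_next
        gl[i] = glc
        ac[i] = ace
        for s in states:
            s.advance_phase(t_next, glc, ace)
    return times, xs, gl, ac, gfp


def simulate_batch(genotype: GenotypeParams,
                   reporter: ReporterParams | None = None,
                   noise: NoiseModel | None = None,
                   od0: float = 0.01,
                   glucose0: float = 1.0,
                   acetate0: float = 0.0,
                   horizon_h: float = 24.0,
                   seed: int | np.random.SeedSequence | None = None,
                   readout_min: float = 10.0,
                   step_min: float = 1.0) -> BatchSimResult:
    """Simulate one well of a glucose(-acetate) batch culture.

    Defaults match the study conditions: M9 + 1 g/l glucose inoculated
    at calibrated OD 0.01, read every 10 min for 24 h (one daily
    passage).  ``noise=None`` means the default 2% OD CV measurement
    noise; pass ``NoiseModel.none()`` for deterministic traces.
    """
    if od0 <= 0:
        raise ParameterError("od0 must be positive")
    if readout_min <= 0 or readout_min % step_min != 0:
        raise ParameterError("readout interval must be a multiple of the step")
    noise = NoiseModel() if noise is None else noise

    state = _GenotypeState(genotype, od0)
    times, xs, gl, ac, gfp = _integrate(
        [state], glucose0, acetate0, horizon_h, step_min, reporter)

    stride = int(round(readout_min / step_min))
    sel = slice(None, None, stride)
    time_h = times[sel].copy()
    od = xs[0, sel].copy()
    glucose = gl[sel].copy()
    acetate = ac[sel].copy()
    gfp_tr = gfp[0, sel].copy() if gfp is not None else None

    if np.any(glucose < -1e-12) or np.any(acetate < -1e-12):
        raise AssertionError("internal invariant violated: negative substrate")

    needs_rng = (noise.od_cv > 0) or (noise.gfp_sd > 0 and gfp_tr is not None)
    if needs_rng:
        rng = np.random.default_rng(seed)
        if noise.od_cv > 0:
            sigma = math.sqrt(math.log(1.0 + noise.od_cv ** 2))
            z = rng.standard_normal(len(od))
            od = od * np.exp(sigma * z - 0.5 * sigma ** 2)
        if noise.gfp_sd > 0 and gfp_tr is not None:
            gfp_tr = gfp_tr + noise.gfp_sd * rng.standard_normal(len(gfp_tr))

    return BatchSimResult(
        time_h=time_h, od=od, gfp=gfp_tr, glucose_gl=glucose,
        acetate_gl=acetate, genotype=genotype, reporter=reporter,
        noise=noise, t_glucose_exhausted=state.t_exhaust)


def simulate_serial_passages(genotypes: list[GenotypeParams],
                             fractions: list[float],
                             dilution: float = 512.0,
                             n_passages: int = 7,
                             passage_h: float = 24.0,
                             glucose0: float = 1.0,
                             acetate0: float = 0.0,
                             od0_total: float = 0.001,
                             n_counts: int | None = 45000,
                             count_noise: bool = True,
                             seed: int | np.random.SeedSequence | None = None,
                             step_min: float = 1.0) -> CompetitionTrajectory:
    """Serial-passage competition of genotypes sharing substrate pools.

    Within each passage all genotypes grow in the same well-mixed
    culture: acetate secreted by one genotype is available to every
    other.  At the end of each passage the biomass fraction of the
    first (focal) genotype is recorded — optionally as binomially
    sampled flow-cytometry counts out of ``n_counts`` cells — and the
    whole culture is diluted ``1/dilution`` into fresh medium.

    Defaults follow the evolution-experiment protocol: 512-fold daily
    dilution (9 doublings per passage) in 1 g/l glucose.
    """
    if dilution <= 1:
        raise ParameterError("dilution must exceed 1")
    if len(genotypes) != len(fractions) or not genotypes:
        raise ParameterError("need one starting fraction per genotype")
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ParameterError("starting fractions must be >= 0 and sum to 1")

    rng = np.random.default_rng(seed) if (n_counts and count_noise) else None
    xs = od0_total * fr
    focal_fraction = np.empty(n_passages)
    counts = np.empty((n_passages, 2), dtype=int) if n_counts else None
    incomplete = False
    for p in range(n_passages):
        states = [_GenotypeState(g, x) for g, x in zip(genotypes, xs)]
        _, traces, gl, ac, _ = _integrate(
            states, glucose0, acetate0, passage_h, step_min, None)
        end = traces[:, -1]
        if gl[-1] > 1e-3 or ac[-1] > 1e-3:
            incomplete = True
        frac = float(end[0] / end.sum())
        if n_counts:
            if rng is not None:
                focal = int(rng.binomial(n_counts, frac))
            else:
                focal = int(round(n_counts * frac))
            counts[p] = (focal, n_counts)
            focal_fraction[p] = focal / n_counts
        else:
            focal_fraction[p] = frac
        xs = end / dilution

    return CompetitionTrajectory(
        passages=np.arange(1, n_passages + 1),
        focal_fraction=focal_fraction,
        counts=counts,
        dilution=float(dilution),
        incomplete_regrowth=incomplete)


def simulate_qpcr(fractions,
                  slope: float = -540.0,
                  intercept: float = 802.0,
                  ct_sd: float = 0.2,
                  reps: int = 3,
                  seed: int | np.random.SeedSequence | None = None,
                  form: str = "fraction_on_log_ct") -> pd.DataFrame:
    """Simulate allele-specific qPCR Ct values for known mixture fractions.

    Two log-linear conventions are supported, mirroring the fitting
    module.  The default, ``fraction_on_log_ct``, places the allele
    fraction (percent) linearly on log10(Ct):
    ``fraction = intercept + slope * log10(Ct)`` with slope in percent
    per decade of Ct (negative: frequency falls as Ct rises).  The
    conventional dilution-series alternative, ``ct_on_log_fraction``,
    places Ct linearly on log10(fraction):
    ``Ct = intercept + slope * log10(fraction)`` with slope in Ct per
    decade of template (e.g. -3.32 at 100% efficiency).

    Zero-percent mixtures carry no template for the allele-specific
    primer and are emitted as censored Ct (NaN, "no amplification").

    Returns a long-format DataFrame with columns
    ``fraction, replicate, ct``.
    """
    if ct_sd < 0:
        raise ParameterError("ct_sd must be nonnegative")
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0) or np.any(fractions > 100):
        raise ParameterError("fractions are percentages in [0, 100]")
    rng = np.random.default_rng(seed) if ct_sd > 0 else None

    rows = []
    for f in fractions:
        if f == 0.0:
            cts = [math.nan] * reps
        else:
            if form == "fraction_on_log_ct":
                ct_mean = 10.0 ** ((f - intercept) / slope)
            elif form == "ct_on_log_fraction":
                ct_mean = intercept + slope * math.log10(f)
            else:
                raise ParameterError(f"unknown standard-curve form {form!r}")
            if ct_mean <= 0:
                raise ParameterError(
                    "standard-curve parameters imply nonpositive Ct")
            if rng is not None:
                cts = ct_mean + ct_sd * rng.standard_normal(reps)
            else:
                cts = [ct_mean] * reps
        for r, ct in enumerate(cts, start=1):
            rows.append({"fraction": f, "replicate": r, "ct": float(ct)})
    return pd.DataFrame(rows)


def write_plate_csv(results: dict[str, BatchSimResult], path,
                    map_path=None, strains: dict[str, str] | None = None,
                    promoters: dict[str, str] | None = None) -> None:
    """Write wells as a long-format plate table plus a sidecar well map.

    The CSV schema (``time_h, well, channel, value`` with channel in
    {OD, GFP}) matches the readers in the growth and reporter modules.
    The optional YAML sidecar maps each well to its strain label,
    reporter promoter and ground-truth generator parameters.
    """
    frames = []
    for well, res in results.items():
        frames.append(pd.DataFrame({
            "time_h": res.time_h, "well": well,
            "channel": "OD", "value": res.od}))
        if res.gfp is not None:
            frames.append(pd.DataFrame({
                "time_h": res.time_h, "well": well,
                "channel": "GFP", "value": res.gfp}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    if map_path is not None:
        wmap = {}
        for well, res in results.items():
            entry: dict = {
                "strain": (strains or {}).get(well, well),
                "truth": {k: getattr(res.genotype, k)
                          for k in GenotypeParams.__dataclass_fields__},
            }
            if promoters and well in promoters:
                entry["reporter"] = promoters[well]
            if res.reporter is not None:
                entry["truth_reporter"] = {
                    k: getattr(res.reporter, k)
                    for k in ReporterParams.__dataclass_fields__}
            wmap[well] = entry
        with open(map_path, "w") as fh:
            yaml.safe_dump(wmap, fh, sort_keys=True)
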