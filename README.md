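# diauxkit

Analysis toolkit for glucose-fed batch-culture experimental evolution in
*E. coli*: growth-curve kinetics and diauxic-shift quantification, GFP
promoter-reporter dynamics, substrate uptake/secretion rates, qPCR
relative expression and allele frequencies, and serial-passage
competition statistics — plus a synthetic batch-culture generator with
known ground truth so every estimator can be validated end to end.

It is aimed at microbial physiology and experimental-evolution labs that
follow cultures on a microplate reader (OD600 and GFP every 10 min),
measure extracellular metabolites, quantify expression or allele
frequencies by real-time PCR, and compete genotypes by daily serial
transfer.

## The quantities it computes

* **Growth rate** μ: OLS slope of ln OD against time over the window of
  calibrated OD 0.05–0.35 (plate-reader ODs are multiplied by 2.2 to
  match a 1-cm-path spectrophotometer). **Yield** is the smoothed
  maximum OD.
* **Diauxie call**: a second slope over the extended window OD 0.05 to
  0.9·max OD; a genuine second, slower growth phase lowers it, and a
  one-sided slope-equality test (Welch t on the two regression slopes)
  classifies the curve at α = 0.05. The **diauxic shift** is the
  growth-arrest interval between the glucose and acetate phases,
  refined by intersecting the flanking exponential regression lines
  with the arrest plateau of ln OD.
* **Transcriptional activity** GFP/OD and **promoter activity**
  (dGFP/dt)/OD, summarized by averaging over the exponential window
  OD 0.1–0.3 with t-based 95% CIs across replicates. **CRP activity**
  is the transcription of a CRP-binding-site hybrid promoter divided by
  that of the constitutive control promoter.
* **Substrate yield** Y: OLS slope of extracellular concentration
  against biomass over ≥5 exponential-phase points; **specific rate**
  q = |Y|·μ, with the slope sign deciding uptake vs secretion, and a
  co-utilization call when glucose and acetate are taken up together.
* **qPCR**: relative expression 2^ΔΔCt (ΔCt = Ct(target) − Ct(*rpoD*);
  ΔΔCt = ΔCt(control) − ΔCt(test)), and allele frequencies inverted
  from a mixture standard curve in which the fraction is linear in
  log10(Ct).
* **Competition**: log2(dilution) generations per passage (9 at the
  512-fold daily transfer), focal-genotype frequencies with Wilson
  binomial intervals from ≥45 000-cell cytometry counts, coexistence /
  exclusion calls, an exact one-sided Fisher test (log-factorial
  hypergeometric tail), one-way and nested ANOVA (isolates nested in
  populations), CVs and Pearson/Spearman correlations.

The simulator integrates the three-stage batch cycle — exponential
glucose growth with overflow acetate secretion, a growth-arrest lag at
glucose exhaustion, then growth on the accumulated acetate — or a
single-phase glucose/acetate co-utilizing mode, with a phase-dependent
GFP synthesis rate and per-readout measurement noise. Serial passages
share the substrate pools between genotypes, so acetate secreted by one
is available to the other (cross-feeding).

## Worked example

```python
import diauxkit as dk
from diauxkit import reporter as rp, stats as dst

zed = dk.GenotypeParams()                # ancestor: mu 0.56/h, 3.47 h shift
res = dk.simulate_batch(zed, seed=7)     # 24 h, 10-min readouts, 2% OD noise
curve = dk.GrowthCurve(res.time_h, res.od, well="A1", strain="ZED")

fit = dk.fit_growth_rate(curve)
call = dk.detect_diauxie(curve)
shift = dk.estimate_shift(curve, call)
print(f"mu = {fit.mu:.3f} /h (r2 = {fit.r2:.4f})")
print(f"diauxic: {call.is_diauxic} (one-sided p = {call.p_value:.2e})")
print(f"shift duration = {shift.duration_h:.2f} h")

fisher = dst.fisher_exact_one_sided([[48, 0], [36, 12]])
print(f"Fisher one-sided p = {fisher.p_one_sided:.3g}")

crp = rp.crp_activity(rp.ExpressionSummary(9555, 51, 3, (0.1, 0.3)),
                      rp.ExpressionSummary(1479, 43, 3, (0.1, 0.3)))
print(f"CRP activity = {rp.round_half_away(crp.value, 1)} +/- {crp.ci95:.2f}")
```

prints

```
mu = 0.568 /h (r2 = 0.9992)
diauxic: True (one-sided p = 7.55e-19)
shift duration = 3.66 h
Fisher one-sided p = 0.000112
CRP activity = 6.5 +/- 0.19
```

The fitted rate recovers the generating 0.56 h⁻¹ within noise, the
two-slope test flags the diauxie decisively, and the shift estimate
lands near the generating 3.47 h lag. The Fisher tail is the exact
probability of a 48/48-isolate diauxie contingency at least as uneven
as observed, and the CRP activity is the hybrid/constitutive promoter
ratio with first-order error propagation.

A command-line interface mirrors the library
(`diauxkit growth|reporter|rates|qpcr|compete|stats ...`); see
`diauxkit --help`.

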