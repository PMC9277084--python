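# Methods

## Model structure

The analysis is a cohort-level, three-state partitioned survival model
(progression-free, progressed disease, dead) for second-line treatment of
advanced oesophageal squamous cell carcinoma: nivolumab (n=210) versus
paclitaxel/docetaxel chemotherapy (n=209, split 144/65). State occupancy is
read directly off the arm's overall-survival and progression-free-survival
functions — PF = S_PFS, PD = S_OS − S_PFS, Dead = 1 − S_OS — so no transition
probabilities are estimated and the mutual consistency of the two curves is a
structural assumption. If independent calibration ever produced S_PFS > S_OS,
PF is clamped to S_OS with a logged warning so occupancies stay in [0,1] and
conserve to 1 (tolerance 1e-12 in tests).

The cycle grid is 60 days with a 36-month horizon. One month is 30.4375 days
everywhere (mean Gregorian month; a single constant avoids unit drift), so the
horizon is 1095.75 days = 18 full cycles plus one 15.75-day cycle accrued
pro-rata. There is no extrapolation beyond the horizon and no background
(general-population) mortality: the disease is rapidly fatal over this span
and the trial follow-up covers it.

### Accrual convention

The published description does not state a half-cycle correction or
integration rule. Occupancy for cost/QALY accrual is therefore evaluated at a
configurable point per cycle — `start`, `mid`, or `end` — with **mid** the
default, as the least-biased single-point rule for a monotone survival
integrand (the start/end rules bracket the true integral; tests verify the
bracket). Death increments always come from cycle boundaries, so they
telescope exactly to cumulative mortality. Discounting is continuous-time
compounding of the 5 %/year rate, (1+r)^(−t/365.25), applied at each cycle's
midpoint (and at the actual event day for administration-linked costs).

## Survival reconstruction

Only medians and a few landmark probabilities are published per arm/endpoint
(nivolumab OS: median 10.9 mo, 47 %/31 % at 12/18 mo; chemotherapy OS: 8.4 mo,
34 %/21 %; nivolumab PFS: 1.7 mo, 24 %/12 % at 6/12 mo; chemotherapy PFS:
3.4 mo, 17 %/7 %). Each curve is piecewise exponential with knots exactly at
the anchor times (median treated as an S=0.5 anchor); the segment hazard has
the closed form λᵢ = [ln S(tᵢ₋₁) − ln S(tᵢ)]/(tᵢ − tᵢ₋₁), so every printed
summary is reproduced exactly (tests assert 1e-9). The last segment's hazard
continues to the horizon. Non-monotone anchor pairs are reconciled by clipping
the hazard at 0 with a warning, never silently. This is deliberately the
fewest-parameter curve consistent with all printed values; it is *not* a fit
to the unpublished Kaplan–Meier curves, and its constant-hazard tails carry
no information about tail behaviour beyond the last landmark (see
Limitations).

### Pseudo-individual-patient data

Pseudo-IPD are drawn by inverse-CDF sampling, T = S⁻¹(U), with administrative
censoring at the 36-month horizon (the only censoring mechanism; no dropout
model is published). The default sampler is **stratified**: one uniform per
probability stratum, uᵢ = (i + Uᵢ)/n. This is unbiased, and it bounds the gap
between the empirical survival fraction and the generating curve by 1/n at
every time point — appropriate for a generator whose purpose is to reproduce
published summaries at the trial's own sample sizes. Plain `iid` sampling is
available and is what the large-sample consistency tests use. Seeds: one
master seed in the config; per-arm/endpoint and PSA streams are spawned from
it deterministically.

Re-estimation mirrors the source analysis: Kaplan–Meier (via lifelines) for
OS with the median read as the first time the estimate reaches ≤0.5, and a
hand-implemented actuarial life-table for PFS with effective denominator
n − c/2 per interval (default width 30 days, configurable), interval-end
survival, and the median interpolated linearly inside the crossing interval.
The life-table interval width is configurable because coarse intervals are
the one mechanism in this pipeline that shifts the PFS median upward from the
trial values, in the direction of the model medians reported by the source.

## Costs

All costs are 2021 US$, healthcare-system perspective, and every total is
unit cost × expected discounted quantity, which keeps totals linear in unit
costs (the PSA is then a matrix product, not 10,000 model re-runs).

* **Acquisition.** Time on treatment is proxied by PFS: the expected number of
  administrations is Σ S_PFS(d) over scheduled dose days d, discounted at the
  dose day. Nivolumab 240 mg every 14 days; paclitaxel 171 mg (100 mg/m² ×
  1.71 m²) weekly six-on/one-off; docetaxel 128.25 mg (75 mg/m²) every 21
  days; chemotherapy weights 144/209 and 65/209. The base case uses the
  published per-administration unit costs ($3,614.08 / $459.60 / $997.19),
  which are what the sensitivity ranges attach to; a `vial` mode instead
  prices each administration by a least-cost whole-vial cover (no sharing,
  round up) over the list prices ($718/40 mg and $1,448/100 mg nivolumab,
  $77/30 mg paclitaxel, $142/20 mg docetaxel). The two agree to ≤$0.10 for
  nivolumab (2×$1,448+$718 = $3,614 vs $3,614.08), which is the consistency
  check that motivated treating the per-administration values as vial
  arithmetic. The printed mean chemotherapy doses (115/275 mg) conflict with
  the mg/m² rule and are not used; the mg/m² rule is authoritative here.
* **Administration.** Preventive medication $93.93 + infusion $1.86 +
  hospitalization $39.14 per expected administration, both arms.
* **Monitoring.** A baseline work-up bundle once at t=0 (ECG, hematology,
  serum chemistry, urinalysis, coagulation, thyroid, pulmonary function,
  HBV/HCV serology, one tumour scan; $582.83 at base prices); the
  five-test laboratory panel before every administration, weighted by
  S_PFS; thyroid function repeated every 6/3/9 weeks (nivolumab/
  paclitaxel/docetaxel) while on treatment; tumour imaging every 6 weeks in
  year 1 then every 12 weeks, weighted by PF occupancy because the protocol
  stops scans at progression. HBV DNA is a conditional screening test and
  accrues no quantity in the base case (its parameter row is kept so the DSA
  sweeps it, with zero effect).
* **Adverse events.** Grade ≥3 only, as a one-time expected cost at model
  entry (Σ incidence × management cost), undiscounted. **Incidences are not
  published for this comparison**; the shipped profile is a synthetic
  placeholder patterned on the trial's qualitative safety picture
  (chemotherapy-dominant haematological toxicity, low-frequency immune events
  on nivolumab). It was chosen once, is clearly labelled in the config, and
  contributes ≈$370 (nivolumab) and ≈$920 (chemotherapy) — small relative to
  drug acquisition, matching the source's remark that AE costs are minor.
* **Progressed disease.** The published composition of PD-stage cost is
  underdetermined; the default is a per-cycle bundle of hematology + serum
  chemistry + hospitalization fee weighted by PD occupancy, configurable and
  deliberately *not* tuned to the $45 per-patient difference the source
  mentions.
* **Terminal.** Funeral cost $4,517.85 × per-cycle death increments,
  discounted at cycle midpoints.

## Outcomes

Utilities 0.74 (PF), 0.58 (PD), 0 (dead); QALYs = Σ (PF·u_PF + PD·u_PD) ×
cycle/365.25 × discount. The source also describes utility "declining
linearly" toward death; because only the two constant state utilities are
parameterized (and sampled in the PSA), the base case is constant-per-state,
and a `linear_decline` mode is provided that values PF person-time at
(u_PF+u_PD)/2 and PD person-time at (u_PD+u_dead)/2 — a cohort-level
approximation of within-state decline, off by default.

## Sensitivity analyses

* **One-way DSA.** Every unit-cost row (including each AE management cost),
  both utilities, the discount rate over 0–8 %, and each arm's survival time.
  Survival time has no published excursion mechanism; it is implemented as a
  multiplicative hazard scale on that arm's OS and PFS curves with range
  [0.8, 1.25] (±20 % on the time scale), configurable. Entries are sorted by
  ICER range; the two survival-time parameters dominate the tornado, matching
  the source's ordering.
* **PSA.** 10,000 iterations; Gamma for costs (shape = μ²/σ², scale = σ²/μ),
  Beta for utilities (moment-matched on [0,1]); μ anchored at the base value
  and σ = (high − low)/3.92, reading the range as a 95 % interval — the σ rule
  is this package's documented choice, as none is published. Survival curves
  and the discount rate are "fixed in model" and not sampled. Degenerate
  ranges collapse to point masses. The CEAC uses net monetary benefit,
  P(ΔE·λ − ΔC > 0), which is well defined in all four quadrants.
* **Price solver.** Bisection on the multiplier applied to the intervention
  arm's per-administration acquisition cost until |ICER − target| < $1/QALY;
  monotonicity of ICER in the multiplier is guaranteed by linearity (ΔE is
  unaffected) and verified by tests that plug the solution back through the
  full model.

## Problem sizes and determinism

The shipped base case runs in seconds: a full model evaluation is one pass
over ~19 cycles and ~80–140 scheduled dose days per arm; the DSA is 96
evaluations; the PSA is a 10,000 × ~49 matrix product. All randomness flows
from the single master seed; the PSA and pseudo-IPD are bit-reproducible
under a fixed seed (tested).

## What the synthetic data do and do not show

The pseudo-IPD generator emulates the *published summaries* of the trial:
sample sizes, medians, landmark probabilities, administrative censoring at
36 months. It does not emulate staggered accrual, dropout, within-trial
censoring before the horizon, covariates, or the true curves' tail shape
between and beyond the printed landmarks. Tests that pass on these data show
the pipeline is internally correct and faithful to the printed inputs — not
that the piecewise-exponential tails match the unpublished Kaplan–Meier
curves.

## Known limitations and discrepancies

* **The reported base case is not recoverable from the printed survival
  summaries.** Integrating the calibrated curves over 36 months gives an
  incremental OS area of ≈2.7 months and hence ΔE ≈ 0.13 QALYs, while the
  original analysis reports 0.28 (0.80 vs 0.52). No accrual convention
  (start/mid/end), utility mode, or life-table interval width available here
  moves ΔE above ≈0.17: the originally reported per-arm chemotherapy QALY
  (0.52) is lower than its own printed survival curves imply (≈0.6), and the
  original nivolumab acquisition total implies ≈13 administrations where the
  printed PFS summaries support ≈10.5 — both consistent with the original
  Excel model reading unpublished curve data with heavier between-arm
  separation in the tails. Consequently this package reproduces the survival
  landmarks, the tornado ordering, the DSA's $80,000 ICER floor, and the
  PSA probability at the base ICER, but computes a higher ICER (≈$233k vs
  $132k/QALY) and a deeper required price cut (≈65 % vs 53.5 %) than
  originally reported. The qualitative conclusion — not cost-effective at
  $37,653/QALY without a large price reduction — is unchanged and, if
  anything, strengthened.
* AE incidences are placeholders (above); totals that include them should be
  read accordingly.
* Grade 1–2 adverse events, subsequent-line therapy, indirect costs, and
  currency conversion are out of scope, as in the source analysis.
* The model is cohort-level: within-state utility decline and
  individual-level treatment-duration distributions are approximated at the
  cohort mean.
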