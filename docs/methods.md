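# Methods

## Virtual population

Each experiment generates two cohorts of adult male subjects (hemophilia A is
X-linked; only male anthropometric formulas are implemented):

* *normal*: BMI uniform on [20.3, 29.6) kg·m⁻²;
* *overweight/obese*: BMI uniform on [29.6, 40.0) kg·m⁻².

The bins are half-open so the shared 29.6 boundary is unambiguous.  Heights
are sampled independently of BMI from a truncated normal — mean 175.7 cm,
SD 7.4 cm, bounds [150, 200] cm — chosen to represent the NHANES adult-male
height distribution.  All four parameters are configuration-exposed because
the exact source distribution (survey cycle, age stratum, empirical vs
fitted) is a genuinely open choice; sensitivity to it is discussed under
*Limitations*.  Total body weight is the exact product BMI·(HT/100 m)², and
every derived metric (LBW, IBW, ABW₂₅, ABW₄₀) is computed unrounded; per-kg
doses are applied to the unrounded metric.

One ambiguity in the adjusted-body-weight definition was resolved in favour
of the standard pharmacokinetic form `ABW_f = IBW + f·(TBW − IBW)` — the
correction applies to the excess weight above ideal weight, so f = 0 recovers
IBW and f = 1 recovers TBW exactly.

Populations are generated once per experiment (deterministic in the seed via
`numpy.random.SeedSequence`, one child stream per BMI group) and reused
across every regimen and metric, so dose comparisons are paired on the same
virtual subjects.

## Pharmacokinetic model

A two-compartment IV-bolus model with lean-body-weight covariate scaling
(power functions on CL and V1, reference LBW 51.1 kg) and lognormal
between-subject variability.  The published variability is stated as %CV;
we map it to the log-scale variance with the standard popPK convention
ω² = ln(1 + CV²), which keeps parameters positive, makes the *median* of the
sampled distribution equal the typical value, and reproduces the stated CV
exactly (verified by Monte-Carlo in the tests).  No η-correlation between CL
and V1 is modelled (none is reported), and Q and V2 carry no variability.

Two deliberate scoping decisions:

* **Residual unexplained variability is not applied.**  Simulated activities
  are *true* levels; the safety criterion is evaluated on true levels.  The
  RUV magnitudes (26.7 %CV proportional, 1.10 IU·dL⁻¹ additive) are retained
  in `PKModelSpec` as documentation only.
* **The PK covariate is always LBW**, regardless of which metric the dose is
  computed from.  Dosing metric and covariate are independent axes.

Profiles are evaluated analytically: the unit-dose impulse response
`A·e^(−αt) + B·e^(−βt)` is superposed over the bolus history on top of an
additive baseline.  α and β come from the quadratic in the micro rate
constants, with β computed via Vieta's product for numerical stability; an
exactly repeated root falls back to the one-compartment limit with an
explicit flag (unreachable for strictly positive parameters).  Numerical ODE
integration exists only as an independent test oracle and agrees with the
analytic path to better than 0.1% relative across random parameter draws.

## Regimens and endpoints

Two calendars: `q48h` (equal doses every 48 h) and `mwf` (doses at hours 0,
48 and 96 of each 168 h cycle; the Friday dose may differ to cover the 72 h
weekend gap).  Simulations run from t = 0 with a 4-week run-in; endpoints are
read from the 5th week, [672 h, 840 h), on a 0.2 h grid.  The run-in is
validated: for typical subjects under q48h, pre-dose troughs at the start and
end of the analysis week differ by < 1%.

Per-subject endpoints:

* **Cmin** — weekly minimum on the grid, using the *pre-dose* value at dose
  instants (recovered exactly as post-dose level − dose/V1; troughs occur
  immediately before a bolus).  The analysis window for M-W-F starts at a
  Monday dose instant so the weekend trough lies inside it.
* **time below target** — 0.2 h × number of grid points strictly below
  1 IU·dL⁻¹.  "Safe" is the inclusive comparison Cmin ≥ 1 IU·dL⁻¹.
* **weekly consumption** — for M-W-F, the three doses actually given; for
  q48h, 3.5 × the per-dose amount (a 168 h window alternately contains 3 or 4
  doses; 3.5 is the long-run average and matches the consumption bookkeeping
  of the reference tables).

Cohort aggregates: safe ratio, median Cmin with an empirical 5th–95th
percentile band, mean weekly consumption, and the 95th percentile of time
below target.  Quantiles use NumPy's inclusive linear-interpolation
convention (the choice is documented because no convention was prescribed).

## Dose titration

The titration grid is 2 IU/kg steps on [10, 100], 10 IU/kg on [100, 210],
refined to 0.1 IU/kg on [20, 30] where the q48h optima fall — so optima with
one decimal are only reachable inside [20, 30], as intended.  Because
activity is linear in dose, each subject's Cmin is strictly increasing in the
dose and the population safe ratio is monotone; the search may therefore use
binary search over the grid, and a property test pins its result to the
linear scan.  A criterion that is unreachable at the grid maximum yields an
explicit "not achievable" result rather than an exception — this genuinely
occurs for the M-W-F calendar with baseline 0 at the 95% criterion.

The scan is accelerated by precomputing each subject's analysis-week response
to *unit* boluses on the calendar (`SteadyStateEngine`); troughs under any
dose follow by scaling.  The engine path is verified against the full
profile-based evaluation to 1e-9 relative.

For the M-W-F study rows, Monday/Wednesday doses are fixed at the
corresponding q48h optimum and the Friday dose is escalated; the default
M-W-F criterion is 0.90 (the published weekly-table convention) while the
q48h criterion is 0.95 — both are plain configuration values, and the
headline Friday-dose endpoint additionally uses the 0.95 criterion with
Monday/Wednesday fixed at 20 IU/kg TBW.

## Problem sizes and seeds

The reference experiment uses 1000 subjects per BMI group.  Headline
endpoints are averaged over 10 replicate seeds derived from one master seed
(`SeedSequence.generate_state`, kept below 2³¹); each replicate draws a fresh
population and fresh PK parameters, so the replicate spread reflects full
Monte-Carlo variability.  The optimum of a 95% population criterion is a
tail-quantile statistic and is noticeably seed-sensitive at n = 1000 —
single-seed optima for a given cell can move by ±2 IU/kg — which is why
averaged replicates are reported.

## Limitations

* The height distribution is a modelling choice, and the optimum doses are
  mildly sensitive to it.  Mean weekly consumption scales directly with mean
  body size (≈ ±3% per ±2 cm of mean height), and the fine-grid optima for
  metrics with small masses (notably LBW in the normal-BMI group) can shift
  by 1–3 IU/kg between plausible height models, since the limiting patients
  are small subjects with fast clearance.  The distribution is
  config-exposed precisely so this sensitivity can be probed.
* Virtual subjects are adult males with independent height and BMI; no
  pediatric anthropometrics, no female subjects, no joint height–BMI model.
* True activity levels only: no assay error, no Bayesian individual PK
  estimation, no bleed-risk model on time below target; economics are the
  flat $1/IU proxy.
* The PK model is that of one conventional FVIII concentrate; extended
  half-life products and non-bolus infusions are out of scope.
* Passing tests demonstrate internal consistency and reproduction of the
  simulated study's numbers under these synthetic conditions, not clinical
  performance in real patients.
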