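# Methods

This note documents the model, its conventions, the design choices that were
genuinely open, and what the test suite does and does not establish. It is
the package's own account; every number quoted here is computed by the code
(`examples/`, `scripts/acceptance.py`, or the test suite).

## Cohort model

Three states — progression-free (PFS), progressed disease (PD), dead — with
one-directional transitions. Everyone starts in PFS. The cycle is 21 days
(0.68994 months at 30.4375 days/month); the horizon is exactly 10 years.
The cycle grid holds 174 whole-cycle boundaries (cycles 0–173, the last at
119.36 months) plus a terminal boundary at 120 months, so the final partial
cycle enters every accumulation with its true length (175 boundary rows,
174 intervals).

Two evaluation modes share one surface:

* **Partitioned survival (default).** Occupancy is read directly off the
  independently fitted curves: `pfs = min(S_PFS, S_OS)`, `death = 1 − S_OS`,
  `pd` the remainder. The min-cap guarantees non-negative PD occupancy when
  the fitted curves cross (they do here past ~8 years in the immunotherapy
  arm, because the log-normal PFS tail is heavier than the Weibull OS tail).
* **Markov.** Per-cycle conditional probabilities from the same curves:
  death claims `1 − S_OS(t+Δ)/S_OS(t)` of both alive states; the PFS exit
  probability is floored at the death probability (the discrete twin of the
  min-cap) and its residual is progression. Death occupancy therefore
  matches partitioned mode to machine precision, which the suite asserts at
  1e−9. No state-specific mortality is available from the inputs, so PD
  carries the same conditional death risk as PFS.

**Discounting** is continuous-equivalent: weight `(1.03)^(−t_years)` at each
boundary (an annual-step variant is a config flag). **Half-cycle
correction** is the trapezoid rule applied to the discounted occupancy — by
construction it lands between the left- and right-endpoint rectangle rules,
which the suite verifies, and it is applied to costs and effects alike (the
original analysis does not say which; both-sides is the symmetric default).

Time is **months** throughout the survival layer. The unit is pinned by the
fitted chemotherapy OS law: its log-logistic scale (= median) of 14.1088
reproduces the arm's 14.1-month median survival. The survival layer floors
S at 1e−300 before forming conditional ratios; a numerically exhausted state
transitions with probability 1.

## Valuation

Per-cycle composition (2021 USD):

* **PFS**: on-treatment drug acquisition + administration ($69.81) +
  laboratory ($157.50) + follow-up ($59.20). Immunotherapy arm drugs:
  nivolumab $18,419.94 + ipilimumab $11,258.31 per cycle, given to
  progression (no cap by default). Chemotherapy arm: pemetrexed $12,832.51
  plus a 50/50 cisplatin/carboplatin blend ($52.21), capped at 6 induction
  cycles (monitoring continues afterwards). The blend ratio and caps are
  config-exposed; the underlying dosing constant is a 1.68 m² body surface
  area.
* **PD**: best supportive care ($117.10) + follow-up, plus the
  probability-weighted subsequent-therapy regimen (immunotherapy →
  pembrolizumab $21,479.60; chemotherapy → vinorelbine $227.28; mix 3.3%/43.2%
  after immunotherapy, 20.2%/31.5% after chemotherapy) for the first
  6 post-progression cycles. Because a cohort trace does not track time
  since progression per occupant, the on-subsequent-therapy fraction is
  approximated by a progression-inflow queue: the PFS-curve decrement of the
  last 6 cycles, capped by current PD occupancy. The named
  oxaliplatin/leucovorin/fluorouracil alternative has no published unit
  cost, so the regimen slot is configurable rather than hard-coded.
* **Death**: zero.
* **Adverse events** (grade ≥3, top three per arm) are one-time burdens at
  model entry: expected cost Σ risk·cost ($24.37 immunotherapy, $276.84
  chemotherapy) and a one-cycle utility decrement Σ risk·disutility·(cycle
  length in years). No duration is published; one cycle is the minimal
  convention.
* **Utilities**: 0.65 (PFS), 0.47 (PD) per year in state.

## Sensitivity analysis

One-way: every input with a published ±20% range (35 parameters: 11 unit
costs, 2 utilities, 6 AE risks/costs/disutilities per arm, 4
subsequent-therapy probabilities) swung to 0.8× and 1.2× base; entries
ranked by ICER spread. PSA: gamma for costs, beta for probabilities and
utilities (disutilities: beta on the magnitude, re-negated), all
moment-matched with SD = 20% of base (the published dispersion column);
one named generator per run, parameters drawn in list order so seeds are
portable. The four fitted survival parameter sets are held fixed: they are
published as point estimates from model fitting with no dispersion, and no
variance–covariance is available to propagate.

The price-threshold search bisects on a scalar reduction fraction applied
multiplicatively to the nivolumab and ipilimumab acquisition costs only
(not administration/monitoring), snapped to a 0.1% grid.

## Kaplan–Meier reconstruction and fitting

The Guyot risk-table-constrained reconstruction: within each interval
between consecutive numbers-at-risk, an integer censoring count is solved
so the implied risk count at the next risk time matches the published one
(censorings spread uniformly within the interval); event counts at each
digitized time then follow from the KM ratios. Digitized survival is
clipped non-increasing first (hand-digitized points can invert). Small
risk-set shortfalls forced by digitization noise are tolerated best-effort;
a shortfall beyond max(2, 5% of the initial cohort) raises an error naming
the interval. After the last risk-table time no further censoring is
assumed, and survivors at the last digitized time are administratively
censored there. Round-trip accuracy — KM recomputed from the output vs the
digitized input — is within 1/n at every digitized time, exact for
uncensored curves.

Fitting maximises the right-censored log-likelihood for the Weibull,
log-normal and log-logistic families via lifelines' univariate fitters;
AIC = 2k − 2lnL and BIC = k·ln n − 2lnL with k = 2; selection takes the
criterion minimum with ties broken in family order (Weibull, log-normal,
log-logistic) and flagged.

## Synthetic data

The generator emulates what the pipeline's real inputs would look like:
event times drawn by inverse-CDF from a known law, administrative or
exponential censoring, product-limit curves with risk tables, and
digitization noise (pixel-grid resampling + truncated Gaussian jitter +
monotonicity repair). Default scenarios are the four published laws at the
trial arm sizes (303/302) with administrative censoring at 36 months,
approximating the ~30-month median follow-up. It does **not** emulate
correlated OS/PFS at the patient level, covariate structure, or real
digitizer artefacts such as axis-calibration bias — so passing recovery
tests show the algorithms are correct under the stated error model, not
that any particular published figure was digitized accurately.

Fixed-seed recovery results asserted by the suite: parameters within 5% on
clean IPD at n = 5,000; within 10% through the full digitize → reconstruct
→ fit pipeline at the trial scale (n ≈ 300, noise SD 0.01).

## Reproduction of the published analysis

The faithful model run from the published inputs gives (discounted,
10-year):

| quantity | this package | published |
|---|---|---|
| chemotherapy cost | $98,768 | $95,715 |
| chemotherapy QALYs | 0.984 | 0.58 |
| immunotherapy cost | $549,974 | $292,319 |
| immunotherapy QALYs | 1.081 | 1.11 |
| ΔQALY | 0.097 | 0.53 |
| ICER/QALY | $4,639,529 | $371,861 |

Comparator cost and intervention QALYs reproduce well (≤4%). The rest
cannot be reproduced from the printed inputs under any accounting
convention, for two verifiable reasons:

1. **The published results table is internally inconsistent.** Both arms'
   QALY/LY ratios (1.11/1.58 ≈ 0.70; 0.58/0.65 ≈ 0.89) exceed the maximum
   printed utility (0.65), which is impossible under
   QALY ≤ u_PFS · LY. This package enforces that invariant on its own
   outputs.
2. **The fitted curves nearly coincide in restricted means.** The
   chemotherapy log-logistic OS has a heavier tail than the immunotherapy
   Weibull (restricted means 22.6 vs 24.0 months over 120 months), so the
   10-year life-year delta is ~0.13, not the published 0.92 — no valuation
   convention can manufacture a 0.53 QALY gap from these curves. Likewise,
   pricing the immunotherapy per-cycle costs over the fitted
   progression-free time (~18 discounted cycles) necessarily exceeds the
   published arm total, which would correspond to roughly 9–10 treatment
   cycles.

Consequences that follow mechanically: the price reduction required for
cost-effectiveness is 80.2% rather than ~34%, and with the small QALY delta
the PFS utility (which rescales the ICER denominator directly) overtakes
the nivolumab price at the top of the tornado (nivolumab remains the
top-ranked cost). The qualitative conclusions all reproduce: the
immunotherapy combination is far above the $207,659/QALY threshold, zero of
10,000 PSA iterations favour it, and the CEAC is monotone in WTP.

The chemotherapy arm reaches 97.5% absorption at 10 years (1 − S(120));
the immunotherapy arm 99.8%, consistent with the published "approximately
99%" remark.

## Numerical choices

* Closed-form survival identities are exact to 1e−9 (asserted); the
  log-normal Φ uses the error function.
* Restricted means use adaptive quadrature (scipy), cross-checked in tests
  against an independent fine-grid trapezoid oracle at 1e−6 relative.
* Optimizer details for censored MLE are delegated to lifelines (Newton-type
  on transformed parameters); non-convergence surfaces as a typed error.
* Conservation is enforced per boundary row at 1e−12; the markov recursion
  re-dumps accumulated float residue (≪1e−12) into the death state.
* PSA problem size: 10,000 iterations complete in a few seconds because
  survival (hence the trace) is fixed, so only the valuation layer re-runs
  per draw.

## Known limitations

* Subsequent-therapy timing is an inflow-queue approximation, exact only
  when no one dies within 6 cycles of progressing.
* AE burdens are entry-time lump sums; a per-cycle incidence model would
  shift a few dollars/micro-QALYs into discounted time.
* No correlation between PSA draws; no survival-parameter uncertainty; no
  EVPI.
* The published totals themselves are not a usable validation target beyond
  the anchors noted above, for the reasons documented in the reproduction
  section.
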