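# mesocea

A cost-effectiveness model of first-line **nivolumab + ipilimumab versus
platinum–pemetrexed chemotherapy in unresectable malignant pleural
mesothelioma (MPM)**, rebuilt as a tested, reusable Python package for
health-economics researchers and reviewers.

The package reimplements a published US-payer analysis of the CheckMate 743
trial comparison: a three-state cohort model (progression-free → progressed
→ dead) driven by parametric survival extrapolation, valued with per-cycle
drug/monitoring/adverse-event/subsequent-therapy costs and state utilities,
and interrogated with deterministic and probabilistic sensitivity analysis.
It also ships the supporting machinery such an analysis needs: pseudo
individual-patient-data reconstruction from digitized Kaplan–Meier curves
(the Guyot risk-table-constrained algorithm), censored maximum-likelihood
fitting with AIC/BIC model selection, and a synthetic-data generator that
makes the whole pipeline testable offline.

## The model

* **States.** All patients start progression-free (PFS); transitions are
  one-directional (PFS → PD → death). Cycle length 3 weeks, horizon 10
  years, half-cycle correction, 3% annual discount on costs and effects.
* **Survival.** Occupancy is read off two independently fitted curves
  (partitioned-survival mode, default): PFS(t) = min(S_PFS(t), S_OS(t)),
  death(t) = 1 − S_OS(t). A transition-probability (Markov) mode derived
  from the same curves is provided and agrees on death occupancy to
  machine precision. Fitted laws (time in months): Weibull OS
  (shape 1.19536, scale 25.48855) and log-normal PFS (meanlog 1.88660,
  sdlog 1.23141) for the immunotherapy arm; log-logistic OS
  (1.7027, 14.1088) and PFS (2.185, 7.392) for chemotherapy.
* **Decision statistics.** ICER = ΔC/ΔE from unrounded deltas;
  NMB = WTP·QALY − cost; willingness-to-pay threshold $207,659/QALY
  (3 × 2021 US GDP per capita).
* **Uncertainty.** One-way ±20% sweeps ranked into a tornado; second-order
  Monte Carlo (10,000 iterations) with gamma-distributed costs and
  beta-distributed probabilities/utilities, summarised as a
  cost-effectiveness acceptability curve (CEAC).

## Worked example

```bash
python examples/base_case.py
```

prints

```
chemotherapy           cost $   98,768.48   LY 1.7752   QALY 0.9842
nivolumab_ipilimumab   cost $  549,974.06   LY 1.9021   QALY 1.0814

incremental cost  $451,205.58
incremental QALYs  0.0973
ICER              $4,639,528.90 per QALY

At $207,659/QALY the immunotherapy combination is NOT cost-effective.
```

Each arm row is its discounted 10-year total cost, life-years and
quality-adjusted life-years; the ICER is the extra spend per QALY gained by
choosing the immunotherapy combination, compared against the
willingness-to-pay line to reach the verdict. The qualitative conclusion —
immunotherapy is not cost-effective at US prices, and no probabilistic
iteration reverses that — reproduces the published analysis; the magnitudes
differ from the published table, which is internally inconsistent with its
own printed inputs (see `docs/methods.md` for the reproduction analysis).

Other entry points: `examples/price_threshold.py` (price-reduction search +
tornado), `examples/probabilistic_sensitivity.py` (PSA + CEAC),
`examples/km_reconstruction.py` (simulate → digitize → reconstruct → refit),
and a CLI mirroring them:

```bash
mesocea base-case --out results/
mesocea psa --n 10000 --seed 1 --out results/
mesocea dsa --out results/
mesocea threshold --out results/
mesocea simulate --family weibull --params 1.2,25 --n 300 --out sim/
mesocea reconstruct-km --curve sim/km_curve.csv --risk-table sim/risk_table.csv --out rec/
```

All inputs load from a validated YAML config
(`src/mesocea/data/default_config.yaml` is the shipped base case); pass
`--config` to override.

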