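# nedose

Norepinephrine (NE) dose is the everyday severity compass of septic shock:
clinicians read mortality risk off dose thresholds (0.1, 0.25, 1.0 µg/kg/min)
and trigger therapies on them. But NE is marketed both as the free **base
molecule** and as **salt formulations** — tartrate, bitartrate, hydrochloride —
that contain less active base per milligram, and charts rarely say which
convention is in use. `nedose` is a tested analysis pipeline that quantifies
how much that bookkeeping choice distorts mortality prediction, for intensive
care researchers and anyone building or auditing vasopressor-based risk
models.

## The model

A salt-reported dose is a rescaled base dose, `d_f = c_f · d_base`, with
`c = 1.22` (hydrochloride), `1.89` (bitartrate), `2` (tartrate). If 28-day
mortality follows a logistic dose–response on the base scale,

```
logit Pr(death) = α + β·d_base ,
```

then under convention *f* the same data give `β_f = β / c_f`, so the per-unit
odds ratio becomes `OR^(1/c_f)` and predictions obey the equivariance
`p_f(d) = p_base(d / c_f)`. With a base-scale OR of 9.4 per µg/kg/min, salt
reporting shrinks the apparent OR by 33% / 65% / 67% — and because the curve
is sigmoid, the predicted-mortality gap between conventions *widens* with
dose. Same patients, same outcomes, different arithmetic.

The package implements, with tests against independent oracles:

* formulation conversion and the norepinephrine-equivalent (NEE) score for
  multi-vasopressor regimens (config-driven weights);
* a synthetic MIMIC-like event-table generator (five tables: patients,
  infusions, labs, infection events, SOFA) with latent truths retained;
* Sepsis-3 septic-shock screening with a reproducible exclusion ledger;
* stability-filtered peak-dose extraction from infusion streams (highest rate
  stable within 10% for ≥ 5 min) plus diagnosis dose and NEE peak;
* logistic dose–response fits per reporting convention (separate, interaction
  and random-intercept variants), delta-method CIs, and threshold tables.

## Worked example

```
python analysis/01_simulate_cohort.py --seed 0   # 4086 patients
python analysis/02_screen_cohort.py
python analysis/03_fit_dose_response.py
python analysis/04_threshold_tables.py
```

The simulated cohort lands on the intended structure — `latent peak dose
median [IQR]: 0.24 [0.13-0.46] µg/kg/min`, `28-day mortality: 42.4%`, `second
vasopressor: 58.3%` — and the screen retains all 4086 patients with the
extracted peak doses matching the latent ones. The peak-dose fit then prints

```
peak dose (n=4086):
  base molecule OR per ug/kg/min: 18.26 (95% CI 13.85-24.07)
  hydrochloride  OR  10.81  (40.8% lower; rescaling residual 0.0e+00)
  bitartrate     OR   4.65  (74.5% lower; rescaling residual 8.9e-16)
  tartrate       OR   4.27  (76.6% lower; rescaling residual 0.0e+00)
```

— the same cohort, scored under four conventions, spans a four-fold range of
per-unit odds ratios, and the fitted slopes satisfy the rescaling identity to
machine precision. The threshold table makes the clinical stakes concrete: at
a *reported* peak dose of 1.0 µg/kg/min the anchored curves predict

```
base-vs-tartrate divergence (anchored peak curve): 3 points at 0.1, 29 points at 1.0 ug/kg/min
```

i.e. 83% vs 54% predicted mortality depending on which convention the chart
silently used. A `nedose` CLI wraps the same stages
(`nedose simulate|screen|doses|fit|report --seed ... --out ...`).

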