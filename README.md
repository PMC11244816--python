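# neoquad

Age- and cause-specific mortality estimation **within** the neonatal
period (0–28 days), for settings where causes of death come from verbal
autopsy and vital statistics are incomplete.

Cause-specific neonatal mortality is usually reported only for the whole
0–28-day window, yet the causes are strongly age-structured: prematurity
and birth asphyxia dominate the first days of life, sepsis the later
weeks. This package estimates *cumulative* cause-specific mortality at
higher age resolution — by default at 24 h, 48 h, 7 days and 28 days —
from quarterly life tables, and quantifies how well that age pattern can
be predicted out of sample.

## The model

For cumulative age group *x* and cause *c*, with `nmr` the all-cause
neonatal mortality rate of a life table (one calendar quarter), the
adapted log-quadratic model is

```
log q(x,c) = a(x,c) + b(x,c)·log nmr + c(x,c)·(log nmr)² + v(x,c)·k
```

* `a, b, c` — quadratic coefficients, fit per age group by OLS across
  training quarters (zero cells replaced by a 1e-5 offset before logs);
* `v` — deviation vector: the first right singular vector of the
  training residual matrix, normalized so v = 1 at 28 days;
* `k` — per-life-table shape parameter. With `k = 0` the model gives the
  *typical* age pattern at that mortality level. Calibrating `k` to an
  observed cause-specific NMR has a closed form (because v(28d) = 1) and
  reproduces that NMR exactly at 28 days.

The comparator ("standard approach") spreads the 28-day cause-specific
risk uniformly over the period: `q(x,c) = cause_nmr · hours(x)/672`.

Model performance is measured by leave-one-quarter-out cross-validation:
fit on 24 quarters, predict the held-out quarter's age pattern given its
observed mortality level, average the absolute (and, for common causes,
relative) errors over the 25 holdouts.

Because the real surveillance cohort that motivates this design is not
public, the package ships a record-level synthetic cohort generator
emulating its structure (25 quarters, NMR declining 35.3 → 27.9 per
1000 live births, 41/15/25/19% deaths across the four age bands, an
age-varying cause profile, 5% missing death times, 0.2% missing verbal
autopsies), so the entire analysis is reproducible from a seed.

## Worked example

The numbered scripts under `analysis/` run the whole study and write
their outputs under `results/`:

```
python analysis/01_simulate_cohort.py
python analysis/02_build_life_tables.py
python analysis/03_fit_logquad.py
python analysis/04_cross_validate.py
python analysis/05_plot_age_patterns.py
```

The first two stages print

```
simulated 1144 neonatal deaths among 35000 live births over 25 quarters (crude NMR 32.7 per 1000)
retained 1088/1144 deaths (95%); exclusions: {'no_time': 54, 'no_va': 2, 'post_neonatal': 0, 'out_of_range': 0}
built 25 quarterly life tables; NMR range 22.9-46.4 per 1000
```

and the cross-validation stage prints the error table (absolute errors
in probability per live birth, 5 decimal places; an excerpt):

```
   cause age_label  abs_err_k0  abs_err_best_k  abs_err_standard  rel_err_k0  rel_err_best_k  rel_err_standard
 preterm 0h-6 days     0.00253         0.00080           0.00814       0.227           0.073             0.732
 preterm 0h-4weeks     0.00237         0.00000           0.00000       0.209           0.000             0.000
asphyxia 0h-6 days     0.00230         0.00094           0.00724       0.235           0.101             0.723
asphyxia 0h-4weeks     0.00209         0.00000           0.00000       0.193           0.000             0.000
```

Reading: predicting the first-week cumulative preterm mortality of a
held-out quarter with the best-k log-quadratic model is off by 0.8 per
1000 live births on average, versus 8.1 per 1000 for the uniform
allocation — a tenfold improvement for the strongly age-concentrated
causes. The 0.00000 entries at 0h-4weeks are structural: both best-k
calibration and the uniform baseline reproduce the observed 28-day
cause-specific NMR exactly. Relative errors are suppressed (NaN) for
sepsis, pneumonia and congenital malformations, whose observed quarterly
rates are often zero.

The same pipeline is available as a CLI (`neoquad simulate | tabulate |
fit | cv | plot`); all randomness flows from `--seed`.

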