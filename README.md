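# tdpe

Temporal-difference prediction-error (PE) modelling for a probabilistic
taste-conditioning fMRI task, with dopamine-genotype group statistics.

## The problem

In reinforcement-learning accounts of dopamine function, a phasic PE
signal δ is emitted when reward outcomes deviate from learned
predictions: positive on unexpected reward receipt, negative on
unexpected omission. Model-based fMRI studies regress a computed
trial-wise PE signal against striatal BOLD response and then ask what
explains the between-subject variation in that response. This package
implements that full analysis chain for a taste-conditioning design in
which three visual cues probabilistically predict sucrose, no solution,
or a neutral artificial-saliva control, and tests whether dopamine D2
receptor polymorphisms (the DRD2 promoter −141C Ins/Del, rs1799732, and
the ANKK1/DRD2 Taq1A, rs1800497) together with body mass index explain
per-subject striatal PE response — the hypothesis being that higher BMI
and higher major-allele dosage go with lower PE response.

It is written for computational-psychiatry and neuroimaging-genetics
researchers who want a tested, fully scriptable version of this
pipeline, and includes a synthetic-data generator so every stage runs
and is verifiable without any imaging or genotype data.

## The model

**Task.** 280 trials at a fixed 6-s onset spacing (28 min): 100 sucrose,
100 no-solution, 80 saliva deliveries. 20% of sucrose-cue trials deliver
no solution (negative PE) and 20% of no-solution-cue trials deliver
sucrose (positive PE); the first 10 trials are fixed congruent sucrose
pairings. Violation counts are exact design constants, not draws.

**TD model** (complete serial compound, three 1-s bins per trial, US in
the last bin):

    V̂(t)  = Σᵢ wᵢ xᵢ(t)
    δ(t)  = r(t) + γ·V̂(t+1) − V̂(t),     γ = 0.99
    Δwᵢ   = α·Σₜ xᵢ(t)·δ(t),             α ∈ {0.2, 0.5, 0.7}, default 0.7

with r = 1 for sucrose and 0 otherwise. The per-trial regressor is
|δ(US bin)| — response strength, sign-blind.

**First level.** The |PE| impulse train at US onsets is convolved with
the canonical double-gamma HRF and sampled at the TR grid (TR 2.1 s,
800 volumes); OLS on each ROI time series yields the subject's PE
parameter estimate β_PE.

**Group level.** Enter-method multiple regression of ROI β_PE on
BMI + genotype codes (D2: −141C, Taq1A; and parallel D1 / COMT-DAT-DRD4
groupings), with standardized β, case-resampling bootstrap p-values and
percentile CIs, tolerance/VIF collinearity screening (VIF > 5 flagged),
Shapiro–Wilk-triggered rank transforms, and Bonferroni correction across
the 8 bilateral reward-circuitry ROIs. Genotypes are coded ordinally by
major-allele dosage (Del/Del = 1, Ins/Del = 2, Ins/Ins = 3; A1/A1 = 1,
A1/A2 = 2, A2/A2 = 3), Hardy–Weinberg equilibrium is checked with the
exact conditional test, and a summary score BMI + code(−141C) +
code(Taq1A) supports a single-regressor analysis.

## Worked example

```python
import numpy as np
from tdpe import (generate_schedule, simulate_td, pe_regressor, TDParams,
                  AcquisitionParams, build_design, FirstLevelModel)

sched = generate_schedule(seed=1)                 # 280 trials, 28 min
trace = simulate_td(sched, TDParams(alpha=0.7))
pe = pe_regressor(trace, sched)                   # |delta| at the US bin
print(pe.pe[:3])                                  # [1.   0.3  0.09]  (fixed congruent block)

design = build_design(pe, AcquisitionParams())
ts = 3.5 * design["pe"].to_numpy() + 7.0          # noiseless synthetic ROI
print(FirstLevelModel(ts, design).fit().summary())
```

```
First-level ROI GLM (OLS)
  subject: None  roi: None  n volumes: 800
  beta_pe:    3.5
  R-squared: 1.0000
  resid sd:  1.27908e-15
```

The first trials print `1.0, 0.3, 0.09`: with all weights at zero the
first sucrose delivery is fully unexpected (δ = 1), and on a congruent
run the US-bin PE decays geometrically as (1 − α)ⁿ⁻¹ = 0.3ⁿ⁻¹. The
noiseless fit returns exactly the generating slope 3.5 with R² = 1.

A full synthetic study (cohort → BOLD → first level → group regression):

```sh
tdpe all --seed 11 --out-dir run --bootstrap 1000
```

writes `events.tsv`, `pe.tsv`, `cohort.csv`, `hwe.csv`,
`first_level.csv` and `table1_shaped_results.csv` (one row per
predictor × ROI × grouping with standardized β, bootstrap p, tolerance,
VIF, model F and Bonferroni-adjusted model p), plus a `run_log.json`
recording seeds and settings. Runs are byte-identical for a given seed.

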