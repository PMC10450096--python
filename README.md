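# jitaema

Just-in-time adaptive ecological momentary assessment (EMA): a toolkit for
measuring momentary psychological states — the running example is momentary
fatigue — efficiently enough to drive just-in-time adaptive interventions
(JITAI).

Mobile interventions that react to a person's *current* state need momentary
classifications ("is fatigue elevated right now?") that are both accurate and
cheap to obtain: long in-the-moment surveys burn participants out, short ones
are noisy, and noisy measurement turns tailored treatment timing into coin
flips.  This package applies computerized classification testing (CCT) to
EMA: at each prompt it adaptively selects the most informative items from a
calibrated item bank, stops as soon as the person's state is classified with
requisite confidence, and supports classification cutoffs that are tailored
to the person and time of day.

It is intended for quantitative/psychometric researchers designing EMA
protocols or JITAI tailoring rules, and is used from Python (a thin
`jitaema` command-line interface wraps the same functions for scripted
runs).

## The model

Items follow the graded response model (GRM).  Item *j* with discrimination
*a<sub>j</sub>* and ordered thresholds *b<sub>j1</sub> < … <
b<sub>j,K−1</sub>* yields, at latent state θ (z-standardized),

> P(X<sub>j</sub> ≥ k | θ) = logistic(a<sub>j</sub>(θ − b<sub>jk</sub>)),  
> P(X<sub>j</sub> = k | θ) = P(X<sub>j</sub> ≥ k) − P(X<sub>j</sub> ≥ k+1).

States are scored by maximum a posteriori (MAP) estimation under a N(0, 1)
prior; the standard error of measurement is
SE = (1/σ<sub>prior</sub>² + Σ<sub>j</sub> I<sub>j</sub>(θ̂))<sup>−1/2</sup>
with I<sub>j</sub> the item Fisher information.  Items are selected by the
maximum expected information (MEI) criterion: candidate information at the
hypothetically updated estimate, weighted by predictive response
probabilities.  A session stops when the Wald interval θ̂ ± z·SE excludes the
classification cutoff (or at a 5-item cap).

Dynamic cutoffs come from a per-person cosinor regression on clock time,

> θ<sub>i</sub> = β₀ + β₁ sin(2πh<sub>i</sub>/24) + β₂ cos(2πh<sub>i</sub>/24) + r<sub>i</sub>,

with the cutoff set half a residual SD above the expected level for the
current hour.  A study simulator generates synthetic persons with
idiographic diurnal cycles and runs five item-selection conditions (2/3/5
fixed items, variable-length, fully adaptive) over identical ground truth;
evaluation reports median-person sensitivity/specificity (random-intercept
logistic model by Gauss–Hermite quadrature), Cohen's kappa from
sensitivity/specificity/prevalence, and items-per-prompt variance
decompositions.

## Worked example

```python
from jitaema import run_study, study1_config, summarize_condition

cfg = study1_config(n_persons=15, n_days=10, master_seed=42)
result = run_study(cfg)
for cond in cfg.conditions:
    s = summarize_condition(result.condition(cond), n_boot=0)
    print(f"{cond:<10} items={s.mean_items:.2f} Se={s.sensitivity:.2f} "
          f"Sp={s.specificity:.2f} kappa={s.kappa:.2f}")
```

prints (uniform cutoff z = 1.0, 762 prompts per condition):

```
fixed2     items=2.00 Se=0.57 Sp=0.98 kappa=0.62
fixed3     items=3.00 Se=0.60 Sp=0.97 kappa=0.63
fixed5     items=5.00 Se=0.68 Sp=0.98 kappa=0.71
variable   items=2.67 Se=0.75 Sp=0.98 kappa=0.76
jita       items=2.28 Se=0.74 Sp=0.99 kappa=0.77
```

Reading: fixed-length accuracy grows with survey length; the adaptive
condition (`jita`) matches or beats the 5-item fixed assessment while asking
under half as many questions per prompt — the point of adaptive EMA.  The
`examples/` scripts walk through each capability (bank construction and
scoring, a single adaptive session, diurnal cutoffs, full simulated studies
with weekly breakdowns and cutoff-error curves).

The same runs are available from a shell:

```bash
jitaema make-bank --out bank.csv --seed 1
jitaema simulate --preset study1 --persons 15 --days 10 --seed 42 --out run/
jitaema evaluate --records run/records.csv --out eval/ --weekly
```

## Layout

- `src/jitaema/bank.py` — GRM item banks: validation, CSV/JSON I/O, synthetic generation
- `src/jitaema/irt.py` — GRM probabilities, information, MAP scoring, response simulation
- `src/jitaema/engine.py` — adaptive sessions: selection, stopping, classification
- `src/jitaema/cutoffs.py` — cosinor fits, dynamic cutoffs, run-in/daytime gating
- `src/jitaema/simulate.py` — synthetic populations, schedules, five-condition studies
- `src/jitaema/evaluate.py` — sensitivity/specificity/kappa, variance decomposition, cutoff RMSE
- `src/jitaema/cli.py` — `jitaema` command-line interface
- `docs/methods.md` — modeling assumptions, defaults, and limitations
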