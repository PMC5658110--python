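# mddcea

Lifetime cost-effectiveness analysis of repetitive transcranial magnetic
stimulation (rTMS) versus continued antidepressant pharmacotherapy in adults
with newly diagnosed major depressive disorder (MDD) who have failed one
medication trial.

The package is written for health-economics and psychiatry researchers who
want a transparent, scriptable re-implementation of this decision problem: a
two-arm decision tree feeding a discrete-time cohort Markov model over the
patient's remaining lifetime, with full deterministic and probabilistic
sensitivity machinery.

## The model

Each arm expands into an annual-cycle state space

```
in_treatment(1..4) → {remission_maintenance, response_maintenance, next attempt}
after 4 failures   → ECT (fallback, until remission)
maintenance        → relapse → re-treatment (attempt counter resets)
all states         → death (absorbing)
```

The probability of succeeding on attempt *k* diminishes multiplicatively with
each prior failure: `p(k) = p(1) · a^(k−1)` with attenuation `a ∈ (0, 1]`.
Background mortality is an annual hazard `1/LE` (LE = the cohort's likely
additional life expectancy) applied as a competing risk each cycle, with a
hard stop at the lifetime horizon.

A unit cohort `x₀` is propagated by row-stochastic matrices `P`,
`x_{t+1} = x_t P`, and rewarded per state-year: USD costs built from
Medicare-style unit rates (CPT 90867/90868/90869 for rTMS, monthly drug
supply, psychotherapy, ECT, other direct medical costs) and Euro-QoL
utilities in [0, 1].  Lifetime totals discount at `r = 3%/year`:

```
Cost = Σ_t Σ_s x_t[s] · c(s) / (1+r)^t        QALY = Σ_t Σ_s x_t[s] · u(s) / (1+r)^t
```

The economics layer compares the arms by incremental cost-effectiveness
ratio `ICER = ΔC/ΔQ`, net monetary benefit `NMB = Q·λ − C` (λ = willingness
to pay; at λ = 0 the least costly arm has the highest NMB), and strict
dominance (lower cost AND more QALYs).  Sensitivity analyses cover one-way
threshold finding by bisection, tornado ranking of NMB spreads, and a
1,000-draw probabilistic sensitivity analysis sampling beta/gamma
distributions moment-matched to each parameter's range.

The original analysis's full variable and distribution tables are
unpublished; the bundled cohort scenarios pin every value its main text
prints ($206/session, $372.50/month drug supply, 25.3 sessions/year, 3%
discount, cohort life expectancies, $9,140/year other direct costs) and fill
the rest with documented reconstructions (see `docs/methods.md`).

## Worked example

```python
from mddcea import ScenarioSpec, generate_parameter_set, run_strategy, compare_strategies

ps = generate_parameter_set(ScenarioSpec(seed=0, cohort="mid-50s"))
print(run_strategy(ps, "rTMS"))
print(run_strategy(ps, "pharmacotherapy"))
print(compare_strategies(ps).dominance)
```

prints (bundled mid-50s scenario, 16-year horizon):

```
StrategyOutcome(label='rTMS', cost=130141.31..., qaly=5.8797...)
StrategyOutcome(label='pharmacotherapy', cost=128801.79..., qaly=5.6396...)
trade-off
```

i.e. under the reconstructed clinical inputs the rTMS arm buys 0.24 extra
QALYs for an extra $1,340 over the patient's remaining lifetime — an ICER of
about $5,600/QALY, far below the $100,000/QALY US threshold.  Applying the
same economics layer to the *published* per-arm totals instead reproduces
the printed dominant base case exactly (e.g. mid-20s: rTMS saves $11,140 and
gains 0.43 QALYs); run `python examples/02_published_icer_rows.py`.

The `examples/` directory has one short script per capability: base case,
published-totals ICER arithmetic, one-way thresholds, tornado, PSA.

A thin CLI wraps the same pipeline:

```
mdd-cea run --cohort 50s --out-dir out/
mdd-cea oneway --cohort 50s --parameter cost_per_rtms_session --out-dir out/
mdd-cea tornado --cohort 50s --out-dir out/
mdd-cea psa --cohort 50s --n 1000 --seed 1 --out-dir out/
mdd-cea generate-scenario --cohort 40s --regime random-valid --out scenario.yaml
```

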