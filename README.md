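# nsclineage

Feedback-regulated ODE models of the adult neural stem cell (NSC)
lineage in the mouse ventricular–subventricular zone, with the full
inference pipeline around them: simulation, steady-state and stability
analysis, weighted-least-squares fitting with AICc model selection,
Adaptive Metropolis uncertainty quantification, perturbation experiments
(chemotherapy ablation, interferon-receptor knock-out), and a
synthetic-data generator that emulates cross-sectional mouse studies.

It is written for systems biologists and modellers who want to ask
*which lineage populations regulate NSC activation and self-renewal*:
candidate feedback wirings are fitted to longitudinal cell-count data
and compared by information criteria.

## The model

Quiescent NSCs `Q` activate at rate `r` into active NSCs `A`, which
divide (rate `pA`) into two NSCs with probability `b` (self-renewal) or
two transient amplifying progenitors (TAPs); TAPs amplify through
`n + 1` compartments (rate `pT`) into neuroblasts `N`, which exit at
rate `delta`:

    Q' = -rQ + 2 b pA A
    A' =  rQ - pA A
    T0' = 2(1-b) pA A - pT T0,   Ti' = 2 pT T(i-1) - pT Ti
    N' = 2 pT Tn - delta N

The feedbacks are Hill-type functions of population sizes,

    r = (r1 + r0 c1)/(K + c2),      b = b0/(1 + beta c3),

and a *scenario* names the populations wired into `c1, c2, c3` (e.g.
`"r(Q,A),b(Q)"`: quiescent NSCs promote and active NSCs inhibit
activation, quiescent NSCs inhibit self-renewal).  Because
`(Q + A)' = (2b - 1) pA A`, the stem cell pool is doomed to decay unless
`b0 > 1/2`, in which case a unique stable positive steady state exists
at which the realized self-renewal is exactly one half.

## Worked example

```python
import numpy as np
import nsclineage as nl

# 1. a synthetic cross-sectional mouse study (4 mice x 8 ages, known truth)
cfg = nl.GeneratorConfig(ages=nl.default_ages(8), seed=0)
data = nl.generate_dataset(cfg)

# 2. fit two competing feedback scenarios
fits = [nl.fit_multistart(data, name, "WT", n_starts=150, seed=1)
        for name in ("r(Q,A),b(Q)", "r(Q,A),b(N)")]

# 3. compare them
table = nl.build_selection_table(fits)
print(table[["scenario", "E", "AICc", "deltaAICc", "weight"]].to_string(index=False))
```

prints (seed 0):

```
   scenario          E      AICc  deltaAICc       weight
r(Q,A),b(Q) 130.511312 10.812197   0.000000 1.000000e+00
r(Q,A),b(N) 239.772894 88.665931  77.853734 1.242443e-17
```

The generating scenario (`r(Q,A),b(Q)`) fits with roughly half the
weighted cost `E` of the alternative and takes essentially all of the
Akaike weight; its fitted self-renewal parameters land close to the
generating values (`b0 = 0.70`, `beta = 1.33e-3`):

```python
print({k: round(v, 4) for k, v in fits[0].theta.items()})
# {'r0': 0.0067, 'K': 80.6708, 'b0': 0.6895, 'beta': 0.0013}
```

Steady-state analysis of the fitted model:

```python
p = nl.ModelParameters(**{**fits[0].fixed, **fits[0].theta})
for eq in nl.steady_states(p, nl.get_scenario("r(Q,A),b(Q)")):
    print(eq.kind, "stable" if eq.stable else "unstable",
          np.round(eq.state[:2], 1))
# trivial unstable [0. 0.]
# positive stable [295.2   7. ]
```

i.e. the pool declines from 1900 towards a stable residual population of
~300 NSCs — the quantitative signature of neurogenic ageing in this
model family.

A command-line pipeline wraps the same stages:

```bash
nsclineage generate --config gen.yaml --out run/
nsclineage fit --data run/dataset.csv --setting WT --scenario "r(Q,A),b(Q)" --starts 500 --seed 1
nsclineage select --fits fits/
nsclineage mcmc --fit out_fit/fit.json --data run/dataset.csv --samples 250000 --seed 1
```

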