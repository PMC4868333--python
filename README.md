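# pulsechase

Pulse-length-aware analysis of macromolecule decay from pulse-chase
experiments.

## The problem

Pulse-chase experiments measure the degradation of proteins or mRNA: newly
synthesized molecules are labeled during a *pulse* of length *t_p*, and the
surviving labeled abundance is tracked during the *chase*.  When decay is
non-exponential — as it is for most molecules whose degradation passes
through several biochemical stages — the shape of the decay pattern depends
on *t_p*: a longer pulse labels an older, slower-decaying cohort.  Fitting
such patterns while ignoring the pulse length yields biased rates and a
half-time that is a property of the experiment, not of the molecule.

`pulsechase` implements the analysis for the two-stage Markov model of
degradation.  A molecule is born in state 1, leaves it with rate
κ₁₀ + κ₁₂ (direct degradation κ₁₀, transit to state 2 with κ₁₂), and
degrades from state 2 with rate κ₂₀.  The lifetime *T* is the absorption
time of this chain — a phase-type distribution with survival function

    S(t) = w₁·e^(−λ₁t) + w₂·e^(−λ₂t),   λ₁ = κ₁₀ + κ₁₂,  λ₂ = κ₂₀,
    w₂ = κ₁₂/(λ₁ − λ₂),  w₁ = 1 − w₂.

The chase decay pattern after a pulse of length *t_p* is the closed form

    C(Δt) = [A_c·e^(−λ₁Δt) + B_c·e^(−λ₂Δt)] / (A_c + B_c),
    A_c = (κ₁₀ − κ₂₀)/λ₁ · [1 − e^(−λ₁ t_p)],
    B_c = κ₁₂/κ₂₀ · [1 − e^(−κ₂₀ t_p)],

one formula valid for any pulse length, including the synthesis-shutoff
limit *t_p* → ∞.  A matching closed form covers pulse-only ("pulse,
no-chase") accumulation measurements, P(Δt) = N(Δt)/N^(st).  Rates are
estimated by bounded multistart least squares on log abundances (assuming
lognormal measurement error), optionally pooling experiments with different
pulse lengths; from the fitted rates the package derives the mean lifetime
T̄ = 1/λ₁ + κ₁₂/(λ₁κ₂₀), true and apparent half-times, state occupancies,
steady-state abundance N^(st) = ωT̄, and local parameter sensitivities of
the pulse-only output.

Intended users: quantitative biologists analyzing pulse-chase / metabolic
labeling decay data, and modelers who need a well-tested reference
implementation of pulse-aware phase-type decay fitting.

## A worked example

Fabricate a decay pattern from known rates, refit it, and derive stability
quantities (`examples/02_fit_recovery.py`):

```python
from pulsechase import RateSet, fabricate_pattern, fit

truth = RateSet(kappa10=0.0109, kappa12=0.0189, kappa20=0.0002)  # 1/min
pattern = fabricate_pattern(truth, pulse_length=1.0)  # chase, 0..480 min
result = fit(pattern, starts=200, seed=1)
```

prints

```
generating rates (1/min):  kappa10=0.0109  kappa12=0.0189  kappa20=0.0002
recovered rates  (1/min):  kappa10=0.0109  kappa12=0.0189  kappa20=0.0002
objective M = 1.53e-30 (squared-log units; 0 = perfect)
```

The multistart fit returns exactly the generating rates — the pulse-aware
closed form makes all three rates identifiable from a single short-pulse
pattern.  The same rates give a mean lifetime of 3204.7 min (53.4 h), while
the apparent half-time read off the curve ranges from 1249 min (1-min
pulse) to 3447 min (infinite pulse) — the bias the method corrects
(`examples/01_decay_curves.py`):

```
 pulse (min)  C(120 min)   apparent t1/2 (min)
           1      0.6367                1249.2
          30      0.7175                1872.1
        1200      0.9597                3377.5
         inf      0.9727                3446.8
```

The other examples cover pooled fitting under noise, AIC model selection
against the one-stage (exponential) model, a 100 000-molecule Monte-Carlo
cross-check of the closed forms, and the closed-form sensitivities
validated against finite differences.

There is also a thin CLI:

```sh
pulsechase simulate --kappa10 0.0109 --kappa12 0.0189 --kappa20 0.0002 \
    --pulse 1 --pulse 30 --out-dir patterns/
pulsechase fit patterns/p1.csv patterns/p30.csv --starts 1000 --json-out fit.json
pulsechase derive --kappa10 0.0109 --kappa12 0.0189 --kappa20 0.0002
```

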