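# cgtree

Survival analysis under **dependent censoring**: copula-graphic survival
estimation, a two-sample permutation test on the integrated distance of
copula-graphic estimators, and survival trees that use this test as their
splitting criterion.

## The problem

Kaplan–Meier curves and the logrank test assume that censoring carries no
information about survival. In clinical data that assumption often fails —
e.g. when sicker patients drop out, or when transplantation removes
patients who were about to die — and the usual estimators are then biased
(optimistically so under positive dependence). `cgtree` is for
biostatisticians who want two-group comparisons and prognostic trees that
make the dependence explicit instead of assuming it away.

## The model

Event time T and censoring time C are coupled through an Archimedean
copula on the survival scale,

    P(T > t, C > s) = φ⁻¹( φ(S_T(t)) + φ(S_C(s)) ),

with Clayton (φ(u) = (u^−θ − 1)/θ, Kendall's τ = θ/(θ+2)), Frank, and
independence (φ(u) = −log u) generators. Given an assumed τ, the
**copula-graphic estimator** (CGE) of S_T is

    Ŝ(t) = φ⁻¹( Σ_{xᵢ ≤ t, δᵢ=1} [ φ((Rᵢ−1)/n) − φ(Rᵢ/n) ] ),

where Rᵢ is the at-risk count just before the event at xᵢ; with the
independence generator this is exactly Kaplan–Meier.

Two groups are compared with the time-normalized integrated absolute CGE
distance

    L1 = (1/t*) ∫₀^{t*} | Ŝ₁(t) − Ŝ₂(t) | dt,   t* = min(max x₁, max x₂),

whose null distribution is obtained by permuting the pooled
(time, indicator) pairs over group assignments (Monte-Carlo p-value, the
observed assignment always counted). The signed version L̃1 orders the
groups by prognosis. The **survival tree** grid-searches all
(covariate, cutoff) splits, accepts the split with the smallest
permutation p-value if it is below a threshold p̃ (default 0.01), places
the better-surviving child on the right, and numbers terminal nodes right
to left so node 1 always has the best prognosis.

## Worked example

```python
import numpy as np
from cgtree import (PHConfig, simulate_ph, archimedean_copula,
                    SurvivalSample, TwoSampleData, permutation_test)

# two groups of 150, hazard ratio exp(-0.4), 50% calibrated censoring,
# Clayton-dependent censoring with Kendall tau 0.5
cop = archimedean_copula("clayton", 0.5)
df = simulate_ph(PHConfig(n1=150, n2=150, beta=-0.4, r=0.5, copula=cop, seed=7))
g1, g2 = df[df.group == 1], df[df.group == 2]
data = TwoSampleData(
    SurvivalSample(g1.time.to_numpy(), g1.event.to_numpy()),
    SurvivalSample(g2.time.to_numpy(), g2.event.to_numpy()),
)
res = permutation_test(data, cop, nperm=1000, seed=1)
print(f"L1 = {res.l1:.4f}, signed = {res.l1_signed:.4f}, p = {res.p_value:.3f}")
```

prints

```
L1 = 0.2579, signed = -0.2577, p = 0.001
```

L1 ≈ 0.26 means the two CGE curves differ by about 26 survival-probability
points on average over the common observation window; the negative signed
value says group 2 (the β = −0.4 arm) survives longer; p = 0.001 is the
smallest value attainable with 1000 permutations, so the difference is
clearly significant.

Growing a tree works the scikit-learn way:

```python
from cgtree import CGESurvivalTree
tree = CGESurvivalTree(family="clayton", tau=0.25, p_threshold=0.01,
                       nperm=1000, random_state=0)
tree.fit(X, (times, events))          # X: (n, p) covariate array
tree.predict(X)                        # terminal node numbers, 1 = best
tree.predict_survival(X, t_grid)       # CGE survival probabilities
print(tree.to_dot())                   # Graphviz export
```

A command-line interface mirrors the library:
`cgtree test|tree|cv-tau|simulate|study --help`. The `tree` and `cv-tau`
subcommands run end to end on any user-supplied survival CSV (e.g. a
clinical-trial table with an observed-time column, a 0/1 event column and
numeric covariates); `cv-tau` produces the cross-validated table
(terminal nodes, Harrell's C, integrated Brier score) used to choose the
assumed τ.

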