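# Methods

## Model and estimators

Right-censored data are pairs (xᵢ, δᵢ) with xᵢ = min(Tᵢ, Cᵢ) and
δᵢ = 1(Tᵢ ≤ Cᵢ). The joint survival function of event time T and
censoring time C is modelled with an Archimedean copula,
P(T > t, C > s) = φ⁻¹(φ(S_T(t)) + φ(S_C(s))), so the marginal survival
function is identifiable once the copula (family and Kendall's τ) is
assumed. Three generators are implemented: Clayton
φ(u) = (u^−θ − 1)/θ with τ = θ/(θ+2) (lower-tail dependence, the default
working family), Frank (no tail dependence, used for
misspecification checks), and independence φ(u) = −log u. τ ↦ θ for
Frank is solved by Brent root-finding on the generator integral
τ = 1 + 4∫₀¹ φ/φ′ (tolerance 1e−10); no series approximation is used
because the conversion runs once per analysis. Dependent uniform pairs
are sampled with the conditional-distribution method, which has a
closed-form conditional inverse for both families. Negative τ is
supported for Clayton (θ ∈ [−1, 0)) with a warning; every study setting
in this package uses τ ≥ 0.

The copula-graphic estimator (CGE) is computed as

  Ŝ(t) = φ⁻¹( Σ_{xᵢ ≤ t, δᵢ=1} [ φ((Rᵢ−1)/n) − φ(Rᵢ/n) ] ),

with Rᵢ the at-risk fraction numerator just before the i-th event: the
naive pooled survival fraction π̂(t) = #{xⱼ > t}/n enters through its left
limit π̂(xᵢ−) = Rᵢ/n. This convention is what makes the estimator reduce
*exactly* to the Kaplan–Meier product-limit estimator under the
independence generator (verified to 1e−10 on random samples, including
heavy ties); evaluating π̂ right-continuously instead breaks that
reduction. d tied events at one time consume the risk set one by one, so
their summed contribution telescopes from Rᵢ/n down to (Rᵢ−d)/n and the
KM equivalence survives ties. Tied events and censorings are ordered
events-first (the standard risk-set convention). When the largest
observation is an event the final generator argument is 0 and
φ(0⁺) = +∞ for all three families with positive dependence, so the
pseudo-inverse truncates the curve to exactly 0 — no epsilon flooring is
needed. All curves are right-continuous nonincreasing step functions on
[0, max xᵢ], equal to 1 at t = 0, clipped to [0, 1]; evaluation beyond
the domain raises unless constant extrapolation is requested explicitly
(prediction does request it). A Clayton closed form is kept as a second,
independent arithmetic path and agrees with the generic generator path to
1e−12 at every breakpoint.

## Two-sample permutation test

The test statistic is the time-normalized integrated absolute CGE
distance L1 = (1/t*)∫₀^{t*}|Ŝ₁ − Ŝ₂|dt with t* = min(max x₁, max x₂).
The lower integration limit (first pooled observation) is equivalent to 0
because both curves equal 1 before the first observed time; the
integration is exact (piecewise-constant integrand, merged breakpoints),
with no quadrature error. The signed variant L̃1 omits the absolute value;
L̃1 > 0 means group 1 has the larger integrated survival.

Because the null distribution of L1 is analytically intractable, a
permutation approach is used: (time, indicator) pairs are permuted
jointly across the pooled sample with group sizes fixed. The statistic
depends on a permutation only through the group assignment, so the n!
permutations collapse to C(n₁+n₂, n₁) distinct assignments; an
exhaustive enumerator (capped at 1e5 assignments, configurable) serves as
the exact reference, and the production test draws nperm − 1 uniformly
random assignments plus the observed one. The Monte-Carlo p-value counts
ties as extreme and includes the observed assignment in numerator and
denominator, so p ≥ 1/nperm and the test is valid (conservative) under
exchangeability. The randomized tie-breaking component that would make
the exact test achieve level α exactly is intentionally not implemented;
the Monte-Carlo, non-randomized test is used throughout. A vectorized
kernel evaluates all nperm assignments over one sorted pooled-time grid
(the float work is confined to event columns), which is what keeps
nperm = 1000 × tree grid search feasible; all assumed-τ variants share
the same random assignments, so comparisons across assumed τ are matched.

Comparators: the standard two-sample logrank test and the Peto–Peto
weighted variant, computed from risk-set tables with chi-square (1 df)
p-values. Peto–Peto weights use Peto's modified pooled survival estimate
Π(1 − d/(n+1)); this matches lifelines' "peto" convention exactly (the
cross-check oracle in the tests) and differs in the third decimal from
implementations that weight by the left-limit Kaplan–Meier curve.

## Survival tree

Recursive binary partitioning on single covariates: candidate cutoffs at
a node are the sorted unique covariate values excluding the maximum
(so the ">" child is nonempty); candidates leaving a child below
`min_child` (default 2, can be lowered to 1 to allow singleton leaves)
are skipped. Every candidate runs the permutation test on the induced
two groups; the split with the smallest p-value wins (ties: larger L1,
then lower covariate index, then lower cutoff — deterministic because
candidates are scanned in that order). A node is split only if the best
p-value is at or below `p_threshold` (default 0.01); this threshold and
the child-size floor are the only regularization — no multiplicity
correction is applied across the cutoff grid, a deliberately liberal
choice that mirrors how p-value-based trees are usually grown, and no
pruning or amalgamation is performed. The child with positive signed
statistic (longer survival) is placed on the right; terminal nodes are
numbered 1..K right to left, so node 1 always has the best prognosis and
high numbers mean short survival. Each terminal node stores the CGE
fitted on its members (with the tree's assumed copula) and its median
survival time; prediction routes a covariate vector by ≤/> comparisons
(boundary values go to the ≤ group) and evaluates the node curve,
constant beyond the node's last observed time. Missing covariate values
are rejected — there is no surrogate-split machinery. Per-node random
seeds are derived from (root seed, node path) through numpy seed
sequences, so an identical seed reproduces the tree bit for bit and
growth order cannot change results. A logrank-splitting comparator tree
is produced by the same engine with the criterion swapped (split chosen
by minimal logrank chi-square p-value; no variance stabilization is
applied to the permutation p-values, which need none). Trees serialize
to a documented JSON schema and to Graphviz DOT.

Because the dependence parameter is not identifiable from competing-risks
data, τ is an assumption, not an estimate. `cv_select_tau` supports the
recommended sensitivity workflow: event-stratified K-fold
cross-validation (folds re-shuffled with the next sub-seed in the rare
case a fold lacks events) reporting, per τ, the mean number of terminal
nodes, Harrell's C on terminal-node ranks and the integrated Brier score
with Kaplan–Meier censoring weights.

## Evaluation metrics

*Selection precision* is the fraction of internal nodes splitting on an
informative covariate; a depth-0 tree returns None and is excluded from
averages rather than diluting them. *Harrell's C* is computed on
terminal-node ranks over ordered pairs (i, j) with xᵢ > xⱼ — the pair is
comparable only when the earlier subject's time is an event (δⱼ = 1),
since otherwise the survival ordering is uncertain; the printed count
formulas show only the time indicator, but the comparability sentence
fixes the event condition and it is implemented. HC = (CC + 0.5·TR)/
(CC + DC + TR), invariant under order-preserving relabelings of the node
numbers; one single node gives HC = 0.5. *The integrated Brier score*
uses inverse-probability-of-censoring weights: before a subject's
observed time the error (1 − Ŝ)² is weighted by 1/Ĉ(t), after an
observed event the error Ŝ² by 1/Ĉ(xᵢ−). The time integral is a
rectangle sum over a grid containing all jump points (default: the union
of train and test times, configurable to either); segment membership uses
1{xᵢ > t̃ⱼ} / 1{xᵢ ≤ t̃ⱼ} so that the sum equals the continuous
integral exactly and is invariant to grid refinement, and a perfect
predictor scores exactly 0. The grid weight Ĉ(t̃ⱼ) is evaluated
right-continuously (the almost-everywhere value on the segment); the
subject weight Ĉ(xᵢ−) as a left limit, with a flag for the
right-continuous reading. Zero-weight terms are dropped with a logged
count. Ĉ can be the Kaplan–Meier censoring estimate (default) or the
CGE of the censoring distribution under a stated τ.

## Synthetic data

The generators define the study conditions under which this package's
claims are tested; they emulate randomized-trial survival data with
informative censoring, not any particular real dataset.

*Proportional hazards*: T = −log(U)·exp(−βz) (unit-exponential baseline)
with (U, V) drawn from the chosen copula, and C = −log(V)/λ_C with
λ_C = r/(1−r), so that at β = 0 under independence exactly 100r% of
observations are censored in expectation (r ∈ {0.1, 0.25, 0.5} in the
presets; r = 0 means no censoring). Covariates: binary group labels by
default, or normal mean-shift (μ = 0 vs γ), normal scale (σ = 1 vs γ),
or Poisson (λ = 1 vs 1 + γ) mechanisms. Kendall's τ of (T, C) equals the
copula's τ within each covariate level (monotone-transform invariance);
pooled over groups with β ≠ 0 it is attenuated.

*Non-proportional hazards*: hazard h(t) = exp(γt + β₁z + β₂zt)
(Gompertz with a time-dependent group effect), inverted analytically as
T = log(1 − (γ+β₂z)·e^{−β₁z}·log U)/(γ+β₂z); the β₂ = 0 special case is
verified to give a constant hazard ratio e^{β₁}.

*Pathway covariates*: p covariates in three blocks (q, q, p − 2q); the
two leading blocks have within-block Pearson correlation ρ, produced by
a Gaussian copula with normal correlation 2·sin(πρ/6) mapped to
Uniform(−√3, √3) margins (mean 0, sd 1). The first ⌈q/2⌉ columns of each
informative block are binarized at their sample median (clinical-style
categorical markers — binarization and rounding attenuate the realized
correlation, so the ρ target is checked pre-transformation); all columns
are rounded to one decimal, which keeps the tree's cutoff grids small.
Effects are +β on block 1, −β on block 2, 0 elsewhere;
T = −log(U)·exp(−βᵀz) with dependent censoring as above.

*Unequal-censoring arms* deliberately violate the equal-censoring
assumption: group-specific calibration parameters (r₁, r₂), or censoring
generated by the same covariate-dependent mechanism as survival.

Every generator takes an explicit seed and is bit-reproducible;
simulation drivers derive per-cell and per-round seeds from the study
seed via seed-sequence spawning, so results are independent of
evaluation order. What these simulations do not emulate: covariate
measurement error, time-varying covariates, cross-block interactions,
administrative censoring, or real biomarker distributions — passing
performance here shows correctness of the machinery under the stated
models, not field performance on arbitrary clinical data.

## Study scales and numerical choices

The simulation presets reproduce the headline numbers at the following
problem sizes, chosen as this package's desk-scale defaults: power
benchmarks at nsim = 1000 datasets × nperm = 1000 permutations
(balanced n₁ = n₂ = 150 and unbalanced n₁ = 20, n₂ = 50 settings);
type-I error at nsim = 2000 on a reduced null grid (n₁ = n₂ = 50,
r = 0.5, Clayton τ ∈ {0.0001, 0.25, 0.5, 0.75} plus Frank
τ ∈ {0.25, 0.5}); extreme-effect power (β = ±5) at nsim = 200 over
n ∈ {20, 50, 150} pairs × r ∈ {0.1, 0.5} × τ ∈ {0.0001, 0.5}; and the
tree study at n = 100, p = 10, q = 2, nsim = 10, nperm = 300, where the
full-scale design (p = 50, nsim = 100, nperm = 1000) is a cluster-sized
computation and the package asserts the one-sided claims (selection
precision and Harrell's C above 0.5) plus the structural invariants.
Monte-Carlo uncertainty is reported as √(p̂(1−p̂)/nsim) with worst-case
bound 0.5/√nsim.

Numerical conventions worth knowing: p-value ties are counted as extreme;
generator evaluations at 0 produce +∞ and propagate to a curve value of
exactly 0 rather than raising; curve values are clipped to [0, 1] after
the pseudo-inverse; the L1 integration and both metric oracles are exact
rectangle sums, so cross-checks against brute-force enumerations are
asserted at 1e−12, not at quadrature tolerances.

## Known limitations

The equal-censoring-distributions assumption underlies the test's
validity; the sensitivity arms show that group-specific censoring rates
can inflate the type-I error of every test considered, including the
logrank comparator. τ cannot be estimated from the data within this
framework — only assumed or tuned by cross-validation. The tree applies
no multiplicity correction over cutoffs and no pruning, so it overfits on
deep grids; singleton terminal nodes destabilize the IBS. Categorical
covariates must be pre-encoded numerically (splits are ≤/> only), and
missing values are not handled. Studentized permutation variants,
restricted-mean-survival-time splitting and random survival forests are
out of scope.
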