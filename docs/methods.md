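# Methods

## The age-stage, two-sex life table

A cohort of `n_01` eggs is followed daily until the last individual dies.
Because development times vary among individuals and both sexes are kept,
the census lives on an age × stage grid rather than a female-only age
vector. With `n_xj` the number of individuals alive at age `x` (integer
days, day 0 = first egg day) in stage `j`:

- age-stage survival `s_xj = n_xj / n_01`, age-specific survival
  `l_x = Σ_j s_xj`;
- `f_xj` is the mean egg output of a stage-`j` individual of age `x`
  (non-zero only for female adults) and
  `m_x = Σ_j s_xj f_xj / Σ_j s_xj` — i.e. total eggs laid at age `x` over
  the number alive at age `x`. Where `l_x = 0` the ratio is 0/0 and we
  define `m_x = 0`; such ages contribute nothing to any downstream sum.
- net reproductive rate `R0 = Σ_x l_x m_x`; the intrinsic rate of increase
  `r` solves the Euler–Lotka equation `Σ_x e^{-r(x+1)} l_x m_x = 1`
  (age indexed from 0, which puts the `x+1` in the exponent); finite rate
  `λ = e^r`; mean generation time `T = ln(R0)/r`; gross reproductive rate
  `GRR = Σ_x m_x`.

Two conventions matter and are applied consistently: an individual is
attributed to its **new** stage on a transition day, and every quantity
counts the **current** day (so a newborn that dies on day 0 has lifespan 1
and `e_00 = 1`).

Useful exact identities follow from the construction and are enforced in
tests: `R0 = (mean eggs per female) × (N_f / n_01)` (the two-sex identity),
`e_00` equals the cohort's mean lifespan, and the reproductive value of a
fresh egg equals `λ`.

### Life expectancy and reproductive value

Both are built on the empirical one-day transition fractions
`P[x, j → y]` — of the individuals observed in cell `(x, j)`, the fraction
found in stage `y` the next day (stage-skipping transitions are allowed,
since a daily census can straddle two molts). Forward propagation of these
fractions from an origin cell gives the conditional survival probabilities
`s'_iy`; from the origin `(0, egg)` this reproduces the marginal `s_xj`
exactly, because the empirical fractions compose back into the empirical
counts.

- `e_xj = Σ_{i≥x} Σ_y s'_iy`, the expected remaining days of life;
- `v_xj = e^{r(x+1)} Σ_{i≥x} e^{-r(i+1)} Σ_y s'_iy f_iy`, the expected
  contribution to future growth. `s'` here is conditional on the origin
  (probability 1 at `(x, j)`); a common printed form of the same equation
  uses unconditional probabilities divided by `s_xj`, which is algebraically
  identical and numerically worse (0/0 in empty cells).

Both are computed by backward recursion over the transition fractions
(`e_xj = 1 + Σ_y P[x, j → y] e_{x+1,y}` and the analogous recursion for
`v`), which is exactly the forward double sum evaluated efficiently; tests
assert the equality against the forward definition on random cells.

### The Euler–Lotka solver

The left-hand side is strictly decreasing in `r`, so the root is unique.
We bracket it on `r ∈ [−2, 2]` day⁻¹ (far wider than any insect cohort can
produce), solve with Brent's method at xtol 1e-10, and apply one Newton
polish; the residual is checked below 1e-8 in the test suite. `R0 = 1`
short-circuits to `r = 0`; `R0 = 0` raises (no root exists), and bootstrap
replicates hitting that case are excluded from the `r`, `λ`, `T` summaries
with the exclusion count recorded. `T = ln(R0)/r` is NaN when `r = 0`.

## Bootstrap inference

The resampling unit is the individual: each replicate draws `n_01` records
with replacement and reruns the same life-table computation (no shortcut
formulas — spot equality with the full pipeline is tested). The SE of a
parameter is the standard deviation of its replicate distribution. The
published convention is 100 000 replicates; the library default is
B = 2000, which resolves SEs to a few percent and keeps desk runtime in
seconds, with B configurable everywhere.

Two strains are compared by a paired bootstrap test: replicate-wise
differences `d_k = a_k − b_k`, a percentile confidence interval, and the
two-sided percentile p-value `p = 2·min(frac(d ≤ 0), frac(d ≥ 0))`
clamped at 1. The exact rule used by the classical two-sex life-table
software is not published; this percentile construction is the documented
stand-in, and its type-I error is verified empirically (cohort pairs drawn
from one population reject at ≈ 5%). Note the calibration statement applies
to *independently sampled cohorts*: comparing two bootstrap runs of the
same observed cohort gives a difference distribution centred at zero and
essentially never rejects, which is a property of the test's construction,
not an error.

Relative fitness is `Rf = R0(selected) / R0(control)`. Parameter-versus-
generation association is summarised by Pearson correlation, reported both
over pooled generation-labelled replicates (bootstrap pooling inflates the
effective n, so its p-values are optimistic and should be read as
descriptive) and over the generation means (n = number of generations).
No multiplicity correction is applied across parameters.

## Probit dose-mortality analysis

Mortality counts at each concentration are modelled as binomial with
`probit(π) = α + β·log10(dose)`. log10 (not natural log) is the dose scale:
the published LC25/LC50/slope triples are internally consistent under that
convention (verified to 0.5% for seven of eight selected-generation rows;
the third-generation row of the source table is internally inconsistent —
its printed slope 0.558 implies LC25 = 2.26 against a printed 4.73 — and is
excluded from the regression test as a table defect). The MLE and its
observed-information covariance come from a standard GLM fit; goodness of
fit is the Pearson χ² on the dose groups with `df = groups − 2`, and the
heterogeneity factor `h = max(1, χ²/df)` inflates all variances when the
data over-disperse, with Student's t replacing the normal critical value in
that case — the classical probit (Finney/SPSS) convention.

`LC_p = 10^((Φ⁻¹(p/100) − α)/β)`; its 95% limits come from Fieller's
theorem on the log10 scale (the exact quadratic, returning NaN when the
slope is too poorly determined for a bounded interval, i.e. Fieller's
g ≥ 1); a delta-method alternative is provided for comparison. Resistance
ratio = LC50(test)/LC50(reference). Abbott's correction
`p' = (p − c)/(1 − c)` is available but off by default, as the source study
does not report applying it.

## Synthetic data

The cohort generator emulates the study design: egg → L1…L4 → pupa →
sexed adult, one record per initial egg, integer-day census. Choices:

- **Stage durations** are `1 + Poisson(mean − 1)` days — guaranteeing ≥ 1
  day per stage, as an integer-day census requires. Defaults (egg 4.9,
  L1 3.0, L2 2.8, L3 2.7, L4 2.8, pupa 7.1 days) sit at the control-strain
  means of the emulated study.
- **Mortality** is a per-day Bernoulli risk within each preadult stage
  (defaults 0.975–0.99/day), giving preadult survival ≈ 0.71 so that with
  an even sex ratio and ≈ 100 eggs per female, R0 lands near 35 — the
  published control regime. Adults die at a drawn longevity
  (`1 + Poisson`, means 18.1/17.1 days for females/males).
- **Fecundity**: APOP ~ Poisson(2.1) days after emergence, then daily egg
  counts Poisson-distributed around a triangular rate (peak 21 eggs/day on
  day 2 of oviposition, last day 8), totalling ≈ 100 eggs for a female
  surviving the window. A `fixed_eggs` override lays an exact clutch on the
  first oviposition day, giving degenerate specs with closed-form R0 for
  exact tests.
- **Treatment knobs**: `fecundity_multiplier` and `preadult_extra_days`
  emulate a sublethally stressed strain for two-strain comparison tests.

`expected_parameters` evaluates the implied demography without simulation:
survival-weighted convolution of the stage-duration distributions gives the
adult-emergence age distribution; marginalising the APOP/longevity/rate
schedule gives expected eggs per adult day; their convolution is the
expected net-maternity schedule `E[l_x m_x]`, from which R0 (exactly) and
r (as the Euler–Lotka root of the expected schedule) follow. The r so
defined is the large-cohort limit of the estimator; at `n_01 = 500` the
residual estimator bias is far below the Monte-Carlo SE used in the
recovery tests (verified empirically to z ≈ 1 over 1500 cohorts).

What the generator does **not** emulate: overlapping generations, density
dependence, temperature effects, mating structure or any genetic model of
resistance, within-cohort heterogeneity beyond the stated distributions,
and observation error in the daily census. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated sampling model,
not robustness to those real-data features.

The bioassay generator draws replicate-level binomial kills from the exact
probit curve (defaults: the six-concentration serial dilution
500…0.78125 mg/L, six replicates of five larvae, i.e. n = 30/dose),
optionally with a control well of specified background mortality.

## Problem sizes in the test suite

Tests run the generators at n_01 = 30–500 individuals and B = 100–5000
bootstrap replicates; the recovery checks use 20 cohorts of 500 (seeds
0–19) and 200 simulated bioassays at n = 30/dose. These sizes resolve every
assertion's tolerance (2 Monte-Carlo SE, or coverage ≥ 90%) while keeping
the full suite under half a minute on one core.

## Known limitations

- No censoring: every record must end in death, as in the source design
  (`n_01` = cohort size is required by the survival definition).
- Same-day double molts are representable (consecutive entry ages) but the
  generator never produces them; transition estimation handles
  stage-skipping either way.
- Percentile bootstrap intervals only; no BCa or studentized variants.
- Probit only (no logit/cloglog primary output) and a fixed scoring
  endpoint; time-to-death models are out of scope.
- The compact letter display uses insert-and-absorb at α = 0.05; displays
  are not unique in general, only the sharing contract (significant pairs
  never share, non-significant pairs always share) is guaranteed and
  tested.
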