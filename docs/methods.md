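# Methods

## The estimation procedure being studied

A mass-univariate association study computes Pearson correlations between
each of many brain measures and one behavioural measure across subjects,
with two-tailed P values from the exact parametric null (t statistic
`r·√((n−2)/(1−r²))` with `n−2` df). The data-driven replicability analysis
treats the observed large sample as the population: replication samples are
with-replacement draws of subjects, correlations and P values are recomputed
at the resample size, and six error rates are estimated by comparing
significance calls between the full-sample table and each replication table,
averaged over iterations:

| estimator | denominator | numerator |
|---|---|---|
| false negative rate | effects with `p_full < α` | `p_rep ≥ α` |
| power | same | `p_rep < α` (complement of FNR) |
| sign error rate | same | `sign(r_rep) ≠ sign(r_full)` |
| inflation rate (margin m) | replicated effects (significant in both, same sign) | `|r_rep| > (1+m)·|r_full|` |
| probability of replication | effects significant in an "in-sample" subsample | significant with same sign in an "out-of-sample" subsample |
| false positive rate | effects with `p_full ≥ α` | `p_rep < α` |

Power and FNR deliberately do **not** require sign consistency; that choice
is what makes their fresh-sample expectations exactly `α` and `1−α`, and
sign errors are tracked by their own estimator. The FPR denominator is the
full-sample non-significant set for the same reason (expectation exactly α
under fresh sampling; the all-effects alternative differs by the factor
1−α). Replication probability requires sign agreement by default —
matching how replication is usually declared — which makes its fresh-sample
expectation α/2; a config switch (`prob_replication_require_sign=False`)
drops the sign requirement and shifts the analytic comparator to α. The
in/out subsamples are two independent with-replacement draws by default;
`prob_replication_mode="disjoint"` switches to a disjoint split of a
permutation, for users who prefer non-overlapping halves.

## Synthetic data

**Subject level.** Each subject gets `n_nodes` independent standard-normal
time series of length `ts_length`; all pairwise Pearson correlations form
the subject's edge vector, and an independent sub-stream draws one
standard-normal behavioural score. Defaults: 1,000 subjects, 50 nodes
(1,225 edges), `ts_length = 100`. The time-series length is a free
parameter: it only shapes the marginal spread of edge values, and every
downstream statistic depends on the brain–behaviour correlations alone,
which are null for any length ≥ 3. Node series are mean-centred and
norm-scaled before correlation; whether they are standardised first is
immaterial under the null and is exposed only through `ts_length` choice.

What this emulates is the *statistical* situation of a null BWAS — many
exchangeable noisy measures against an independent behaviour. It does not
emulate fMRI signal: no temporal autocorrelation, no motion or global-signal
confounds, no parcellation structure, no dependence between edges beyond
that induced by sharing nodes, and no measurement unreliability. Passing
tests therefore show that the estimation *procedure* is biased even in the
friendliest possible data; they do not quantify additional real-data
effects, and real-data biases can only be worse than this clean floor.

**Summary level.** For ground-truth power scenarios the package skips
subjects entirely and draws correlations through the Fisher approximation:
`z ~ N(atanh ρ, 1/√(n−3))`, `r = tanh z`. A scenario draws 55,278 effects
(the count for a 333-region parcellation) at n = 1,000, replaces 500
randomly chosen ones (~1 %) with true effects of common size ρ, and uses
the Bonferroni threshold α = 0.05/55,278. The eleven default scenarios set
ρ by inverse power analysis so that full-sample power is 1 %, 10 %, …,
90 %, 99 %. Resampling is simulated on the same scale: each full-sample
correlation r* is perturbed as `z ~ N(atanh r*, 1/√(size−3))` and tested at
the resample size. A two-sample KS test in the suite confirms the
summary-level nulls are indistinguishable from subject-level-derived
correlations at matched n.

## Power machinery and conventions

- P values and critical r for *data* are exact t-based; power curves and
  the inverse power analysis are Fisher-z-based. Mixing the two is
  intentional: significance decisions should be exact, while the z scale
  gives closed-form power. The two critical values agree to ~0.1 % at
  n = 1,000.
- The inverse power formula is implemented as
  `tanh((z_{1−α/2} + z_power)/√(n−3))`; written with the type-II deviate
  `Z_β = −z_power` this is the familiar `(Z_α − Z_β)` numerator. Only this
  reading makes the detectable effect grow with the requested power.
- `analytical_power` keeps the wrong-tail term
  `Φ(−√(n−3)·atanh|ρ| − z_{1−α/2})` so that power → α exactly as ρ → 0, and
  the round trip with the inverse analysis is exact to < 1e-6 at the
  Bonferroni thresholds used.
- Two-tailed α is split evenly across tails throughout.

## Numerical and degenerate-input choices

- `p_two_tailed(±1, n)` would underflow; the smallest positive double is
  returned with a `RuntimeWarning`.
- Zero-variance edge columns (impossible with continuous noise, possible
  with user-supplied data) are excluded with a warning; surviving effects
  keep their original `effect_id`.
- `sign(0)` counts as a mismatch against any sign — a measure-zero event,
  but the convention is fixed and tested.
- Inflation uses strict inequality, so a self-replication is never
  "inflated".
- Empty denominators yield `NaN` ("missing"), never 0, and sweep records
  carry the average denominator size (`n_eligible`) so downstream users can
  tell a noisy cell from a well-estimated one.
- Every `(size, iteration, purpose)` cell gets its own `SeedSequence`
  child stream keyed by those integers, so sweeps are reproducible and
  independent of execution order; CSV outputs are byte-identical across
  reruns of the same seed.
- Log-spaced size bins: 10 sizes from 25 to 1,000 (geometric, rounded,
  deduplicated), configurable.
- Inflation margins default to m ∈ {0, 0.2, …, 1.0} (relative margins);
  there is no canonical set, so they are config.
- The reference full sample is generated once and held fixed across both
  the resampling and fresh-sample arms; only the replication samples vary.

## Problem sizes used by the tests and the acceptance script

The subject-level experiments run at the full study scale (n = 1,000,
1,225 edges, 100 iterations; five master seeds for the seed-averaged
checks). The scenario sweep in the test suite uses 100 iterations per cell
rather than the pipeline default of 1,000 — at 100 iterations every bias
conclusion below is already resolved far beyond its Monte-Carlo error —
and unit tests use smaller samples (e.g. 80×45) because every property
checked is scale-free. Monte-Carlo standard errors accompany all averaged
estimates, and stochastic assertions use 3-SE tolerances.

## What the experiments show

Under the null, resampling at the full sample size roughly doubles the
variance of the recomputed correlations (σ₁² + σ₂² ≈ 0.002 against the
nominal σ₁² ≈ 0.001), which inflates estimated power from the true 5 % to
the low-60s % and the false positive rate from 5 % to ≈ 14 % at α = 0.05
(the additive-variance law predicts
`(2Φ(−z_{α/2}/√2) − α·power_resample)/(1−α) ≈ 0.14`). With true effects
present, bias at the full size depends on the scenario's true power:
underpowered large samples inflate power estimates (winner's-curse
conditioning on the significant set), highly powered ones deflate them
slightly, and subsampling at ≤ 10 % of the full size is nearly unbiased in
every scenario.

## Known limitations

- No measurement-reliability model; estimates apply to sampling
  variability only.
- The null generator's edges are exchangeable white-noise correlations;
  effects of realistic spatial/temporal structure on the *magnitude* of the
  bias are out of scope.
- Summary-level resampling inherits the Fisher approximation; at resample
  sizes below ~25 the normal approximation of `atanh r` starts to diverge
  from the exact t behaviour in the far tails used by Bonferroni
  thresholds.
- True-effect scenarios give every planted effect the same ρ; a
  distribution of effect sizes with the same mean would behave similarly on
  average but is not simulated.
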