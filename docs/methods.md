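# Methods

## Data model and networks

A sociometric survey gives every respondent the full roster and one
forced-choice relation per classmate: `best_friend`, `friend`,
`acquaintance`, `unknown`, or `related`. A response is *complete* iff
every non-self roster member has exactly one rating row; a duplicated
rating is a validation error rather than a silent overwrite, because
the survey instrument enforces one answer per pair. Only complete
responses enter the analysis; students who never responded are dropped
from the node set entirely, and ratings naming them are discarded with
a logged warning.

Ties are directed and deliberately unreconciled: if u names v a best
friend and v names u an acquaintance, both edges stand in their
respective tiers. `unknown` and `related` ratings are retained in the
data model for round-tripping but never produce edges.

Networks come in two flavors per tier:

- **cumulative** (`acquaintance_plus` ⊇ `friend_plus` ⊇ `best_only`):
  a tier plus all stronger tiers — the nesting used for whole-network
  metrics;
- **exclusive** (`acquaintance_only`, `friend_only`, `best_only`):
  exactly one relation level — disjoint neighbor sets, the default for
  the regression predictors, because cumulative sets would build
  mechanical collinearity into the three x columns.

Whole-network metrics: density `m / (n(n−1))` and transitivity on the
directed edges — transitivity is the fraction of directed two-paths
`i→j→k` (i ≠ k) closed by an edge `i→k`, the standard directed
generalization (complete digraph = 1, pure cycle = 0) — while average
clustering is computed after symmetrizing each edge by logical OR.
Degree CCDFs report `P(degree ≥ k)` at every integer `k` from 0 to the
maximum. A single-node network has undefined density and is rejected.

## Rankings, progress and environment scores

Ranking `g` = cohort size minus GPA position, so the top student gets
`N−1` and the bottom 0; a tie-free cohort's ranks are exactly
`{0, …, N−1}`. Tie policies: `average` (default; tied students share
the mean of the spanned ranks — the continuous analogue used
throughout), `dense`, and `random` (uniform tie-breaking, requires an
explicit generator); non-default policies are recorded in the output
metadata. Progress `y = g(t1) − g(t0)`; over a fixed tie-free cohort
the ranks at both timepoints are the same multiset, so `Σy = 0`.

The environment score of student u at tier i uses u's *out*-neighbors
(the people u named). Two definitions are implemented because
"difference between the neighbors' average GPA and one's own" admits
both readings:

- `mean_neighbor_rank` (default): `x_u = mean(g_v over out-neighbors) − g_u`.
  Stays in rank units like g and y, and is invariant to adding a
  constant to all ranks.
- `rank_of_mean_gpa`: average the neighbors' raw t0 GPAs, place that
  mean on the class scale by counting classmates (excluding u) with
  lower GPA — exact ties count half — then subtract `g_u`.

Both are exercised by the tests; all x values use January-of-year-one
quantities only. Students with no out-neighbors at a tier have no
defined x there; policy `zero` (default for the regression) fills 0
with a logged warning, `exclude` drops the (student, tier) pair. Real
cohorts of this kind have no friendless students, so this arises only
on synthetic or edge inputs.

## Regression and sequential ANOVA

The four-predictor model is fitted by least squares through an SVD of
the design matrix; singular values below `1e-10` of the largest raise
a collinearity error naming the involved columns. The sequential
(Type I) table fixes the term order `(g, x_acquaintance, x_friend,
x_best_friend)` — matching the one-DF-per-term layout with a shared
error row — and exposes it as a parameter. SS of term k is the RSS
drop when it enters after terms 1..k−1; `F = MS / error MS` with
`(1, n−1−4)` DF, upper-tail p from the F distribution. The identity
`Σ term SS + error SS = total SS` is enforced by construction and
checked to 1e-8 relative tolerance on random inputs. Reports annotate
`*` for p < 0.05 and `***` for p < 0.001, and serialize floats at 6
significant digits. When the residual variance is exactly zero (e.g. a
noiseless null cohort where y ≡ 0) the F ratio is undefined and
reported as NaN rather than inventing a value.

## Permutation null

The null model keeps each student's out-degree fixed and redraws the
targets uniformly without replacement among the other `n−1` students:
no self-loops or duplicate edges by construction, in-degrees free. A
node already naming everyone keeps a forced neighborhood. Only the
friend-tier network is rewired for the headline test; x_friend is
recomputed on each replicate with exactly the observed analysis's
mode and policies, y is never permuted. The empirical p uses the
add-one rule `p = (1 + #{r_null ≥ r_obs}) / (n_reps + 1)` so it is
never zero (`two_sided` doubles the smaller one-sided p, capped at 1).
Replicates whose recomputed x degenerates to a constant are recorded
as missing; more than 10% missing aborts. Box-whisker summaries use
linearly interpolated quartiles.

Two execution paths share this contract: a generic one that accepts
any `network -> {student: x}` callable and rewires explicitly per
replicate, and a vectorized one used when the builder is the package's
own `EnvironmentRecomputer` — each replicate draws one uniform
permutation of the other `n−1` students per node (argsort of i.i.d.
uniforms) and takes the first `k_u` entries, which is exactly uniform
sampling without replacement. The suite checks the two paths agree.

## Synthetic cohorts

`CohortConfig` defaults are the emulated study conditions: 158
students; per-student Poisson out-degrees with exclusive-tier means
(45, 7, 2.5) for acquaintances/friends/best friends — acquaintance
dense, nobody friendless (friend out-degree clipped to ≥ 1), best
ties few; t0 GPA = `100 × Beta(8, 2)` (sample skewness ≈ −0.8, mass
near the top of the scale); upward drift between years; Gaussian
GPA-change noise with sd 3; homophily 0.5 biasing best-friend choice
toward similar-GPA classmates via an exponential kernel with 5-point
bandwidth. Tier sets are drawn disjointly (best first, then friends,
then acquaintances); remaining classmates are `unknown` except a 2%
`related` fraction. Incomplete responses are manufactured by deleting
a single rating row — the minimal completeness violation.

Drift is attenuated toward the scale top,
`shift = drift·(100 − GPA)/100` with default drift 5 (≈ +1 GPA point
at the cohort mean), rather than added as a constant: a constant shift
plus clipping at 100 would pile the top of this left-skewed
distribution into ties and change rankings even in a noiseless null
cohort, whereas the attenuated shift is strictly order-preserving and
bounded, so `noise_sd = 0, contagion_delta = 0` yields exactly `y ≡ 0`.

Contagion is planted in **GPA space**:
`GPA_t1 += contagion_delta × (mean friend GPA_t0 − own GPA_t0)`.
Ranks are derived quantities, so the pipeline has to detect the effect
through the rank transform — the honest end-to-end exercise. The
suite's strong setting is `contagion_delta = 0.5` (the planted signal
is then roughly twice the noise sd at typical friend-GPA spreads).

What the generator does *not* emulate: real homophily on unobserved
traits, reciprocity structure, community structure beyond the GPA
kernel, GPA scale semantics (credit weighting), or covariates such as
gender and attendance. Passing tests therefore demonstrate that the
pipeline recovers a planted GPA-coupled effect under realistic sizes
and noise — not that any particular real cohort exhibits one.

## Calibration and problem sizes

Because friend nominations in null cohorts are drawn uniformly, the
observed network is exchangeable with its rewirings, so the
permutation p is (discretely) uniform and the test's size can be
measured directly: the suite runs 200 null cohorts × 500 replicates
at n = 158 and requires the α = 0.05 rejection rate to land in the
binomial 99% band 2–9%. Power uses 100 strong-contagion cohorts
(ANOVA p < 0.05 in ≥ 90%, fitted `β_xf > 0` in ≥ 95%, observed r
above the null maximum in ≥ 50%). The acceptance script reruns the
same experiments at the same sizes. A single 500-replicate test at
n = 158 takes well under a second via the vectorized path.

## Known limitations

- The permutation null preserves out-degrees only; nulls that also fix
  in-degrees (directed double-edge swaps) are not implemented.
- Homophily in the generator acts on best-friend ties only, so it does
  not confound the friend-tier test; real settings offer no such
  guarantee, and the test inherits the usual inability of rewiring
  nulls to separate influence from unmodeled homophily.
- No coefficient standard errors, R², or robust/regularized variants:
  the analysis is the fixed four-predictor OLS + Type I table plus the
  permutation test.
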