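# gradenet

Social contagion of academic success in a high-school friendship
network: does having friends who outperform you predict that your own
class standing will rise over the following year?

`gradenet` is a tested, reusable pipeline for the full analysis:

1. **Sociometric survey ingestion.** Each student rates every classmate
   as a best/close friend, a friend, an acquaintance, unknown, or a
   relative. The first three levels yield three nested *directed*
   networks (an edge `(u, v)` means *u* named *v*); incomplete
   responses are excluded before any statistics.
2. **Rank transforms.** Raw GPAs are heavily left-skewed and drift
   upward between years, so students are mapped to class rankings
   `g = N − position` (higher is better; ties share average ranks).
   Academic progress is `y = g(t1) − g(t0)`.
3. **Environment scores.** For each tier *i*, `x_i` is the difference,
   in rank units, between a student's self-reported tier-*i* neighbors'
   average standing and their own: positive `x` means your friends
   outrank you.
4. **Progress regression.** Ordinary least squares of
   `y = β₀ + β_g·g + β_xa·x_acq + β_xf·x_friend + β_xb·x_best + ε`
   with a sequential (Type I) ANOVA: each term's SS is the drop in
   residual sum of squares when it enters after the preceding terms,
   F-ratios against the full model's error mean square.
5. **Permutation null.** `x` and `y` are *inherently* positively
   correlated (students with stronger friends sit lower and have more
   room to rise), so significance comes from a network-randomization
   null: each student's number of outgoing friendship nominations is
   kept fixed while the targets are redrawn uniformly at random;
   Pearson's `r(x_friend, y)` is recomputed on each of 500 rewired
   networks and the observed `r` is located in that null distribution
   with an add-one empirical p-value, `p = (1 + #{r_null ≥ r_obs}) / 501`.

The study's student records are IRB-restricted, so the package ships a
first-class synthetic cohort generator that emulates the stated data
features (158 retained of 160 responses, nested tiers with nobody
friendless, left-skewed GPAs near the top of a 0–100 scale, upward
drift) and can *plant* a contagion effect of known strength in GPA
space — the pipeline must then recover it through the rank transform.

## Worked example

Simulate a 158-student cohort with a planted contagion effect
(`contagion_delta: 0.5` in a YAML config) and run the whole analysis:

```sh
echo 'contagion_delta: 0.5' > strong.yaml
gradenet report --seed 7 --config strong.yaml --n-reps 500 --out demo
```

prints

```
y = -85.8849 + 1.07346*g + 0.339917*x_acquaintance + 0.946355*x_friend + 0.00734221*x_best_friend
observed_r=0.522756 empirical_p=0.00199601
```

and writes `demo/anova.tsv`:

```
term            DF  SS       MS       F          p            sig
g               1   17286.4  17286.4  30.9195    1.16961e-07  ***
x_acquaintance  1   19.4438  19.4438  0.0347783  0.852308
x_friend        1   47903.8  47903.8  85.6835    1.78631e-16  ***
x_best_friend   1   5.30281  5.30281  0.00948491 0.922544
Error           153 85539.0  559.079
Total           157 150754.0
```

Reading this: with 158 students the ANOVA has 157 total and 153 error
degrees of freedom. The planted friend-tier effect dominates
(`x_friend` SS, p ≈ 2e-16; fitted `β_xf ≈ 0.95 > 0`), while the
acquaintance and best-friend tiers — where no effect was planted —
stay flat. The permutation test agrees: the observed
`r(x_friend, y) = 0.523` exceeds all 500 rewired-network correlations
(null range ≈ 0.22–0.38; that the *null* is itself far above zero is
the built-in structural correlation the rewiring preserves), giving
the smallest attainable p of 1/501 ≈ 0.002. On a cohort generated with
`contagion_delta = 0` the same pipeline reports an observed `r` inside
the null box and a non-significant `x_friend` row.

Other entry points: `gradenet simulate` (write `survey.csv` +
`roster.csv`), `gradenet analyze` / `gradenet permtest` on those files
(or your own, same headers), and `gradenet quicktest --own-gpa 80
--friend-gpa 90 --friend-gpa 85` for the back-of-the-envelope
direction check (`up`).

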