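# Methods

## Data model

The raw datum is a complete participant × action × object array of
binary endorsements: each participant judged, once per object-action
combination, whether the action applies to the object. Completeness is
a contract, not an assumption: a missing cell is a validation error,
never an implicit 0, because the judgment task presents every
combination exactly once. Animate objects are excluded before analysis
by default (their affordances are qualitatively different from those
of inanimate objects).

Averaging over participants gives each object an affordance vector in
`[0, 1]^A` (A = number of actions, 14 by default). All downstream
statistics operate on these vectors.

## Size ranks

Objects are binned by their real-world bounding-box diagonal into
logarithmic size ranks. The default bins are half-open octaves,
rank *r* spanning `[2^(r+2), 2^(r+3))` cm for ranks 2-7, with the top
bin widened to `[1024, 8192)` cm so that the very largest structures
remain in rank 8. These edges reproduce the conventional anchor sizes
for the rank scale (a ~17 cm object is rank 2, ~77 cm rank 4, ~146 cm
rank 5, ~577 cm rank 7, ~5317 cm rank 8) and place the rank-4|5 edge at
128 cm, inside the adult human body-size range. A size exactly on an
edge belongs to the higher rank; sizes outside `[16, 8192)` cm are a
range error. The edges are configurable (`AnalysisConfig.rank_bin_edges`).

## Boundary statistics

**Rank curve.** Affordance vectors are averaged (unweighted) within
each rank; `r_i` is the Pearson correlation over the action dimension
between the mean vectors of ranks *i* and *i+1*. Its standard error is
`sqrt((1 − r²)/(n − 2))` with *n* = number of actions; the Fisher-z SE
`1/sqrt(n − 3)` is available in `affbound.stats` as an alternative.
A constant rank-mean vector makes the correlation undefined; such
entries are NaN with a warning, never silently zero.

**Trough value.** `T = (r_{i−1} + r_{i+1})/2 − r_i` at a site
`(i, i+1)`: how far the curve at the site dips below the average of
its two banks. `T` is linear in the curve (scaling all `r` by c scales
`T` by c; adding a constant leaves it unchanged). Site selection takes
the interior site maximizing `T`, ties broken toward the smaller rank;
a site fixed a priori via `AnalysisConfig.trough_site` overrides
detection.

**Permutation test.** The exchange unit is the object-to-rank
assignment: each permutation redistributes the observed objects over
the observed rank slots (per-rank counts preserved), recomputes the
rank means, the curve, and `T` at the *same* site; the p-value is the
plain count estimator `p = (1/N) Σ I(T_perm ≥ T_obs)` (it can return
exactly 0; a `(count+1)/(N+1)` variant sits behind
`AnalysisConfig.smoothed_p`). The claim under test is that the trough
location is tied to the object-size structure, which is what this
shuffle destroys. An alternative exchange unit — independently
permuting each object's action entries, which instead destroys action
alignment across objects — is available via
`AnalysisConfig(permute="actions")`. For small object sets an
exhaustive mode enumerates all distinct assignments. Two usage modes
matter:

* *fixed site* (`trough_site` set): the p-value is calibrated; under a
  boundary-free generator it is approximately uniform.
* *detected site*: the p-value inherits the selection of the deepest
  dip and is anti-conservative under the null. Both modes are
  supported; calibration checks always use the fixed-site mode.

**Dependent-correlation contrasts.** Adjacent curve points
`r(j,k)` and `r(k,h)` share rank *k*'s mean vector, so they are
overlapping dependent correlations. The default test is Steiger's Z
(Fisher-z difference scaled by its asymptotic SE with the pooled
correlation; one-tailed at α = 0.05), with Zou's confidence interval
for the raw difference reported alongside. The correlation triple must
be positive semidefinite; |r| = 1 inputs are rejected (Fisher-z
diverges).

**Bayes factor.** The evidence for a difference is summarized by a
normal-normal Bayes factor on the Fisher-z scale: the observed value
is modeled as `N(θ, se²)` with `se = 1/sqrt(n_actions − 3)`, H0 puts a
standard normal prior on θ and H1 a normal prior centered at 2. Both
marginals are closed-form normals, so
`BF10 = N(z_obs; 2, se²+sd1²) / N(z_obs; 0, se²+sd0²)`. The H1 spread
(default sd 1) is a package assumption and materially affects BF
magnitudes; it is exposed as `h1_prior_mean` / `h1_prior_sd`. BF10 >
10 is conventionally read as strong evidence.

**Object-level scan.** Within a rank window (default ranks 3-6) every
same-rank and adjacent-rank object pair contributes one record: mean
real-world size `(d_a + d_b)/2` and the Pearson similarity of the two
affordance vectors. Per rank composition the scan reports mean size
and mean similarity with normal 95% CIs (NaN when a composition has
fewer than two pairs; the composition is retained). The boundary
estimate is the mean pair size of the minimum-similarity composition;
its interval is a seeded percentile bootstrap over that composition's
pairs (1000 resamples), with the normal-approximation interval
reported for reference. The bootstrap-over-pairs choice reflects that
the pairs, not the raters, are the resampling units at this stage.

**Size-similarity control.** `1 − (d_j − d_i)/d_i` between the mean
diagonals of neighboring ranks — deliberately asymmetric, with the
smaller rank as reference. Because rank bins double per rank, this
control curve is roughly flat (~0 everywhere), so a dip in the
affordance curve cannot be explained by real-world size structure.

## Synthetic generator

The generator emulates the study conditions: by default 528
participants, 24 inanimate objects spread over ranks 2-8 (sizes
log-uniform within each rank's bin; the remainder objects go to the
smallest ranks), and 14 actions, 7 per class. Each judgment is an
independent Bernoulli draw with

```
p = lapse/2 + (1 − lapse) · gain_a · sigmoid(s_a · β · log2(d / B))
```

with `s_a = −1` for manipulation actions and `+1` for whole-body
actions. Parameters, units, defaults:

| parameter        | meaning                                  | default |
|------------------|------------------------------------------|--------|
| `agent_size_cm`  | latent boundary B (body diagonal), cm    | 150    |
| `sharpness_beta` | logistic slope per octave of size ratio  | 4      |
| `lapse_rate`     | stimulus-independent response rate       | 0.05   |
| `action_gain`    | per-action base endorsement scale (0,1]  | 1.0    |
| `participant_sd` | per-participant normal logit offset SD   | 0 (off)|

β = 4 makes the switch essentially complete within one octave of the
boundary; β = 0 is the boundary-free null; β = ∞ is a hard step (the
boundary itself stays at chance). Recovery behavior: with B = 150 cm
the trough is detected between ranks 4 and 5; B = 77 cm (cat) moves it
to (3, 4) and B = 577 cm (elephant) to (6, 7), monotonically in B.

**What the generator does not emulate.** Real ratings contain
object-specific idiosyncrasy (a hammer affords throwing, an equally
sized laptop does not) and graded, action-specific base rates. With
the homogeneous default `action_gain = 1.0`, every affordance vector
takes exactly two values (one per action class), so all pairwise
correlations are ±1 up to binomial noise: the RSM is a sign matrix,
cross-boundary similarity is ≈ −1 rather than the ≈ 0 seen in real
data, and the permutation null of `T` concentrates near {−2, 0, +2} —
any label shuffle that flips the class majority at the tested site
produces a trough as deep as the observed one. Two consequences for
interpreting passing tests:

* recovery of the trough *site* and the two-cluster split is robust
  and is what the tests certify;
* the permutation *p-value* under these idealized conditions is a
  near-discrete statistic: with 24 objects it falls below 0.05 only
  when the sampled object set has no object close to the boundary
  (the rank-5 bin spans 128-256 cm and therefore straddles a 150 cm
  agent, so roughly every second object draw places a rank-5 object
  below the boundary, diluting the observed trough relative to the
  sign-flip null). Heterogeneous `action_gain` values soften but do
  not remove this; per-object idiosyncrasy, which the model omits,
  is what makes the test sharp on real data.

Null calibration is unaffected: with β = 0 and a fixed site the
permutation p is approximately uniform (rejection at α = 0.05 stays
near nominal over 200 simulations).

## Numerical choices

* Correlations are computed by centered dot products and clipped to
  [−1, 1] against rounding overshoot.
* Zero-variance affordance vectors yield masked (NaN) similarity
  cells; such objects are dropped from clustering with a warning.
* Clustering (complete linkage, Euclidean) runs on the row profiles of
  the similarity matrix; scipy's deterministic linkage ordering plus
  relabeling clusters in order of first appearance makes the cut
  reproducible. Ties in trough detection go to the smaller rank.
* All random steps (object sampling, Bernoulli draws, permutations,
  bootstrap) use `numpy.random.default_rng` seeded from the relevant
  config seed plus a fixed per-stream offset, so a rerun with the same
  config is byte-identical.
* Problem sizes used by the test suite and the acceptance script: 200
  participants, 24 objects, N = 1000 permutations for recovery runs;
  200 simulations × 500 permutations for null calibration; 2000
  simulations at n = 14 for the Steiger calibration check. These sizes
  give stable statistics while keeping a full run in the seconds
  range.

## Known limitations

* The generator's single latent size dimension cannot produce
  near-zero cross-boundary similarity; it bottoms out near −1.
* The permutation p-value at a detected (rather than pre-specified)
  site is anti-conservative; fixed-site usage is recommended for
  confirmatory claims.
* The Bayes factor depends on an H1 prior spread that the normal-prior
  construction does not itself determine; report it with the prior.
* With < 4 actions the dependent-correlation machinery is undefined,
  and with < 3 curve points no trough site exists.
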