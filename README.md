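# affbound

Affordance-boundary analysis of binary object-action judgment data.

## The problem

An object's *affordance* is the set of actions it offers an agent. When
many raters judge, for each of a fixed list of actions, whether each of
a set of objects "affords" that action (grasp-able? sit-able?), every
object gets an **affordance vector**: the per-action fraction of raters
who endorsed it. Objects much smaller than the rater's body mostly
afford hand-scale manipulation (grasp, hold, throw); objects much
larger mostly afford whole-body actions (sit, stand, climb). The
interesting question is whether the transition along the continuous
size axis is graded or *categorical* — a perceptual boundary located at
the agent's own body size.

`affbound` implements the full analysis pipeline for this question, for
researchers in perception and embodied cognition:

1. **Affordance RSM** — Pearson correlation between affordance vectors
   for every object pair, plus hierarchical clustering (Euclidean
   distance, complete linkage) of its row profiles.
2. **Rank curve** — objects are binned into logarithmic size ranks
   (octave bins on the real-world bounding-box diagonal, ranks 2-8 by
   default); the curve correlates the mean affordance vectors of
   neighboring ranks: `r_i = corr(m_i, m_{i+1})`.
3. **Trough statistic** — the dip of the curve at a candidate boundary
   site `(i, i+1)`:

   `T = (r_{i-1} + r_{i+1})/2 − r_i`

   tested by a permutation that shuffles the object-to-rank assignment
   (per-rank counts preserved) and recomputes `T` at the same site:
   `p = (1/N) Σ I(T_perm ≥ T_obs)`.
4. **Dependent-correlation contrasts** — Steiger's Z for overlapping
   correlations (one-tailed) between adjacent curve points, with a
   normal-normal Bayes factor on the Fisher-z difference and Zou's
   interval.
5. **Object-level localization** — all same-rank and adjacent-rank
   object pairs in a rank window; the rank composition with the lowest
   mean pairwise similarity localizes the boundary at its mean pair
   size (bootstrap CI).
6. **Synthetic generator** — Bernoulli judgments from a logistic
   boundary model, `p = λ/2 + (1−λ)·g_a·σ(s_a β log2(d/B))`, where `B`
   is the agent's body (diagonal) size, so every stage is verifiable
   against a known ground truth and the boundary can be moved to
   cat- (77 cm), human- (150 cm) or elephant-sized (577 cm) agents.

## Worked example

```python
import affbound as ab

gen = ab.GeneratorConfig(n_participants=200, agent_size_cm=150.0, seed=0)
tensor = ab.simulate(gen)                      # 200 x 14 x 24 judgments
report = ab.run_analysis(tensor, ab.AnalysisConfig(n_permutations=1000, seed=0))

for pair, r in zip(report.rank_curve.pairs, report.rank_curve.r):
    print(f"r{pair} = {r:+.3f}")
t = report.trough
print(f"site {t.site}, T_obs = {t.t_obs:.3f}, p = {t.p_value:.3f}")
print(report.pair_scan.boundary_composition,
      f"{report.pair_scan.boundary_estimate_cm:.1f} cm")
```

prints

```
r(2, 3) = +1.000
r(3, 4) = +1.000
r(4, 5) = -0.973
r(5, 6) = +0.973
r(6, 7) = +1.000
r(7, 8) = +1.000
site (4, 5), T_obs = 1.959, p = 0.108
(4, 5) 120.8 cm
```

The similarity curve is high everywhere except between size ranks 4 and
5 — the pair of octave bins whose shared edge (128 cm) sits just below
the simulated 150 cm agent — so the detected affordance boundary falls
exactly where the generator put it, and the object-level scan localizes
it at ~121 cm. The trough value 1.96 is nearly the theoretical maximum
of 2, yet the permutation p here is only 0.108: with a single latent
size dimension and homogeneous action base rates, label shuffles that
happen to flip the class majority at the tested site reproduce deep
troughs by chance (see `docs/methods.md` for why, and for the
conditions under which the permutation test is well calibrated).
Setting `agent_size_cm=77` moves the detected site to ranks (3, 4) and
`577` to (6, 7).

The same pipeline runs from the shell:

```sh
affbound run --seed 0 --n-participants 200 --out-dir out/
affbound analyze --responses r.csv --objects o.csv --actions a.csv --out-dir out/
```

Input CSVs are long-format judgments (`participant,action,object,
response` with binary responses), object metadata (`object,diagonal_cm,
rank,animate`) and action metadata (`action,action_class`).

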