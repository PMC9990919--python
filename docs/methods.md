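# Methods

## The training–test question of confidence-based aggregation

When a group must answer many binary questions, aggregating members'
answers by majority rule improves accuracy only insofar as members'
errors are diverse enough to cancel. Subjective confidence is the obvious
cue for choosing members — but confidence can only be *measured* on
questions already answered. `crowdwise` formalizes the resulting
cross-validation problem: participants are ranked by confidence on a
small set of training questions, groups are assembled from that ranking,
and group accuracy is evaluated on disjoint test questions. The package's
two simulations probe the two halves of the mechanism: whether
confidence-selected individuals make less diverse judgments (pairwise
accordance), and whether a group's training accuracy predicts its test
accuracy (train/test gap and the test-worse decomposition).

## Synthetic data: the latent-trait generator

Real behavioral data for this design are complete participants ×
questions tables from two-alternative forced-choice tasks (no missing
cells, confidence on a 0–100 visual-analog scale). The generator
reproduces that structure from an item-response-style model:

| parameter | meaning | default |
|---|---|---|
| `n_participants`, `n_questions` | design shape | 150 × 70 |
| `ability_sd` (σ_a) | SD of participant general ability a_p | 0.3 |
| `easiness_sd` (σ_e) | SD of question easiness e_q | 0.7 |
| `item_knowledge_sd` (σ_k) | SD of cell-specific knowledge k_pq | 1.0 |
| `calib_intercept` (γ0) | confidence offset (logit units) | 0.0 |
| `calib_slope` (γ1) | confidence–evidence coupling | 1.0 |
| `confidence_noise_sd` (σ_c) | confidence reporting noise | 0.5 |

Latent evidence `s_pq = a_p + e_q + k_pq` (all terms zero-mean normal)
drives both the response, `correct_pq ~ Bernoulli(σ(s_pq))`, and the
report, `confidence_pq = 100·σ(γ0 + γ1·s_pq + ε_pq)` with
`ε_pq ~ N(0, σ_c²)`. Because `k_pq` is informative only about its own
question, confidence predicts same-question accuracy much better than
other-question accuracy — the signature the within/between analyses
measure — while cross-question predictability rides solely on `ability_sd`.
Setting `γ1 = 0` decouples confidence from accuracy entirely (useful for
type-I-error calibration); `γ1 < 0` produces a "wicked" environment in
which confidence anti-tracks accuracy.

The default shape mirrors a ~150-participant, 70-question study (with a
149 × 25 variant for a second task); the variance components were fixed
once, to make item-specific knowledge the dominant evidence source with
moderate question-difficulty spread and weak general ability — the regime
in which confidence is informative within questions but only weakly
across them.

What the generator does **not** emulate: above-chance mean accuracy (the
zero-mean evidence model pins the population at 0.5 overall, whereas real
participants in these tasks average clearly above chance), response
times, question-content effects, participant exclusion artifacts, or
confidence scale-use idiosyncrasies (end-point pileups, integer
rounding). Tests that pass on synthetic data therefore validate the
*machinery* (ranking, selection, aggregation, resampling, estimation) and
the *qualitative* confidence structure, not quantitative agreement with
any particular behavioral dataset. One knock-on effect is documented
under Limitations.

Reproducibility: one integer seed; substreams are derived per named
stream and per question column (PCG64 via `SeedSequence`), so identical
configs give bit-identical datasets and growing `n_questions` leaves
earlier questions' draws unchanged.

## Within/between-question estimation

Each fit is an ordinary maximum-likelihood logistic regression (via
statsmodels) of a 0/1 correctness vector on a confidence vector, with a
95% Wald interval on the slope. Estimation choices:

- **Convergence policy.** A fit is flagged `converged=False` — never an
  exception — when the outcome vector is constant, the optimizer fails or
  detects perfect separation, the standard error is non-finite, or
  |β| exceeds 50 per confidence unit (a quasi-separation cap; a genuine
  slope of 50 logits per confidence point is not a credible estimate).
  Non-converged fits are removed by `apply_exclusions`, alongside any
  caller-specified excluded questions or ordered pairs.
- **Point estimate.** The MLE plays the role a posterior median would
  play in a Bayesian fit of the same model; the inferential target
  (does the 95% interval contain 0) is preserved. An MCMC estimator
  would add dependencies and nondeterminism without changing the
  qualitative contrast, so it is not the default.
- The between-question analysis fits every ordered pair (i, j), i ≠ j —
  n(n−1) fits — in dataset question order.

## Selection categories and stride positions

Rankings sort participants by descending mean training confidence; exact
ties are broken uniformly at random under an explicit tie seed
(confidence is continuous, so ties matter only in constructed data).
Three category pools are defined on a ranking of N participants:
`highest` = the top `group_size` ranks, `higher` = ranks 1..⌈N/2⌉,
`mixed` = all ranks. Deterministic **stride** selection takes
`group_size` evenly spaced ranks across the pool,
`rank_i = 1 + round((i−1)·pool/group_size)`; at N = 150 with 15 members
this yields ranks 1–15, {1, 6, …, 71} and {1, 11, …, 141}. **Random**
selection samples `group_size` distinct ranks uniformly from the pool
(`highest` stays the deterministic top block, the only size-g subset of
its pool). Simulation 1 uses stride panels; Simulation 2 uses random
groups — the asymmetry is deliberate, matching how the two study designs
differ.

## The simulations

**Simulation 1 (accordance).** Per iteration: draw 10 questions without
replacement, rank by confidence on the first, build a 15-member panel per
category by stride, and average the accordance rate over all 105
unordered member pairs on the 9 remaining questions. The per-category
result is the mean over iterations with a t-based 95% CI (a normal/t
interval on thousands of iteration means is standard; nothing about the
per-iteration averages is heavy-tailed).

**Simulation 2 (group accuracy).** Per iteration: draw `n_train` training
and `n_test` test questions (disjoint, without replacement), rank by mean
training confidence, select a group in random mode, and score
majority-rule accuracy separately on both question sets. The full
condition grid crosses n_train ∈ {1, 5, 10}, group size ∈ {3, 15} and the
three categories. Derived summaries: the test-worse proportion
(iterations with test < train), the mean test−train difference within
those iterations (reported as 0, with a flag, when none exist), and
Cliff's delta between conditions' accuracy vectors.

Per-iteration RNG substreams are keyed by (seed, iteration,
condition tag); setting `common_random_numbers=True` drops the condition
tag so different conditions at the same seed see identical question
splits (paired comparisons). Majority ties cannot occur at the odd
default group sizes; for even sizes they are resolved by a fair coin from
the iteration's substream.

## Supporting statistics

- **Cliff's delta** is computed by rank counting against a sorted copy of
  the second sample (O((n+m) log m)); ties contribute zero, the standard
  convention. The test suite checks exact agreement with an O(nm)
  enumeration oracle and antisymmetry.
- **`mean_ci`** is the t-distribution interval for a mean (≥ 2 values).
- **`anova_required_sample_size`** searches the smallest balanced total N
  (multiple of k) whose one-way ANOVA omnibus power reaches the target,
  with power from the noncentral F distribution (λ = f²N, df1 = k−1,
  df2 = N−k). α = .05 and power = .80 are the conventional planning
  defaults — at k = 3 they yield N = 159 for f = 0.25 and N = 111 for
  f = 0.30 — and both are overridable.

## Numerical conventions and degenerate inputs

- CSV output writes floats at 6 significant digits; datasets round-trip
  losslessly at that precision.
- Dataset ordering is lexicographic in participant and question ids, so
  file row order never affects results.
- Aggregation rules raise an explicit tie error when no tie seed is
  supplied; vote ties are otherwise resolved uniformly at random from a
  seeded generator.
- The logistic σ is evaluated in a numerically stable split form; no
  overflow for extreme latent evidence.

## Test problem sizes

The test suite exercises the pipeline at reduced scale, chosen to keep
the statistical assertions sharp while the whole suite runs in well under
a minute: seeded-recovery checks use 20 dataset seeds with 150 × 10 to
150 × 25 designs, 300–1,000 simulation iterations (against the 5,000 a
full study run would use), and 200 questions for the interval-calibration
check. All Monte-Carlo assertions carry 3-standard-error tolerances
derived from their own sampling variability.

## Known limitations

- The zero-mean latent model keeps overall accuracy at chance, so
  population-level "wisdom of crowds" gains appear only through
  confidence-based selection, not through a baseline p > 0.5 majority
  amplification. Related: the expected accordance-rate gaps between
  selection categories on *held-out* questions are tiny at the default
  `ability_sd` (≈10⁻³ between highest and mixed, smaller still between
  adjacent categories), because cross-question information rides only on
  general ability. The mean gaps are positive, but for an appreciable
  fraction of generated datasets the realized category ordering on
  held-out questions inverts — unlike in real behavioral data, where
  low-confidence responders guess near 0.5 rather than anti-correctly and
  the category ordering is clear-cut.
- Wald intervals are first-order; near-separated fits are excluded rather
  than regularized (no Firth correction).
- The transmission chain adopts the first member's judgment
  unconditionally and never revisits confidence within a chain; no
  deliberation dynamics are modeled.
- The OSF import path for real deposits is the canonical long-format CSV
  only; no download automation.
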