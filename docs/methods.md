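# Methods

## Relative expression orderings

All discovery statistics operate on the within-sample ordering of two genes'
log2 intensities, never on the intensities themselves.  `reo_frequency`
counts samples with strictly E_a > E_b; ties count as "not greater" — a
deterministic, conservative convention that matters only for fixture data,
since ties have measure zero for continuous intensities.  Pairs are
canonicalized as unordered pairs with lexicographically sorted gene ids;
reversal directions are re-signed accordingly, so lists from different runs
are directly comparable.

Because only orderings enter, every screening statistic and the final
classifier are invariant under any strictly increasing per-sample transform.
This is the operational meaning of "robust to batch effects and
normalization", and the property suite asserts it with random per-sample
monotone distortions (a·x + b·x³ + c with a, b > 0).

## Screening cascade

* Differential expression: pooled-variance (Student) two-sided t-test per
  gene, Welch behind a flag.  Genes constant in both groups score p = 1
  (or p = 0 in the pathological constant-but-different case, to keep the
  direction defined).  BH adjustment runs over all tested genes.
* Pair reversal: the 2×2 table of (E_a > E_b vs not) by group, two-sided
  Fisher exact test with the standard "probability at most that of the
  observed table" definition.  The BH family is the set of pairs actually
  tested in the run (all unordered pairs with at least one DE member), not a
  theoretical universe.  Group sizes are fixed within a run, so Fisher
  p-values are cached on the pair of success counts; this collapses ~10⁵
  pair tests to at most (n₁+1)(n₂+1) distinct tables.
* Cross-dataset overlap keeps only same-direction pairs; the inconsistent
  ones are dropped at this step.

## Survival machinery

Kaplan-Meier, log-rank, general Cox PH fits and Harrell's C-index are thin
validated wrappers over lifelines.  Tied event times use the Efron
approximation.  The C-index accepts a binary group label as the risk score
(ties 0.5, unusable pairs excluded), matching how a two-group classifier is
evaluated.

The pair-level prognostic screen fits a univariate Cox model to tens of
thousands of binary REO indicators against one shared cohort.  That hot path
uses `cox_binary_batch`, a vectorized one-dimensional Newton iteration on the
Efron partial likelihood: the risk-set and tied-event counts reduce, for
each distinct event time, to terms A + B·e^β whose coefficients are computed
for all pairs at once by cumulative sums over the time-sorted indicator
matrix.  Agreement with per-covariate lifelines fits is asserted in the test
suite (|Δcoef| < 10⁻³, limited by lifelines' own stopping tolerance).
Monotone likelihoods (an immortal group vs an all-event group) are flagged
(|β| > 15 or vanishing information) and fall back to the log-rank score
test, with a surfaced warning.

## Degenerate-partition guard

The contract that a pair with an empty REO group is skipped is generalized:
partitions (and candidate-set classifications during forward selection)
leaving fewer than `min_group_frac` = 10% of the cohort on either side are
treated as degenerate.  The log-rank statistic on a near-empty stratum is
wildly unstable — a 1-vs-202 split can produce p ≈ 10⁻⁴⁶ from noise — and
rewards candidate sets that merely isolate the few earliest relapses; a
stratifier that flags almost nobody is also clinically useless.  Set
`min_group_frac=0` to recover the empty-only rule.

## Forward selection

The seed is the candidate with the smallest single-pair log-rank p.  One
prognosis-associated pair is then added per iteration until the p-value of
the majority-vote classification stops strictly decreasing (so the selected
set's p is non-increasing by construction).  Two addition rules exist:

* **ranked** (default): candidates are tried one at a time in Cox-p rank
  order; the first non-improving addition stops the selection.
* **greedy**: every unused candidate is scored each iteration and the best
  improvement is added.

Greedy-best is the textbook rule, but with candidate lists in the hundreds
(the realistic output of a p < 0.01 screen over ~10⁴ surviving pairs) it
optimizes the in-sample log-rank p aggressively enough to absorb noise pairs
— in simulation it appended 3–10 non-planted pairs and *lowered* the
classifier's agreement with the true risk label.  The ranked rule adds pairs
in evidence order and stops early, which in simulation recovers subsets of
the planted pairs essentially always; it is also the plainer reading of
"add a prognosis-related gene pair at each iteration".  Ties break on
smaller p, then larger |log HR|, then lexicographic pair id, so runs are
deterministic.

Even-sized signatures use the strict majority (votes > k/2); the threshold
is stored with the signature and validated on load.

## Closed-form consistency statistics

The concordance of two directed DE lists with k shared genes, s agreeing in
direction, is s/k with the upper-tail cumulative binomial p-value
P = 1 − Σ_{i=0}^{s−1} C(k,i) Pe^i (1−Pe)^{k−i}, Pe = 0.5 by default (the
(1−Pe) exponent is k−i; with s = k the tail collapses to Pe^k exactly,
asserted up to k = 1000).  Overlap significance and gene-set enrichment use
the upper-tail hypergeometric with the category universe restricted to
measured, annotated genes.  All tail sums run in log space so k in the
thousands does not underflow; the log10 tail is reported alongside the
probability.

## Synthetic cohorts

The generator emulates a multi-stage colorectal-cancer series: stage I,
stage II split into no-CTX/CTX arms, stage III/IV.  Defaults mirror the
stage margins of a large public series (33 / 203 / 56 / 50) with ~1000
genes and 30 planted pairs.  A latent high/low relapse-risk label (25% high
among stage II — the reported relapse fraction of resected stage II
disease) drives both the planted orderings and the hazard.

* **Orderings.**  Each planted pair shows its high-risk orientation
  (E_a < E_b) with probability f_high = 0.9 in metastatic or latent-high
  samples and f_low = 0.1 otherwise, enforced by swapping the two realized
  values within the sample when they contradict the drawn orientation.
  Swapping preserves each sample's value multiset exactly.
* **Co-expressed pair members.**  The two genes of a pair share one baseline
  mean and one per-sample level, plus small independent noise
  (`pair_noise_sd` = 0.25 vs background σ = 1).  Rationale: enforcing an
  ordering necessarily hands the larger draw to one member, coupling that
  member's *level* to the risk label; with iid members this side channel
  made thousands of (pair-gene, background-gene) combinations genuinely
  prognostic, destroying the "planted pairs are the ground truth" property
  that recovery evaluation needs (the same evaluation-clarity reasoning
  behind planting pairs on disjoint genes).  Co-expression confines the
  leak to ~0.1 log2 units.
* **DE genes.**  Each pair's second gene plus 20 extra genes gain +1 log2
  unit in stage III/IV samples — guaranteeing every planted pair contains a
  metastasis-DE member — with an optional partial shift (`risk_shift`,
  default 0) in latent-high stage II samples to couple the risk label to
  the metastatic program for concordance-pipeline tests.
* **Survival.**  Exponential event times (baseline 0.01/month; hazard ×4
  for latent-high) under independent exponential censoring (0.015/month);
  the CTX arm multiplies the hazard by 2.8 in the low-risk stratum (harm)
  and 0.55 in the high-risk stratum (benefit).  Exponential forms keep the
  true hazard ratios closed-form.
* **Seeding.**  One integer seed feeds separate streams for sample labels,
  background noise, orientations, survival and covariates, so changing the
  orientation probabilities never perturbs the background draw.  Gene roles
  and means live on a separate `assignment_seed` stream; the pipeline gives
  its train/train/validation cohorts one shared assignment seed and
  distinct sample seeds, emulating independent datasets measuring the same
  disease.

What the generator does **not** emulate: probe-level structure, array batch
effects (covered instead by the monotone-distortion property tests),
correlated background genes, non-proportional hazards, and informative
censoring.  Passing recovery tests therefore show the pipeline's statistics
behave as designed under the stated model, not that the method will find
reproducible pairs in any particular real cohort.

## Problem sizes

The recovery suite runs the full discovery chain once per session on the
default cohort (≈84 000 pair tests, ≈12 000 screened pairs, ≈150 Cox-filter
candidates; ~15 s on one CPU).  Null calibration uses 500 balanced
background pairs on a cohort generated with hr_true = 1.  Enumeration
oracles cap instances at n ≤ 30, where exhaustive computation is exact and
fast.

## Known limitations

* The multivariate Cox covariate list is caller-configured; age enters as
  given (continuous) unless dichotomized upstream, and "unknown" covariate
  values are dropped casewise by the Cox fit only.
* `cox_binary_batch` handles a single binary covariate only — by design;
  anything richer goes through lifelines.
* GEO/SOFT parsing and CEL processing are out of scope; inputs are
  already-summarized probe or gene matrices (probe collapse by arithmetic
  mean on the log2 scale is provided).
* The Fisher cache assumes fixed group sizes within one screening run.
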