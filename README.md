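# reosig

Rank-based gene-pair prognostic signatures from within-sample relative
expression orderings (REOs), with a full discovery → validation → application
pipeline and a synthetic-cohort generator that makes every stage testable
without external data.

## The problem

Transcriptional signatures for relapse risk in early-stage (stage II)
colorectal cancer are notoriously irreproducible.  Two culprits addressed
here:

1. **Risk-score signatures are cohort-dependent.**  Classifiers built on
   summarized expression levels need normalization and percentile cutoffs
   computed over the samples analyzed *together*, so one patient's risk call
   can change with the company their sample keeps (and with batch effects).
2. **Mixed treatment arms.**  Pooling patients with and without adjuvant
   chemotherapy (CTX) confounds the relapse endpoint during training.

A REO signature sidesteps the first problem entirely.  For a gene pair
(a, b) and one sample, the only question is whether E<sub>a</sub> &lt;
E<sub>b</sub> *within that sample*.  An ordered set of such pairs, each with
the ordering that votes "high risk", plus a strict-majority threshold,
classifies each patient from their own values alone — invariant under any
strictly increasing per-sample transform, hence robust to batch effects and
normalization, and applicable to a single sample.

## The method

Discovery uses stage I (non-metastatic) vs stage III/IV (metastatic) samples
under the hypothesis that high-relapse-risk stage II disease reflects
micro-metastasis:

1. **Metastasis-DE genes** — Student's t-test, BH-FDR &lt; 0.1.
2. **Reversed pairs** — for every pair with at least one DE member, compare
   the frequency of E<sub>a</sub> &gt; E<sub>b</sub> between metastatic and
   non-metastatic samples (two-sided Fisher exact, BH-FDR &lt; 0.2).
3. **Cross-dataset overlap** — keep pairs reversed in the same direction in
   two independent training datasets.
4. **Prognostic pairs** — in stage II patients *without* CTX, split the
   cohort by each pair's REO and keep pairs with univariate Cox Wald
   p &lt; 0.01, oriented so the worse-survival ordering votes high risk.
5. **Forward selection** — seed with the smallest log-rank-p pair, then add
   one pair at a time until the majority-vote classification's log-rank p
   stops decreasing.
6. **Evaluation** — Kaplan-Meier curves, log-rank test, hazard ratios,
   Harrell's C-index on training and validation cohorts; CTX-stratified
   comparisons inside the predicted risk groups.
7. **Biology checks** — risk-DE vs metastasis-DE overlap (hypergeometric),
   direction concordance (upper-tail cumulative binomial,
   P = 1 − Σ<sub>i&lt;s</sub> C(k,i) P<sub>e</sub><sup>i</sup>(1−P<sub>e</sub>)<sup>k−i</sup>),
   and GMT-based gene-set enrichment with BH adjustment.

The published three-pair signature (ORC1-OLR1, MTNR1A-VGLL1, RFX5-MMP14;
E<sub>a</sub> &lt; E<sub>b</sub> votes high risk, 2-of-3 majority) ships as
`reosig.signature.load_3gps()` for the classify-only workflow.

## Worked example

Generate three synthetic cohorts sharing one planted biology (30 reversed
gene pairs driving an exponential relapse hazard, latent high-risk hazard
ratio 4) and run the whole pipeline:

```bash
cat > config.yaml <<'YAML'
synthetic:
  n_genes: 1000
  n_stage1: 33
  n_stage2_noctx: 203
  n_stage2_ctx: 56
  n_stage34: 50
  n_planted_pairs: 30
  seed: 1
seed: 1
YAML
reosig run-all --config config.yaml --outdir run
```

prints

```
pipeline complete; signature pairs: [['G0438', 'G0471']] -> run
```

and `run/evaluation.json` contains the survival separation of the predicted
risk groups:

```
train1:      log-rank p = 1.95e-14, HR = 4.62 [3.02, 7.07], C-index = 0.676
validation:  log-rank p = 7.83e-07, HR = 2.75 [1.81, 4.18], C-index = 0.639
```

Here the selected pair (G0438, G0471) is one of the 30 planted pairs
(`run/data_train1/truth.json` lists them), its high-risk orientation matches
the planted one, and high-risk patients relapse ≈ 4.6× faster in training
and ≈ 2.8× faster in held-out validation.  The run log also reports the
CTX-stratified contrast: chemotherapy associates with *shorter*
relapse-free survival in predicted low-risk patients (train1 HR ≈ 3.7,
p &lt; 10⁻⁴) and with no harm in predicted high-risk patients — the pattern
the generator plants.

Each stage is also a subcommand (`simulate`, `screen`, `select`,
`classify`, `evaluate`, `concord`, `enrich`) and a plain library call.

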