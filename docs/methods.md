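# Methods

## The problem and the method

Most predictable adverse drug reactions (ADRs) arise from drug activity at
on- or off-target proteins, so identifying the proteins that mediate an ADR
is central to understanding and preventing it. Known (ADR, protein) relations
are scarce (a few thousand curated pairs), while known (drug, ADR) relations
are plentiful (hundreds of thousands of records in SIDER-style resources).
The method implemented here transfers the richer drug-level signal to the
protein level through a network construction:

1. **Integrated network.** Drugs, proteins and *single-target compounds*
   (STCs) form a directed, unweighted heterogeneous graph. Drug → protein
   edges come from chemical–protein interaction records, protein–protein
   interaction (PPI) pairs become bidirectional edge pairs, and one
   fictitious STC per protein is wired to its protein by a single directed
   edge. Drugs and STCs have in-degree 0 by construction. Interaction
   records below a confidence threshold (default 700 on the 0–1000 STRING/
   STITCH scale, applied inclusively) are discarded; drugs without any
   recorded ADR, and target proteins absent from the PPI network, are
   dropped. The directed edge count therefore always satisfies
   `D + 2·P + S` (D kept drug–target pairs, P kept PPI pairs, S proteins).
2. **Embedding.** Second-order biased random walks (return parameter `p`,
   in-out parameter `q`; unnormalized weights 1/p to return, 1 to a common
   out-neighbor of the previous node, 1/q outward) generate a walk corpus
   (`num_walks` walks of `walk_length` nodes from every node), which trains
   skip-gram-with-negative-sampling vectors. Drugs and STCs thereby land in
   the same protein-defined embedding space. Because drugs and STCs have no
   incoming edges, walks leave them immediately and never return; their
   vectors are trained purely from protein context. This is the intended
   construction, not an artifact.
3. **Binary-relevance classification.** One L2-regularized logistic
   regression per ADR is fit on drug vectors (inverse regularization
   strength `C = 0.1`), evaluated by 10-fold drug-level cross-validation
   with per-ADR AUROC and average precision (step-sum definition),
   macro-averaged over ADRs with at least 10 positive drugs.
4. **STC read-out.** Each trained classifier is applied to every STC's
   vector; the predicted probability is the relation score between the STC's
   protein and the ADR. Per-ADR descending-score rankings (average ranks on
   ties; percentile = 100·rank/N) prioritize proteins.

## Evaluation statistics

Treating "drug targets protein" as a diagnostic test for "drug has ADR"
yields a 2×2 table per (ADR, protein) pair over the labeled-drug universe,
from which:

* PPV = TP/(TP+FP); prevalence = (TP+FN)/N;
* VAPPV = PPV − prevalence (0 under independence);
* LR = TP·(FP+TN) / (FP·(TP+FN)) (1 under independence).

Top-50 predicted proteins per ADR are summarized by mean VAPPV and LR after
dropping pairs with protein support < 5 drugs or ADR support < 5 drugs.
Benchmark recovery reports the percentile of each known pair and the
fractions recovered in the top 5% / 20%. A balanced evaluation resamples
negatives (non-positive combinations over the benchmark's own ADRs and
proteins) to the size of the positive set 1000 times and reports AUROC/AP
distributions. Similarity analyses correlate drug-pair ADR-set Jaccard with
embedding cosine (Spearman), and compare within-group cosine similarity of
ADR score vectors against the no-shared-label baseline with Welch t-tests
(Benjamini–Hochberg adjusted across labels).

### Numerical conventions

* **Infinite/undefined LR.** When FP = 0 or TP+FN = 0 the likelihood ratio
  is continuity-corrected by adding 0.5 to all four cells (Haldane–
  Anscombe); the correction is flagged on the result.
* **Undefined PPV.** When no drug targets the protein, PPV and VAPPV are
  reported as undefined (`None`) and excluded from averages, never imputed
  as zero; exclusion counts are reported.
* **AUROC ties** get half credit (Mann–Whitney convention); **AP** is the
  non-interpolated step sum.
* **Ranking ties** receive average ranks; top-k boundary ties break by
  lexicographic protein identifier so runs are reproducible.
* **Duplicate interaction records** (symmetric listings) collapse to one
  record keeping the maximum score; self-loops are dropped.

## Synthetic data generator

The generator emits the same TSV dialects the pipeline reads, with planted
ground truth, so every stage is testable offline:

* Proteins are split into equal-size modules (remainder to the last) and
  wired by a stochastic block model (`p_in` within, `p_out` between).
  Isolated proteins (possible at small probabilities) are reconnected to a
  random same-module partner so every protein appears in the PPI table.
* Each ADR gets one causal module, round-robin, so every module is causal
  for some ADR whenever `n_adrs ≥ n_modules`.
* Each drug draws `n_targets_per_drug` targets without replacement — from
  one random module with probability `focus_prob`, otherwise uniformly; if
  the focal module is smaller than the target count the remainder is drawn
  outside it.
* A drug acquires an ADR with probability `theta_hi` if it targets the
  ADR's causal module, else `theta_lo`. `theta_hi = theta_lo` defines the
  null world in which targets and ADRs are independent.
* Confidence scores are uniform on [threshold, 1000] so read-time filtering
  is exercised but lossless; `low_score_fraction` adds sub-threshold decoy
  records to test the filter. Drugs that sample zero ADRs stay in the
  target table deliberately — dropping them is the network builder's job.

### Default study conditions

The planted defaults are 300 proteins in 10 modules, 120 drugs, 20 ADRs,
`p_in = 0.3`, `p_out = 0.01`, `focus_prob = 0.7`, `theta_hi = 0.8`,
`theta_lo = 0.05`. The null-baseline analyses use 200 proteins, 400 drugs,
20 ADRs, `theta = 0.15`, ten seeds.

`n_targets_per_drug` defaults to 15. Real high-confidence chemical–protein
data sit in the tens-of-targets-per-drug regime (≈29 on average at the 700
threshold), and the choice matters statistically: with only a handful of
targeting drugs per protein the pooled mean LR under independence is biased
above 1 (Jensen inequality on TP/FP at small counts), obscuring the
analytic baseline. Fifteen targets per drug keeps per-protein support in
the tens while leaving module-focused sampling feasible for 20–30-protein
modules.

What the generator does **not** emulate: real STRING/STITCH score
distributions, degree heterogeneity and hub structure of real interactomes,
chemical structure, polypharmacology beyond the module/diffuse dichotomy,
and the MedDRA term hierarchy. Passing tests therefore demonstrate that the
implementation recovers planted causal structure under block-model
assumptions, not that the method attains any particular accuracy on real
databases.

## Embedding and training choices

* Skip-gram training follows word2vec conventions: dynamic window (uniform
  on 1..window), unigram^0.75 noise distribution, 5 negative samples,
  learning rate decaying linearly from 0.025 to 0.0001, input vectors
  initialized uniformly in ±0.5/d, context vectors at zero. Training is a
  single-threaded, numba-compiled sequential SGD loop; under a fixed seed it
  is bit-reproducible (the deliberate reproducibility mode — no multi-worker
  speed mode is provided).
* Defaults follow common benchmark practice: d = 128, 10 walks of length 80
  per node, window 10, 5 epochs. The package's own evaluation scales these
  down (d = 64, walk length 40) to keep full-pipeline runs around ten
  seconds per seed on one CPU.
* `p = q = 1` by default; the published tuning loop is reproduced by
  `optimize_walk_params`, a grid search maximizing cross-validated macro
  AUROC with ties broken toward (1, 1).
* **Column standardization before the logistic fit.** The in-package SGD
  trainer leaves embedding dimensions on unequal scales, and an L2-penalized
  linear model is scale-sensitive: on the planted world, raw-coordinate fits
  reach cross-validated macro AUROC ≈ 0.62 against an oracle ceiling of
  ≈ 0.79 computed from the true module-exposure features, while z-scored
  features recover ≈ 0.75. The classifier therefore standardizes feature
  columns (training-fold statistics during cross-validation) and folds the
  scaler back into the stored weights and intercepts, so persisted models
  apply directly to raw embedding vectors.

## Cross-validation protocol

One shared unstratified drug-level fold partition serves all ADRs (labels
live on drugs). Out-of-fold probabilities are pooled per ADR before
computing AUROC/AP. ADRs with fewer than `min_drugs = 10` *positive* drugs
are excluded from the report (the support rule is read on positives);
training folds that collapse to a single class fall back to predicting the
training prevalence. ADRs skipped at final training (all-positive or
all-negative columns) are listed on the model bundle, never silently
dropped.

## Open choices resolved in this package

* The negative pool for balanced benchmark evaluation is all (ADR, protein)
  combinations over the benchmark's own ADRs and proteins minus the
  positives.
* Grouped score-vector similarity treats ADR *pairs* as the test unit; the
  pairs sharing a label are not independent (each ADR contributes to many
  pairs), so the reported p-values are anti-conservative and should be read
  as descriptive.
* The confidence-threshold selector reports Pearson correlations per
  threshold and breaks ties toward the smallest threshold; thresholds
  leaving fewer than two drugs with targets, or degenerate similarity
  vectors, are reported as undefined rather than dropped silently.
* Stage seeds derive from the single global seed by fixed offsets
  (simulate +0, embed +1, train +2, evaluate +3), so stages can be rerun
  independently yet reproducibly.

## Problem sizes used by the test suite

The packaged evaluation runs at desk scale by design: the planted-module
pipeline checks use the 300-protein default world at d = 64 with three
seeds (≈ 10–15 s per seed on one CPU); the null-baseline checks use ten
200-protein/400-drug worlds; walk-bias frequency checks draw ≥ 10⁵
conditional steps on a 4-node toy graph. The `scripts/acceptance.py` entry
point recomputes the null-world baselines from scratch with the same
configuration.

## Known limitations

* The block-model worlds are far smaller and more regular than real
  interactomes; absolute performance numbers on them do not transfer.
* The embedding trainer is single-threaded; at real database scale
  (10⁴–10⁵ nodes, 10⁶ edges) a session would take hours, and a
  multi-worker trainer (with relaxed determinism) would be the natural
  extension.
* Identifier harmonization across databases (Ensembl/UniProt, CID flavors)
  is out of scope; inputs are assumed pre-harmonized.
* Only one embedding backend is provided; the per-ADR classifier is
  logistic regression only, and no probability calibration is applied.
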