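# Methods

## Model and assumptions

`umamistack` treats umami peptide identification as supervised binary
classification of short sequences (validated over the 20 standard
amino-acid letters; non-standard residues are rejected rather than
imputed, because every descriptor below assumes the canonical
alphabet). The classifier is a two-level stack:

* **Level 0** — 42 baseline models, the cross product of six learners
  (ET, KNN, LR, PLS, RF, SVM) and seven descriptor families (AAC, DPC,
  CTDC, CTDT, CTDD, PAAC, APAAC). Each baseline outputs P(umami).
* **Level 1** — an RBF-kernel SVM trained on a pruned subset of the
  baselines' out-of-fold probabilities (PF), their 0.5-thresholded
  class calls (CF), or both (CPF). Subset and SVM cost C are chosen
  jointly by a genetic algorithm maximizing cross-validated MCC.

The central assumption is that class-discriminating information lives
in residue composition and short-range sequence order; no structural,
positional-motif or physicochemical-profile features beyond the seven
descriptor families are used.

## Descriptor definitions and conventions

* AAC: `f(i) = N(i)/L`, alphabetical residue order; sums to 1.
* DPC: `f(i,j) = N(i,j)/(L-1)` over the L−1 overlapping ordered pairs,
  lexicographic order; needs L ≥ 2; sums to 1.
* CTD: 13 physicochemical property tables, each partitioning the 20
  residues into 3 disjoint exhaustive groups (hydrophobicity under
  seven scales, van der Waals volume, polarity, polarizability, charge,
  secondary structure, solvent accessibility — the convention of the
  widely used protein-descriptor toolkits). CTDC is the per-group
  residue fraction (13×3 = 39; each property triple sums to 1). CTDT is
  the adjacent cross-group transition rate `(N(r,s)+N(s,r))/(L−1)` for
  the three unordered group pairs (39). CTDD reports, per group, the
  sequence positions — as percent of L, 1-based — of the first
  occurrence and of the 25/50/75/100 % quantile occurrences, with
  quantile index `ceil(q·n_group)` and five zeros for absent groups
  (13×3×5 = 195).
* PAAC/APAAC: Chou's pseudo-composition with λ = 1 (forced by the
  21/22-D layout) and weight ω = 0.05. Property values (hydrophobicity,
  hydrophilicity, side-chain mass) are standardized to zero mean and
  unit population variance over the alphabet. PAAC's order term θ_d
  averages the mean squared property difference over residue pairs at
  distance d; the assembled vector `[f_i/Z, ωθ_d/Z]`,
  `Z = 1 + ωΣθ`, sums to 1. APAAC uses per-property products
  H_k(R_i)·H_k(R_{i+d}) of the two amphiphilic properties (2λ signed
  terms), so only its construction — not sum-to-one — is guaranteed.

Feature orders are fixed (alphabetical residues, lexicographic
dipeptides, property-major/group-minor CTD) so matrices are
bit-reproducible.

## Baseline hyperparameters

Pinned explicitly rather than inherited: ET/RF 100 trees; KNN k = 5
Euclidean (capped at the training-set size on tiny folds); LR L2 with
C = 1; SVM RBF, C = 1, gamma scaled by 1/(d·Var X), with a Platt-style
logistic calibration fitted on the training decision scores (the
contract is monotonicity in the margin and range [0, 1]); PLS with 2
components (capped by feature/sample counts), regressing on {0, 1} and
clipping the response into [0, 1] as a pseudo-probability — the minimal
standard construction for using a regressor as a scorer. Every
stochastic trainer is seeded from a master seed hashed with the
baseline name.

## Stacking

Training meta-features are strictly out-of-fold: one stratified k-fold
partition (default k = 10) is shared by all 42 baselines, and the model
scoring a peptide never saw it. Resubstitution scoring is available
behind a flag for diagnostics only — with a memorizing learner it
reproduces even shuffled labels perfectly, which is exactly the leakage
the out-of-fold contract prevents (this contrast is a test). CF uses
the strict rule: probability > 0.5 ⇒ 1, so exactly 0.5 ⇒ 0. Inference
meta-features come from baselines refit on the full training set.

## GA selection

Chromosome: n binary feature genes + 3 cost bits (MSB first), decoded
`value mod 6` into {1, 2, 4, 8, 16, 32} so all 8 patterns are valid and
mutation stays closed; an all-zero mask is repaired by activating one
random gene (logged). Fitness is the mean k-fold cross-validated MCC of
the masked-column RBF SVM; single-class test folds contribute 0. The
search is a generational GA — tournament size 2, uniform crossover
(rate 0.8), per-gene bit-flip mutation (rate 1/n_genes), one elite —
followed by single-bit-flip hill climbing on the best chromosome until
no improvement. Ties prefer fewer features, then lower C. Because the
fitness fold assignment is fixed per run (seeded independently of
evolution), fitness values are memoised per (mask, C); on small
matrices the GA therefore explores most of the genotype space and
matches exhaustive search (a test, against a brute-force oracle over
all non-empty masks × costs).

Defaults (population 50, 100 generations) are deliberately generous;
the compact configurations used in tests and the acceptance script are
stated below.

## Evaluation

Metrics come from the confusion counts with class 1 positive; BACC is
exactly (Sn+Sp)/2; MCC (and Sn/Sp/ACC) report 0 on a zero denominator
so reports are total. AUC is computed by scikit-learn's rank-based
routine and cross-checked in tests against an O(n²)
pairwise-concordance oracle at 1e-12. The CV protocol is repeated
stratified k-fold (defaults 10×10); within each repetition out-of-fold
predictions are pooled into a single confusion table (micro averaging —
chosen because per-fold Sn over 2–3 positives is too noisy to average),
then repetitions are averaged. Cross-validated evaluation of the whole
meta-predictor is *nested*: stacking, GA selection and the meta-SVM are
re-run inside each outer training partition, so feature selection never
sees outer test folds.

## Synthetic data

The generator samples residues i.i.d. from
`(1−δ)·uniform + δ·profile`, lengths uniform on [2, 30]; sequences are
deduplicated by resampling. Default profiles encode mild, realistic
bias: positives double the uniform mass on E and D (the acidic residues
associated with umami), negatives double F/L/W/P (bitter-associated;
bitter peptides are the natural negative class). A Bayes-optimal
analysis of these defaults (per-residue Kullback–Leibler divergence
≈ 0.09 nats over typical lengths) caps achievable MCC near ~0.6, so
the *high-signal* study condition used for signal-recovery validation
(`high_signal_config`) concentrates 0.35 mass each on E/D for positives
and 0.175 each on F/L/W/P for negatives, making near-perfect recovery
attainable at δ = 1 while δ = 0 remains exchangeable.

What the generator does not emulate: positional grammar, length–class
correlation, homology between train and test, or real umami motifs.
Passing the synthetic tests therefore demonstrates that the pipeline
recovers compositional signal without leaking labels — not that it
attains any particular accuracy on real peptides.

## Problem sizes and numerical choices

Chosen as the package's study scales: end-to-end signal-recovery runs
use 25+25 peptides, 3 outer folds × 1 repetition, 3-fold stacking and a
compact GA (population 10–12, 4–6 generations, 3-fold fitness) — at
full effect the nested cv MCC still averages ≥ 0.9. GA-recovery tests
use 120 samples with 10-fold fitness (at smaller n, noise columns
genuinely raise cross-validated MCC, so selection overfits — an
instructive property of the selection criterion, not a bug). The
GA-versus-exhaustive check uses 8 columns × 40 samples. Tolerances:
encoder-vs-oracle 1e-12, sum-to-one 1e-9, GA-vs-exhaustive 1e-9.

## Limitations

* The original curated benchmark is an optional external input; all
  in-repo validation is synthetic or closed-form.
* PLS probabilities are clipped regression responses, not calibrated.
* The GA is a heuristic; optimality is only guaranteed (and tested) on
  small search spaces.
* With small samples the MCC-maximizing selection criterion itself
  overfits; reported selection fitness is not an unbiased performance
  estimate — use the nested CV evaluation for that.
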