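# umamistack

Stacked meta-learning for umami peptide identification from sequence.

Umami ("savory") peptides are short amino-acid sequences — typically a
handful to a few dozen residues — that elicit the fifth basic taste, and
finding them by sensory panels or chromatography is slow and expensive.
`umamistack` implements a sequence-only machine-learning meta-predictor
for screening candidate peptides: given a peptide over the 20 standard
residues it returns P(umami) and a binary call.

## The method

1. **Feature encoding.** Each peptide is described by seven classical
   descriptor families with fixed dimensions: amino-acid composition
   (AAC, 20-D), dipeptide composition (DPC, 400-D), grouped
   physicochemical composition / transition / distribution descriptors
   (CTDC 39-D, CTDT 39-D, CTDD 195-D, over 13 property tables that each
   partition the alphabet into 3 groups), and pseudo amino-acid
   composition with sequence-order correlation terms (PAAC 21-D, APAAC
   22-D; λ = 1, ω = 0.05).
2. **Baseline grid.** Six learners — extremely randomized trees (ET),
   k-nearest neighbours (KNN), logistic regression (LR), partial least
   squares (PLS), random forest (RF) and a support vector machine (SVM)
   — are each paired with the seven encodings, giving 42 baseline models
   named `ALGORITHM-ENCODING` (e.g. `RF-PAAC`).
3. **Feature representation learning.** Under a shared stratified
   10-fold partition, each baseline's *out-of-fold* P(umami) for each
   training peptide becomes one column of a probabilistic feature matrix
   (PF, 42-D). Thresholding PF at 0.5 (strictly greater ⇒ 1) gives the
   class features (CF, 42-D); their concatenation is CPF (84-D).
4. **GA feature selection with SVM cost tuning.** A genetic algorithm
   whose chromosome holds one binary gene per meta-feature column plus a
   3-bit gene encoding the SVM cost C ∈ {1, 2, 4, 8, 16, 32} maximizes
   the cross-validated Matthews correlation coefficient (MCC) of an
   RBF-kernel meta-SVM, with ties broken toward fewer features and lower
   C.
5. **Final meta-predictor.** The meta-SVM is fitted on the selected
   columns; at inference the columns come from baselines refit on the
   full training set.

Evaluation uses ACC, Sn, Sp, BACC = (Sn+Sp)/2, MCC and ROC-AUC, under
repeated stratified 10-fold cross-validation (pooled out-of-fold
predictions per repetition, averaged over repetitions).

## Worked example

```python
import umamistack as us

train = us.generate_dataset(us.high_signal_config(n_pos=20, n_neg=20, seed=11))
model = us.train_umami_predictor(
    train, mode="PF",
    ga_cfg=us.GAConfig(population_size=12, generations=6, fitness_folds=3, seed=0),
    plan=us.StackingPlan(k=3, seed=0), seed=0,
)
for rec in us.predict(model, [us.Peptide("acidic", "EDGEEDSA"),
                              us.Peptide("bitter", "FFLWPLGL")]):
    print(rec.id, rec.probability, rec.label)
```

prints (from `examples/train_and_predict.py`):

```
selected meta-features: ['KNN-CTDC']
meta-SVM cost C = 1, selection fitness (cv MCC) = 1.000
 acidic: P(umami) = 0.934 -> label 1
 bitter: P(umami) = 0.066 -> label 0
  mixed: P(umami) = 0.458 -> label 0
```

The glutamate/aspartate-rich peptide scores high (these acidic residues
drive umami perception), the bitter-profile peptide scores low, and the
GA kept a single baseline column that already separates this synthetic
training set perfectly. More narrative walk-throughs live in
`examples/` (one script per capability: encoding, training/prediction,
GA selection, metrics/CV).

A thin CLI mirrors the library: `umamistack encode|train|predict|
evaluate|gasar` (see `umamistack --help`); labels come from a
`id<TAB>label` table or `|0`/`|1` FASTA header suffixes.

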