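"""Confusion-count metrics and repeated stratified cross-validation.

Reconstructs an integer confusion table from a printed operating point
(sensitivity 0.786, specificity 0.934 over 28 positives and 61
negatives) and derives the remaining metrics from it; then demonstrates
the repeated stratified 10-fold CV protocol with a simple
composition-based classifier.
"""

import umamistack as us

c = us.counts_from_rates(0.786, 0.934, n_pos=28, n_neg=61)
print(f"reconstructed counts: TP={c.tp} FN={c.fn} TN={c.tn} FP={c.fp}")
r = us.compute_metrics(c)
print(f"ACC={r.acc:.3f} BACC={r.bacc:.3f} Sn={r.sn:.3f} "
      f"Sp={r.sp:.3f} MCC={r.mcc:.3f}")


def svm_aac_scorer(train_ds, test_ds, seed):
    spec = us.BaselineSpec("SVM", "AAC")
    model = us.fit_baseline(
        spec, us.encode_dataset(train_ds, "AAC").to_numpy(), train_ds.labels, seed=seed
    )
    return us.predict_proba(model, us.encode_dataset(test_ds, "AAC").to_numpy())


ds = us.generate_dataset(us.high_signal_config(n_pos=20, n_neg=20, seed=3))
res = us.repeated_stratified_cv(
    ds, svm_aac_scorer, us.CVProtocol(k=10, repetitions=10, seed=0)
)
print(f"\nSVM-AAC on synthetic data, 10x10-fold CV: "
      f"MCC={res.mean.mcc:.3f} AUC={res.mean.auc:.3f} (mean of 10 repetitions)")
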