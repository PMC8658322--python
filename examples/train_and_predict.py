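"""Train the full meta-predictor on synthetic peptides and score new ones.

The pipeline encodes the training peptides seven ways, trains the 42
baseline models, stacks their out-of-fold umami probabilities into a
42-column meta-representation, lets the genetic algorithm pick
informative columns while tuning the meta-SVM cost, and fits the final
classifier. Printed probabilities are P(umami); labels use the strict
0.5 threshold.
"""

import umamistack as us

train = us.generate_dataset(us.high_signal_config(n_pos=20, n_neg=20, seed=11))
model = us.train_umami_predictor(
    train,
    mode="PF",
    ga_cfg=us.GAConfig(population_size=12, generations=6, fitness_folds=3, seed=0),
    plan=us.StackingPlan(k=3, seed=0),
    seed=0,
)
print(f"selected meta-features: {model.selected_features}")
print(f"meta-SVM cost C = {model.C}, "
      f"selection fitness (cv MCC) = {model.ga_result.best_fitness:.3f}")

candidates = [
    us.Peptide("acidic", "EDGEEDSA"),     # glutamate/aspartate rich
    us.Peptide("bitter", "FFLWPLGL"),     # bitter-associated residues
    us.Peptide("mixed", "AGSTKLYE"),
]
for rec in us.predict(model, candidates):
    print(f"{rec.id:>7}: P(umami) = {rec.probability:.3f} -> label {rec.label}")
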