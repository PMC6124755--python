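"""Fit the top-scoring-pair classifier and predict the blinded set.

The exhaustive search scores all 378 parameter pairs on the 57-animal
training set and returns the pair with the largest between-class rank-order
difference delta = |p1 - p2|. Prediction is the y = x rule in that pair's
plane.
"""

from stresspair import confusion, fit_tsp, generate_cohort, subset_split
from stresspair import CohortConfig

fm = generate_cohort(CohortConfig(seed=1)).to_feature_matrix()
train, valid = subset_split(fm, "train"), subset_split(fm, "validation")

model = fit_tsp(train)
print(f"selected pair : {model.pair}")
print(f"delta         : {model.delta:.3f}   (gamma tie-break {model.gamma:.2f})")
print(f"orientation   : predict {model.orientation!r} when {model.feature_i!r}"
      f" < {model.feature_j!r}\n")

print("runner-up pairs by delta:")
for s in model.pair_scores[1:4]:
    print(f"  {s.delta:.3f}  ({s.feature_i}, {s.feature_j})")

cm = confusion(valid.labels, model.predict(valid))
print("\nblinded-set confusion (rows = actual):")
print(cm.to_dataframe().to_string())
print(f"correctly classified {cm.correct}/{cm.total} ({100 * cm.accuracy:.1f}%), "
      f"prediction error {cm.prediction_error:.3f}")
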