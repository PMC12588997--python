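"""Small end-to-end regression: features -> screening -> 7:2:1 split -> MLP.

Uses 60 synthetic laboratory leaves (fast); the full-scale recovery
experiment in scripts/acceptance.py runs the same path with n = 300.
"""

from leafchem.estimators import ModelSpec, evaluate, train
from leafchem.pipeline import feature_matrix, leaf_feature_dataset
from leafchem.screenaug import pearson_screen, split_7_2_1
from leafchem.synthgen import SceneSpec

spec = SceneSpec(seed=5, noise_sigma=0.005, illumination_jitter=0.02)
table = leaf_feature_dataset(spec, n_leaves=60)
X, cols = feature_matrix(table)
y = table["nitrogen"].to_numpy()

screened = pearson_screen(X, y, threshold=0.5)
top = screened.scores.sort_values(ascending=False).head(4)
print(f"Pearson |r| > 0.5 keeps {len(screened.selected_names)} of {len(cols)} features")
print("strongest nitrogen correlates:")
for name, score in top.items():
    print(f"  {name:28s} |r| = {score:.3f}")

parts = split_7_2_1(len(table), seed=5)
model = train(ModelSpec(architecture="MLP", seed=5, epochs=200),
              X.iloc[parts.train], y[parts.train],
              X.iloc[parts.val], y[parts.val], feature_names=cols)
report = evaluate(model, X.iloc[parts.test], y[parts.test])
print(f"held-out nitrogen: R^2 = {report.r2:.3f}, RMSE = {report.rmse:.3f} % "
      f"(n = {report.n})")
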