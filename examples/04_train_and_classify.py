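"""Train the FT-Transformer on selected features and classify held-out clips.

Each 2 s window's selected feature vector is one tabular sample; the model
tokenizes every numerical feature, prepends a [CLS] token, runs PreNorm
encoder layers and predicts alert (0) vs fatigue (1) from the final [CLS]
representation.
"""

import numpy as np

from asft import fttransformer as ftt
from asft.features import extract_study_features
from asft.select import SelectionConfig, fit_selection
from asft.synthetic import SimConfig, simulate_study

table = extract_study_features(simulate_study(
    SimConfig(n_subjects=6, duration_s=30.0, seed=3)))

selection = fit_selection(table, SelectionConfig(min_combos=16, k=8,
                                                 svm_folds=5, seed=3))
selected = selection.apply(table)
print(f"selected table: {selected.n_samples} × {selected.n_columns} "
      f"({len(selection.retained_features)} features × "
      f"{len(selection.retained_channels)} channels × 4 bands)")

rng = np.random.default_rng(3)
holdout = rng.random(selected.n_samples) < 0.25
train = selected.take(np.flatnonzero(~holdout))
val = selected.take(np.flatnonzero(holdout))

cfg = ftt.FTTConfig(d_embed=32, n_layers=1, n_heads=1, ffn_hidden=64,
                    dropout=0.0, epochs=6, batch_size=32, seed=3)
model = ftt.fit(train, cfg=cfg)
print(f"final training loss: {model.loss_history[-1]:.4f}")

proba, labels = ftt.predict(model, val)
truth = ftt.labels_from_table(val)
print(f"held-out clips: {len(truth)}, accuracy "
      f"{(labels == truth).mean():.3f}")
print("first 5 fatigue probabilities:", np.round(proba[:5, 1], 3))
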