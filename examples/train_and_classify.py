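"""Train the one-vs-one SVM-RBF end to end on synthetic sequences.

Sequence fixtures -> curation -> 70-feature table (thermodynamic folding)
-> training with the default operating point (C=8, gamma=0.003, z-scored)
-> prediction on the training rows. With this few sequences per class the
point is the mechanics, not the headline accuracy.
"""

from ncrclass.classifier import ModelSpec, train
from ncrclass.features import feature_table
from ncrclass.fixtures import FixtureSpec, make_class_dataset
from ncrclass.folding import ThermoBackend

seqs, labels = make_class_dataset(FixtureSpec(n_per_class=6, seed=2))
df = feature_table(seqs, ThermoBackend())

model = train(df, labels, ModelSpec(seed=0))
pred, scores = model.predict(df.to_numpy(float))

agree = (pred == labels).mean()
print(f"classes: {model.classes}")
print(f"training rows per class: {model.n_train_per_class}")
print(f"training-set agreement: {agree:.3f}")
print()
print("first five predictions with pairwise-vote counts:")
cols = list(model.classes)
for i in range(5):
    votes = ", ".join(f"{c}={int(scores.iloc[i][c])}" for c in cols)
    print(f"  {df.index[i]:12s} -> {pred[i]:8s}  ({votes})")
print()
print(
    "Each row's class wins the most of the 28 pairwise SVM contests; the\n"
    "vote counts show how decisively (7 = won every pairing)."
)
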