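"""Compute the 70-feature table for a small synthetic labelled dataset.

Generates a few sequences per class with the fixture generator, extracts
length, AU%, MFEI, ND, Npb, NQ and the 64 3-mer rates for each, and prints
the scalar block per class.
"""

from ncrclass.features import feature_table
from ncrclass.fixtures import FixtureSpec, make_class_dataset
from ncrclass.folding import ThermoBackend

seqs, labels = make_class_dataset(FixtureSpec(n_per_class=3, seed=11))
df = feature_table(seqs, ThermoBackend())

scalars = df[["length", "au_percent", "mfei", "nd", "npb", "nq"]].copy()
scalars["class"] = labels
print(scalars.groupby("class").mean().round(3))
print()
print(
    f"full table: {df.shape[0]} sequences x {df.shape[1]} features "
    "(6 scalars + 64 3-mer rates per 100 nt).\n"
    "The hairpin-built 'pre-miR' class shows the highest Npb (pairing\n"
    "propensity) and a high MFEI, the designed contrast the classifier uses."
)
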