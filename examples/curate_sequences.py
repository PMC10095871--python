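"""Curate a small mixed-quality FASTA: normalise, reject ambiguity, dedup.

Builds an in-memory set of records the way they arrive from public ncRNA
collections (DNA spelling, lowercase, ambiguity codes, repeated sequences),
then runs the curation pass and prints what survived and why.
"""

from ncrclass.seq_io import curate

records = [
    ("tRNA-1", "GCGGAUUUAGCUCAGUUGGG"),     # clean RNA spelling
    ("tRNA-1-copy", "gcggauuuagcucaguuggg"),  # same sequence, lowercase
    ("mir-x", "ACGTACGTACGTACGTACGT"),        # DNA spelling: T -> U
    ("broken", "ACGUNNNACGU"),                # ambiguous N: rejected
    ("snoRNA-7", "AUGGCUACGAUCGAUCGAUU"),
]

kept, report = curate(records)

print("kept sequences:")
for s in kept:
    print(f"  {s.id:12s} {s.residues}")
print()
print(report.to_tsv())
print(
    "n_read splits exactly into kept + rejected(degenerate) + duplicates;\n"
    "the lowercase copy collapsed onto tRNA-1 because duplicate detection\n"
    "uses the normalised residue string, not the header."
)
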