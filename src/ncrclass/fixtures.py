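"""Synthetic sequence and feature-space datasets for testing and examples.

Everything here is a pure function of its parameters plus a seed, so tests
and examples run without any download. Two kinds of fixture:

* sequence fixtures — random-composition sequences and designed hairpins,
  assembled into class-labelled datasets whose length/AU/pairing contrasts
  loosely mimic real ncRNA classes (a ~21-nt "miRNA"-like class, a 200+-nt
  "lncRNA"-like class, a strongly paired hairpin "pre-miR"-like class, ...);

* feature fixtures — isotropic Gaussian clusters in the 70-dimensional
  feature space at a controllable inter-class separation (in units of the
  within-class SD), the classifier's test bed: separation >> 1 is separable
  by construction, separation 0 is indistinguishable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .seq_io import RnaSequence

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

DEFAULT_CLASSES = (
    "lncRNA",
    "miRNA",
    "pre-miR",
    "rRNA",
    "snoRNA",
    "snRNA",
    "tRNA",
    "others",
)


@dataclass(frozen=True)
class FixtureSpec:
    n_per_class: int = 50
    classes: tuple[str, ...] = DEFAULT_CLASSES
    seed: int = 0
    separation: float = 10.0  # inter-class distance in within-class SDs
    length_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "lncRNA": (200, 400),
            "miRNA": (18, 24),
            "pre-miR": (60, 120),
            "rRNA": (100, 200),
            "snoRNA": (70, 140),
            "snRNA": (20, 100),
            "tRNA": (70, 90),
            "others": (100, 300),
        }
    )
    au_targets: dict[str, float] = field(
        default_factory=lambda: {
            "lncRNA": 0.59,
            "miRNA": 0.55,
            "pre-miR": 0.62,
            "rRNA": 0.49,
            "snoRNA": 0.60,
            "snRNA": 0.54,
            "tRNA": 0.49,
            "others": 0.50,
        }
    )


def make_random_seq(
    length: int, au_fraction: float, seed: int | np.random.Generator
) -> RnaSequence:
    """i.i.d. sequence with P(A)=P(U)=au/2 and P(G)=P(C)=(1-au)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= au_fraction <= 1:
        raise ValueError("au_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    p = [au_fraction / 2, (1 - au_fraction) / 2, (1 - au_fraction) / 2, au_fraction / 2]
    residues = "".join(rng.choice(list("ACGU"), size=length, p=p))
    return RnaSequence(f"rand_L{length}", residues)


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def make_hairpin(
    stem_len: int,
    loop_len: int,
    gc_fraction: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> RnaSequence:
    """A perfect hairpin: stem + loop + reverse complement of the stem.

    The loop is all-A (A cannot pair with itself, keeping the designed fold
    dominant). loop_len < 3 would violate the minimum hairpin loop and is
    refused. Under folding, the pairing propensity is at least close to
    stem_len / (2*stem_len + loop_len).
    """
    if stem_len < 1:
        raise ValueError("stem_len must be >= 1")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (minimum hairpin loop)")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    stem = "".join(
        rng.choice(["G", "A"], p=[gc_fraction, 1 - gc_fraction])
        for _ in range(stem_len)
    )
    residues = stem + "A" * loop_len + reverse_complement(stem)
    return RnaSequence(f"hairpin_s{stem_len}_l{loop_len}", residues)


def make_class_dataset(spec: FixtureSpec) -> tuple[list[RnaSequence], list[str]]:
    """Labelled synthetic sequences with per-class length/AU/pairing profiles.

    Directional contrasts only (orderings of length, AU content, and the
    hairpin-built "pre-miR" class's pairing excess) — not calibrated moments.
    """
    rng = np.random.default_rng(spec.seed)
    seqs: list[RnaSequence] = []
    labels: list[str] = []
    for cls in spec.classes:
        lo, hi = spec.length_ranges.get(cls, (50, 200))
        au = spec.au_targets.get(cls, 0.5)
        for i in range(spec.n_per_class):
            length = int(rng.integers(lo, hi + 1))
            if cls == "pre-miR":
                stem = max(4, (length - 4) // 2)
                s = make_hairpin(stem, length - 2 * stem, gc_fraction=0.7, seed=rng)
            else:
                s = make_random_seq(length, au, rng)
            seqs.append(RnaSequence(f"{cls}_{i}", s.residues))
            labels.append(cls)
    return seqs, labels


def make_feature_clusters(spec: FixtureSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian clusters in 70-d feature space at the requested separation.

    Each class has an isotropic unit-SD Gaussian around a center; centers are
    simplex vertices with every inter-center distance equal to ``separation``,
    so separation counts within-class SDs. The simplex is embedded under a
    seeded random rotation so the class signal is spread over all feature
    axes rather than aligned with a few — as in real feature tables, where
    no single column carries a class by itself. separation = 0 collapses all
    centers to the origin.
    """
    rng = np.random.default_rng(spec.seed)
    K = len(spec.classes)
    d = len(FEATURE_NAMES)
    # K mutually equidistant vertices in a K-dim subspace, then rotate
    basis = np.eye(K, d)
    basis -= basis.mean(axis=0)
    basis /= np.linalg.norm(basis[0] - basis[1])
    rotation, _ = np.linalg.qr(rng.normal(size=(d, d)))
    centers = spec.separation * basis @ rotation.T
    rows, labels = [], []
    for k, cls in enumerate(spec.classes):
        X = rng.normal(loc=centers[k], scale=1.0, size=(spec.n_per_class, d))
        rows.append(X)
        labels.extend([cls] * spec.n_per_class)
    df = pd.DataFrame(np.vstack(rows), columns=list(FEATURE_NAMES))
    df.index = [f"{c}_{i}" for c in spec.classes for i in range(spec.n_per_class)]
    df.index.name = "id"
    return df, np.asarray(labels)
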