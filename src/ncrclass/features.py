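"""The 70-dimensional feature vector: sequence, folding and 3-mer measures.

Per sequence: length L, AU%, MFEI, ND, Npb, NQ, then the 64 overlapping
3-mer rates per 100 nt in lexicographic order over A < C < G < U. The scalar
folding measures:

* AMFE = MFE * 100 / L            (adjusted MFE, kcal/mol per 100 nt)
* MFEI = |AMFE| / GC%             (0 by convention when GC% = 0)
* Npb  = base pairs in the MFE structure / L      (in [0, 0.5])
* NQ   = -(1/L) sum_{i<j} p_ij log2 p_ij          (BPPD Shannon entropy/base)
* ND   =  (1/L) sum_{i<j} p_ij (1 - p_ij)         (expected pair distance/base)

with p_ij the McCaskill base-pair probabilities and 0*log 0 := 0. NQ is 0
when the ensemble is dominated by a single structure (all p_ij in {0,1}) and
grows when alternative conformations coexist; ND is 0 under the same
degeneracy condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .folding import FoldBackend, FoldResult, ThermoBackend, count_base_pairs
from .seq_io import RnaSequence

log = logging.getLogger(__name__)

#: the 64 triplets, lexicographic over A < C < G < U
KMERS: tuple[str, ...] = tuple("".join(t) for t in product("ACGU", repeat=3))

SCALAR_FEATURES: tuple[str, ...] = ("length", "au_percent", "mfei", "nd", "npb", "nq")

#: frozen feature order; the classifier fingerprints this
FEATURE_NAMES: tuple[str, ...] = SCALAR_FEATURES + KMERS

N_FEATURES = len(FEATURE_NAMES)  # 70


@dataclass(frozen=True)
class FeatureVector:
    length: int
    au_percent: float
    mfei: float
    nd: float
    npb: float
    nq: float
    kmer_rates: tuple[float, ...]  # 64 rates, KMERS order

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.length, self.au_percent, self.mfei, self.nd, self.npb, self.nq]
            + list(self.kmer_rates),
            dtype=float,
        )


def au_content(seq: RnaSequence) -> float:
    """Percentage of A+U residues, in [0, 100]."""
    r = seq.residues
    return 100.0 * (r.count("A") + r.count("U")) / len(r)


def gc_content(seq: RnaSequence) -> float:
    return 100.0 - au_content(seq)


def amfe(mfe: float, length: int) -> float:
    """Adjusted MFE: the MFE rescaled to a 100-nt sequence."""
    return mfe * 100.0 / length


def mfei(mfe: float, length: int, gc_percent: float) -> float:
    """Minimum folding energy index, |AMFE| / GC%, reported non-negative.

    GC% on the 0-100 scale gives the canonical magnitude (~0.85 for typical
    pre-miRNA hairpins). GC% = 0 means no GC normalisation is possible and no
    stable GC-driven fold either; 0 is returned by convention with a warning.
    """
    if gc_percent == 0.0:
        if mfe != 0.0:
            log.warning("MFEI undefined for GC=0 (mfe=%g); returning 0", mfe)
        return 0.0
    return abs(amfe(mfe, length)) / gc_percent


def npb(fold: FoldResult, length: int) -> float:
    """Base-pairing propensity: pairs in the MFE structure per nucleotide."""
    return count_base_pairs(fold.structure) / length


def _upper_probs(fold: FoldResult) -> np.ndarray:
    if fold.bppm is None:
        raise ValueError("FoldResult has no base-pair probability matrix")
    iu = np.triu_indices(fold.bppm.shape[0], k=1)
    return fold.bppm[iu]


def nq(fold: FoldResult, length: int) -> float:
    """Normalised Shannon entropy of the BPPD, bits per base."""
    p = _upper_probs(fold)
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-np.sum(p * np.log2(p)) / length)


def nd(fold: FoldResult, length: int) -> float:
    """Normalised expected base-pair distance, sum p(1-p) per base."""
    p = _upper_probs(fold)
    return float(np.sum(p * (1.0 - p)) / length)


def kmer_profile(seq: RnaSequence) -> tuple[float, ...]:
    """Overlapping 3-mer rates per 100 nt, in KMERS order.

    R_k = 100 * count_k / L. A sequence shorter than 3 nt has no windows and
    rates of all zero. Note the L (not L-2) denominator, hence
    sum_k R_k = 100 (L-2)/L.
    """
    r = seq.residues
    L = len(r)
    if L < 3:
        return (0.0,) * 64
    counts = dict.fromkeys(KMERS, 0)
    for i in range(L - 2):
        counts[r[i : i + 3]] += 1
    return tuple(100.0 * counts[k] / L for k in KMERS)


def extract_features(
    seq: RnaSequence, backend: FoldBackend | None = None
) -> FeatureVector:
    """Fold one sequence and assemble its 70-feature vector."""
    backend = backend or ThermoBackend()
    try:
        fold = backend.fold(seq)
    except Exception as exc:
        raise RuntimeError(f"folding failed for sequence {seq.id!r}: {exc}") from exc
    L = seq.length
    gc = gc_content(seq)
    return FeatureVector(
        length=L,
        au_percent=au_content(seq),
        mfei=mfei(fold.mfe, L, gc),
        nd=nd(fold, L),
        npb=npb(fold, L),
        nq=nq(fold, L),
        kmer_rates=kmer_profile(seq),
    )


def feature_table(
    seqs: Iterable[RnaSequence], backend: FoldBackend | None = None
) -> pd.DataFrame:
    """Feature vectors for many sequences as a DataFrame indexed by id."""
    backend = backend or ThermoBackend()
    rows = {}
    for seq in seqs:
        rows[seq.id] = extract_features(seq, backend).to_array()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    df.index.name = "id"
    return df


def validate_feature_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a feature table has the frozen column order and finite values."""
    if list(df.columns) != list(FEATURE_NAMES):
        raise ValueError(
            "feature table columns do not match the frozen 70-feature order"
        )
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("feature table contains non-finite values")
    return df


def feature_fingerprint(names: Sequence[str] = FEATURE_NAMES) -> str:
    """Stable fingerprint of the feature order, embedded in model files."""
    import hashlib

    return hashlib.sha256("|".join(names).encode()).hexdigest()[:16]
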