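"""RNA secondary-structure prediction: MFE structures and base-pair probabilities.

Two interchangeable backends:

* ``ThermoBackend`` — an adapter to the ViennaRNA thermodynamic engine
  (nearest-neighbour parameters). This is the production path: it produces
  the MFE structures and McCaskill base-pair probability matrices that feed
  the folding measures.

* ``ReferenceBackend`` — a self-contained model with additive per-pair
  energies (GC/AU/GU) and no stacking terms. Its Nussinov-style energy
  minimisation and McCaskill-style partition-function dynamic programs are
  exact over the space of nested structures with a minimum hairpin loop, so
  they can be verified against exhaustive structure enumeration on small
  sequences. It exists to make the folding mathematics testable in closed
  form, independently of any external engine.

Structures are linear (non-pseudoknotted) dot-bracket strings. A pair (i, j)
is admissible iff the bases are complementary (Watson-Crick or GU wobble)
and j - i > min_loop, i.e. at least ``min_loop`` unpaired bases could sit in
a hairpin closed by it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Protocol

import numpy as np

from .seq_io import RnaSequence

log = logging.getLogger(__name__)

#: canonical pairs, including GU wobble
COMPLEMENTS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: default guard above which thermodynamic folding is attempted but warned
LONG_SEQUENCE_WARN = 5000

#: cap for exhaustive enumeration (structure count explodes beyond this)
ENUMERATION_MAX_LENGTH = 20


class BackendUnavailableError(RuntimeError):
    """A folding backend's underlying engine cannot be imported/used."""


class StructureError(ValueError):
    """Malformed dot-bracket string."""


@dataclass
class FoldResult:
    """Outcome of folding one sequence.

    structure : dot-bracket MFE structure (length L)
    mfe       : minimum free energy, kcal/mol (<= 0)
    bppm      : L x L symmetric matrix of equilibrium pair probabilities p_ij
    partition_value : Boltzmann sum Z over all admissible structures
                      (reference backend only; >= 1 because the open chain
                      always contributes weight 1)
    """

    structure: str
    mfe: float
    bppm: np.ndarray | None = None
    partition_value: float | None = None


@dataclass(frozen=True)
class EnergyModel:
    """Additive per-pair energy rules for the reference backend.

    Defaults (e_gc=-3, e_au=-2, e_gu=-1 kcal/mol, kT=0.6) are a documented
    toy parameterisation ordering pair stabilities the standard way while
    keeping Boltzmann factors hand-computable.
    """

    e_gc: float = -3.0
    e_au: float = -2.0
    e_gu: float = -1.0
    kT: float = 0.6
    min_loop: int = 3

    def __post_init__(self) -> None:
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")
        if max(self.e_gc, self.e_au, self.e_gu) > 0:
            raise ValueError("pair energies must be <= 0")

    def pair_energy(self, a: str, b: str) -> float | None:
        """Energy of pairing bases a,b; None if not complementary."""
        if (a, b) not in COMPLEMENTS:
            return None
        pair = frozenset((a, b))
        if pair == frozenset("GC"):
            return self.e_gc
        if pair == frozenset("AU"):
            return self.e_au
        return self.e_gu


def count_base_pairs(structure: str) -> int:
    """Number of base pairs in a balanced dot-bracket string."""
    depth = 0
    n_open = 0
    for c in structure:
        if c == "(":
            depth += 1
            n_open += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise StructureError(f"unbalanced dot-bracket: {structure!r}")
        elif c != ".":
            raise StructureError(f"invalid character {c!r} in {structure!r}")
    if depth != 0:
        raise StructureError(f"unbalanced dot-bracket: {structure!r}")
    return n_open


def _valid_pair_matrix(residues: str, model: EnergyModel) -> list[list[float | None]]:
    n = len(residues)
    e = [[None] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + model.min_loop + 1, n):
            e[i][j] = model.pair_energy(residues[i], residues[j])
    return e


class FoldBackend(Protocol):
    def fold(self, seq: RnaSequence) -> FoldResult: ...


@dataclass
class ReferenceBackend:
    """Exact dynamic programs over nested structures under an EnergyModel."""

    model: EnergyModel = field(default_factory=EnergyModel)

    # -- minimum free energy -------------------------------------------------

    def fold(self, seq: RnaSequence) -> FoldResult:
        res = self.fold_mfe(seq)
        bp = self.mccaskill(seq)
        res.bppm = bp.bppm
        res.partition_value = bp.partition_value
        return res

    def fold_mfe(self, seq: RnaSequence) -> FoldResult:
        """Minimum-energy structure; lexicographically smallest on ties.

        Energy DP:  E(i,j) = min( E(i+1,j),
                                  min_k e(i,k) + E(i+1,k-1) + E(k+1,j) ).
        The traceback picks, among co-optimal choices, the dot-bracket string
        that is lexicographically smallest ('(' < '.' in ASCII), which makes
        the output deterministic.
        """
        r = seq.residues
        n = len(r)
        pe = _valid_pair_matrix(r, self.model)

        @lru_cache(maxsize=None)
        def energy(i: int, j: int) -> float:
            if j - i < self.model.min_loop + 1:
                return 0.0
            best = energy(i + 1, j)
            for k in range(i + self.model.min_loop + 1, j + 1):
                e = pe[i][k]
                if e is not None:
                    best = min(best, e + energy(i + 1, k - 1) + energy(k + 1, j))
            return best

        @lru_cache(maxsize=None)
        def structure(i: int, j: int) -> str:
            if i > j:
                return ""
            if j - i < self.model.min_loop + 1:
                return "." * (j - i + 1)
            target = energy(i, j)
            candidates = []
            for k in range(i + self.model.min_loop + 1, j + 1):
                e = pe[i][k]
                if e is not None and math.isclose(
                    e + energy(i + 1, k - 1) + energy(k + 1, j), target
                ):
                    candidates.append(
                        "(" + structure(i + 1, k - 1) + ")" + structure(k + 1, j)
                    )
            if math.isclose(energy(i + 1, j), target):
                candidates.append("." + structure(i + 1, j))
            return min(candidates)

        mfe = energy(0, n - 1) if n > 1 else 0.0
        ss = structure(0, n - 1) if n > 1 else "." * n
        energy.cache_clear()
        return FoldResult(structure=ss, mfe=mfe)

    # -- partition function / base-pair probabilities ------------------------

    def mccaskill(self, seq: RnaSequence) -> FoldResult:
        """Inside-outside partition-function DP for p_ij.

        Inside:  Z(i,j) = Z(i+1,j) + sum_k q(i,k) Z(i+1,k-1) Z(k+1,j)
        with q(i,k) = exp(-e(i,k)/kT); empty intervals have Z = 1, so the
        open chain contributes weight 1 and Z >= 1.

        Outside: Zout(i,j) = Z(1,i-1) Z(j+1,L)
                   + sum_{k<i, l>j} q(k,l) Zout(k,l) Z(k+1,i-1) Z(j+1,l-1)

        p_ij = q(i,j) Z(i+1,j-1) Zout(i,j) / Z.
        """
        r = seq.residues
        n = len(r)
        kT = self.model.kT
        pe = _valid_pair_matrix(r, self.model)
        q = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if pe[i][j] is not None:
                    q[i, j] = math.exp(-pe[i][j] / kT)

        # inside: Zin[i][j] over closed interval i..j; empty -> 1
        Zin = np.ones((n + 1, n + 1))  # Zin[i, j+1] layout to allow empties

        def zin(i: int, j: int) -> float:  # closed interval, 1.0 if empty
            return Zin[i, j + 1] if j >= i else 1.0

        for span in range(1, n + 1):
            for i in range(0, n - span + 1):
                j = i + span - 1
                total = zin(i + 1, j)
                for k in range(i + self.model.min_loop + 1, j + 1):
                    if q[i, k] > 0:
                        total += q[i, k] * zin(i + 1, k - 1) * zin(k + 1, j)
                Zin[i, j + 1] = total

        Z = zin(0, n - 1)

        # outside, longest spans first
        Zout = np.zeros((n, n))
        pairs = [
            (i, j) for i in range(n) for j in range(i + 1, n) if q[i, j] > 0
        ]
        pairs.sort(key=lambda ij: ij[0] - ij[1])  # decreasing span
        for i, j in pairs:
            total = zin(0, i - 1) * zin(j + 1, n - 1)
            for k in range(0, i):
                for l in range(j + 1, n):
                    if q[k, l] > 0:
                        total += (
                            q[k, l] * Zout[k, l] * zin(k + 1, i - 1) * zin(j + 1, l - 1)
                        )
            Zout[i, j] = total

        bppm = np.zeros((n, n))
        for i, j in pairs:
            p = q[i, j] * zin(i + 1, j - 1) * Zout[i, j] / Z
            bppm[i, j] = bppm[j, i] = p
        return FoldResult(structure="", mfe=0.0, bppm=bppm, partition_value=Z)


@dataclass
class ThermoBackend:
    """Adapter to the ViennaRNA engine (RNAfold's MFE + partition function)."""

    long_sequence_warn: int = LONG_SEQUENCE_WARN

    def fold(self, seq: RnaSequence) -> FoldResult:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - environment guard
            raise BackendUnavailableError(
                "the 'thermo' backend needs the ViennaRNA python bindings "
                "(import RNA); install ViennaRNA or use --fold-backend reference"
            ) from exc
        if seq.length > self.long_sequence_warn:
            log.warning(
                "%s: length %d exceeds %d nt; folding cost grows cubically",
                seq.id,
                seq.length,
                self.long_sequence_warn,
            )
        fc = RNA.fold_compound(seq.residues)
        structure, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        fc.pf()
        n = seq.length
        bppm = np.zeros((n, n))
        raw = fc.bpp()  # (n+1)x(n+1), 1-indexed upper triangle
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                p = raw[i][j]
                if p > 0:
                    bppm[i - 1, j - 1] = bppm[j - 1, i - 1] = p
        return FoldResult(structure=structure, mfe=float(mfe), bppm=bppm)


def get_backend(name: str, model: EnergyModel | None = None) -> FoldBackend:
    """Resolve a backend by name: 'thermo' (ViennaRNA) or 'reference'."""
    if name == "thermo":
        return ThermoBackend()
    if name == "reference":
        return ReferenceBackend(model or EnergyModel())
    raise BackendUnavailableError(f"unknown fold backend {name!r}")


# -- exhaustive enumeration oracle -------------------------------------------


def enumerate_structures(
    seq: RnaSequence, model: EnergyModel | None = None
) -> list[tuple[str, float]]:
    """Every nested, admissible structure of a short sequence, with its energy.

    Exhaustive recursion over the leftmost position: either unpaired, or
    paired with each admissible partner. Includes the open chain. Guarded to
    L <= 20; meant as an independent test oracle for the dynamic programs.
    """
    model = model or EnergyModel()
    n = seq.length
    if n > ENUMERATION_MAX_LENGTH:
        raise ValueError(
            f"enumeration is limited to L <= {ENUMERATION_MAX_LENGTH} (got {n})"
        )
    r = seq.residues
    pe = _valid_pair_matrix(r, model)

    def rec(i: int, j: int) -> Iterator[tuple[str, float]]:
        if i > j:
            yield "", 0.0
            return
        for s, e in rec(i + 1, j):
            yield "." + s, e
        for k in range(i + model.min_loop + 1, j + 1):
            ek = pe[i][k]
            if ek is None:
                continue
            for s_in, e_in in rec(i + 1, k - 1):
                for s_out, e_out in rec(k + 1, j):
                    yield "(" + s_in + ")" + s_out, ek + e_in + e_out

    return list(rec(0, n - 1))


def brute_force_ensemble(
    seq: RnaSequence, model: EnergyModel | None = None
) -> tuple[float, np.ndarray, float]:
    """Boltzmann sum, pair probabilities and MFE by full enumeration.

    Returns (Z, bppm, mfe) computed structure-by-structure; the independent
    oracle the dynamic programs are checked against.
    """
    model = model or EnergyModel()
    n = seq.length
    Z = 0.0
    weighted = np.zeros((n, n))
    mfe = 0.0
    for s, e in enumerate_structures(seq, model):
        w = math.exp(-e / model.kT)
        Z += w
        mfe = min(mfe, e)
        stack: list[int] = []
        for pos, c in enumerate(s):
            if c == "(":
                stack.append(pos)
            elif c == ")":
                i = stack.pop()
                weighted[i, pos] += w
                weighted[pos, i] += w
    return Z, weighted / Z, mfe
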