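"""Reading, validation, normalisation and deduplication of RNA sequences.

Public ncRNA collections mix DNA- and RNA-alphabet records, wrap sequence
bodies over several lines, and repeat identical sequences under different
accessions. This module applies the curation rules used throughout the
package: uppercase, T->U, reject any record containing letters outside
{A, C, G, U} (degenerate/ambiguous IUPAC codes such as N, R, Y), and collapse
exact duplicate residue strings to their first occurrence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

log = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

_NORMALIZE = str.maketrans("acgutT", "ACGUUU")


class FastaParseError(ValueError):
    """Raised for a structurally malformed FASTA file."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence: identifier plus residues over {A,C,G,U}."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id!r}: empty sequence")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.id!r}: invalid residues {sorted(bad)}; "
                "normalize first (see normalize_sequence)"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class CurationReport:
    """Bookkeeping for a curation pass; counts always reconcile."""

    n_read: int = 0
    n_rejected_degenerate: int = 0
    n_duplicates_removed: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_read - self.n_rejected_degenerate - self.n_duplicates_removed

    def to_tsv(self) -> str:
        rows = [
            ("n_read", self.n_read),
            ("n_rejected_degenerate", self.n_rejected_degenerate),
            ("n_duplicates_removed", self.n_duplicates_removed),
            ("n_kept", self.n_kept),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse a FASTA file into raw ``(id, residues, description)`` records.

    Multi-line bodies are concatenated; record order is preserved. The id is
    the first whitespace-delimited token of the header, the remainder is kept
    as the description. No alphabet validation happens here.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[tuple[str, str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(_finish(header, chunks))
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunks.append(line.strip())
    if header is not None:
        records.append(_finish(header, chunks))
    if not records:
        log.warning("%s: empty FASTA file", path)
    return records


def _finish(header: str, chunks: list[str]) -> tuple[str, str, str]:
    parts = header.split(None, 1)
    seq_id = parts[0] if parts else ""
    desc = parts[1] if len(parts) > 1 else ""
    return seq_id, "".join(chunks), desc


def normalize_sequence(raw: str) -> str | None:
    """Normalise a raw residue string; return None if it must be rejected.

    Lowercase is mapped to uppercase and T to U. Any remaining letter outside
    {A,C,G,U} (e.g. N or other IUPAC ambiguity codes) rejects the whole
    sequence rather than masking it, since masking would distort k-mer counts.
    """
    norm = raw.translate(_NORMALIZE)
    if not norm or set(norm) - RNA_ALPHABET:
        return None
    return norm


def curate(
    records: Iterable[tuple[str, str] | tuple[str, str, str]],
    deduplicate_sequences: bool = True,
) -> tuple[list[RnaSequence], CurationReport]:
    """Normalise, validate and (optionally) deduplicate raw records.

    Duplicates are detected on the residue string only: identical sequences
    under different accessions count as one. Survivor order follows first
    occurrence.
    """
    report = CurationReport()
    seen: set[str] = set()
    kept: list[RnaSequence] = []
    for rec in records:
        seq_id, raw = rec[0], rec[1]
        desc = rec[2] if len(rec) > 2 else ""
        report.n_read += 1
        norm = normalize_sequence(raw)
        if norm is None:
            report.n_rejected_degenerate += 1
            log.debug("rejected %s: degenerate/ambiguous letters", seq_id)
            continue
        if deduplicate_sequences:
            if norm in seen:
                report.n_duplicates_removed += 1
                continue
            seen.add(norm)
        kept.append(RnaSequence(seq_id, norm, desc))
    return kept, report


def deduplicate(
    seqs: Sequence[RnaSequence],
) -> tuple[list[RnaSequence], CurationReport]:
    """Collapse exact residue-string duplicates to their first occurrence."""
    report = CurationReport(n_read=len(seqs))
    seen: set[str] = set()
    out: list[RnaSequence] = []
    for s in seqs:
        if s.residues in seen:
            report.n_duplicates_removed += 1
        else:
            seen.add(s.residues)
            out.append(s)
    return out, report


def write_fasta(seqs: Iterable[RnaSequence], handle: TextIO, width: int = 60) -> None:
    """Write sequences as FASTA with bodies wrapped at ``width`` columns."""
    for s in seqs:
        header = f">{s.id} {s.description}".rstrip()
        handle.write(header + "\n")
        for i in range(0, len(s.residues), width):
            handle.write(s.residues[i : i + width] + "\n")


def read_curated_fasta(
    path: str | Path, deduplicate_sequences: bool = True
) -> tuple[list[RnaSequence], CurationReport]:
    """read_fasta + curate in one step."""
    return curate(read_fasta(path), deduplicate_sequences=deduplicate_sequences)


def iter_labels(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (sequence id, class label) pairs from a two-column TSV."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            yield parts[0], parts[1]
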