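"""FASTA input/output and nucleotide-sequence normalization.

All sequences entering the pipeline pass through this module: residues are
upper-cased, RNA ``U`` is converted to DNA ``T`` (all matching downstream is
done in the DNA alphabet, as in a nucleotide BLAST workflow), and any symbol
outside ``{A, C, G, T, N}`` is rejected at parse time rather than surfacing
later as a silent mismatch.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "NucleotideSequence",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
]

#: Residue alphabet after normalization.
ALPHABET = frozenset("ACGTN")

#: Characters accepted on ingest (case-folded); U is rewritten to T.
_INGEST_ALPHABET = frozenset("ACGTUN")

FASTA_LINE_WIDTH = 80


class FastaParseError(ValueError):
    """Raised when a FASTA file or sequence string violates the format rules."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide sequence over the alphabet ``{A, C, G, T, N}``.

    Parameters
    ----------
    identifier : str
        The FASTA identifier (first whitespace-delimited token of the header).
    residues : str
        Normalized residue string: non-empty, uppercase, ``U`` already mapped
        to ``T``.
    description : str
        The remainder of the FASTA header after the identifier (may be empty).
    """

    identifier: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.identifier:
            raise FastaParseError("sequence identifier must be non-empty")
        if not self.residues:
            raise FastaParseError(
                f"record '{self.identifier}': empty sequence"
            )
        bad = set(self.residues) - ALPHABET
        if bad:
            offender = sorted(bad)[0]
            pos = self.residues.index(offender) + 1
            raise FastaParseError(
                f"record '{self.identifier}': illegal character "
                f"'{offender}' at residue {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str, identifier: str = "<anonymous>") -> str:
    """Upper-case, convert U to T, and validate a raw residue string."""
    folded = raw.upper()
    bad = set(folded) - _INGEST_ALPHABET
    if bad:
        offender = sorted(bad)[0]
        pos = folded.index(offender) + 1
        raise FastaParseError(
            f"record '{identifier}': illegal character '{offender}' "
            f"at residue {pos}"
        )
    return folded.replace("U", "T")


def read_fasta(path: Union[str, Path, io.TextIOBase]) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file into :class:`NucleotideSequence` records.

    Record order is preserved. Residues are normalized (case-folded, U→T) and
    validated; duplicate identifiers, empty sequences and illegal characters
    raise :class:`FastaParseError` naming the offending record.
    """
    if isinstance(path, io.TextIOBase):
        handle = path
        close = False
    else:
        handle = open(path, "r", encoding="utf-8")
        close = True
    records: list[NucleotideSequence] = []
    seen: set[str] = set()
    try:
        for index, (header, seq) in enumerate(SimpleFastaParser(handle), start=1):
            header = header.strip()
            if not header:
                raise FastaParseError(f"record {index}: empty FASTA header")
            parts = header.split(None, 1)
            identifier = parts[0]
            description = parts[1] if len(parts) > 1 else ""
            if identifier in seen:
                raise FastaParseError(
                    f"record {index}: duplicate identifier '{identifier}'"
                )
            seen.add(identifier)
            if not seq:
                raise FastaParseError(
                    f"record '{identifier}': empty sequence"
                )
            residues = normalize_residues(seq, identifier)
            records.append(
                NucleotideSequence(identifier=identifier, residues=residues,
                                   description=description)
            )
    finally:
        if close:
            handle.close()
    if not records:
        raise FastaParseError("no FASTA records found")
    return records


def write_fasta(records: Iterable[NucleotideSequence],
                path: Union[str, Path]) -> None:
    """Write records as FASTA, sequence lines wrapped at 80 columns.

    Output is byte-stable for identical inputs (UTF-8, LF line endings).
    """
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        for rec in records:
            header = rec.identifier
            if rec.description:
                header += " " + rec.description
            out.write(f">{header}\n")
            for i in range(0, len(rec.residues), FASTA_LINE_WIDTH):
                out.write(rec.residues[i:i + FASTA_LINE_WIDTH] + "\n")


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement over ``{A, C, G, T, N}``.

    N maps to N; length is preserved; the operation is an involution.
    """
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(
            f"illegal character {sorted(bad)[0]!r} in sequence; "
            "expected alphabet {A, C, G, T, N}"
        )
    return str(Seq(seq).reverse_complement())
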