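"""In-silico Dicer processing: sliding-window k-mer fragmentation of a dsRNA.

Dicer enzymes cleave long dsRNA into ~21-nt siRNAs with largely stochastic
cleavage positions, so the conservative in-silico emulation enumerates *every*
k-mer window of the construct at 1-nt steps. Dicing is performed on the sense
strand only; because a dsRNA duplex releases siRNAs from both strands,
:func:`enumerate_orientations` adds the reverse-complement (antisense)
fragment for each window — mathematically equivalent to dicing both strands
without double bookkeeping.

Positions *within* a fragment are "guide coordinates": 1..k counted from the
fragment's 5' end. These are the single coordinate system used for mismatch
positions and the seed region (nt 2-8) everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .io_formats import NucleotideSequence, normalize_residues, reverse_complement

__all__ = [
    "DsRNAConstruct",
    "SirnaFragment",
    "dice",
    "enumerate_orientations",
    "fragments_to_fasta_records",
]

DEFAULT_K = 21
MIN_K = 8  # a fragment must at least contain the seed region (nt 2-8)

Orientation = Literal["sense", "antisense"]


@dataclass(frozen=True)
class DsRNAConstruct:
    """The dsRNA construct to be diced, represented by its sense strand."""

    identifier: str
    sense: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sense", normalize_residues(self.sense, self.identifier)
        )

    def __len__(self) -> int:
        return len(self.sense)


@dataclass(frozen=True)
class SirnaFragment:
    """One k-mer window of a construct, with provenance.

    ``start`` is the 1-based position of the window on the construct's sense
    strand (inclusive); ``residues`` equals the parent window for sense
    orientation, or its reverse complement for antisense. ``fragment_index``
    is the serial number in generation order.
    """

    parent_id: str
    start: int
    k: int
    residues: str
    orientation: Orientation
    fragment_index: int

    @property
    def fragment_id(self) -> str:
        return f"{self.parent_id}|start={self.start}|ori={self.orientation}"


def dice(construct: DsRNAConstruct, k: int = DEFAULT_K,
         dedupe: bool = True) -> list[SirnaFragment]:
    """Fragment the construct into all k-mer windows at 1-nt steps.

    With ``dedupe`` (the default), windows with identical residue strings are
    collapsed to their first occurrence, matching the "all unique k-mers"
    reading: a 398-nt construct whose 21-mers are all distinct yields exactly
    378 fragments. Generation order is ascending start position.
    """
    if k < MIN_K:
        raise ValueError(
            f"fragment length k={k} is below the minimum {MIN_K} "
            "(a fragment must contain the seed region, nt 2-8)"
        )
    L = len(construct)
    if L < k:
        raise ValueError(
            f"construct shorter than fragment length (L={L} < k={k})"
        )
    fragments: list[SirnaFragment] = []
    seen: set[str] = set()
    index = 0
    for start in range(1, L - k + 2):
        window = construct.sense[start - 1:start - 1 + k]
        if dedupe:
            if window in seen:
                continue
            seen.add(window)
        fragments.append(
            SirnaFragment(parent_id=construct.identifier, start=start, k=k,
                          residues=window, orientation="sense",
                          fragment_index=index)
        )
        index += 1
    return fragments


def enumerate_orientations(fragments: Iterable[SirnaFragment],
                           policy: Literal["sense_only", "both"] = "both",
                           dedupe: bool = True) -> list[SirnaFragment]:
    """Expand sense fragments to the requested strand coverage.

    ``policy="both"`` appends, for each sense fragment, an antisense fragment
    whose residues are the reverse complement of the same parent window; with
    ``dedupe`` a fragment that is self-reverse-complementary (possible only
    for even k) is not duplicated. ``policy="sense_only"`` returns the input
    unchanged.
    """
    fragments = list(fragments)
    if policy == "sense_only":
        return fragments
    if policy != "both":
        raise ValueError(f"unknown orientation policy {policy!r}")
    out = list(fragments)
    seen = {f.residues for f in fragments} if dedupe else set()
    index = max((f.fragment_index for f in fragments), default=-1) + 1
    for frag in fragments:
        rc = reverse_complement(frag.residues)
        if dedupe:
            if rc in seen:
                continue
            seen.add(rc)
        out.append(
            SirnaFragment(parent_id=frag.parent_id, start=frag.start,
                          k=frag.k, residues=rc, orientation="antisense",
                          fragment_index=index)
        )
        index += 1
    return out


def fragments_to_fasta_records(
        fragments: Iterable[SirnaFragment]) -> list[NucleotideSequence]:
    """Render fragments as FASTA records with provenance-encoding headers."""
    return [
        NucleotideSequence(identifier=f.fragment_id, residues=f.residues)
        for f in fragments
    ]
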