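"""Synthetic transcript databases with planted off-target sites.

Real non-target transcript databases are large, network-hosted and moving
targets; to exercise the whole screen with exact ground truth, this module
generates multi-record transcript databases in which off-target sites with
controlled identity/mismatch/seed structure are planted at recorded
positions, embedded in random background that is actively scrubbed of
accidental matches.

Two properties make the ground truth an *independent* oracle:

* expected retention flags on each planted site are computed from the
  pattern's mismatch positions by a brute-force rule evaluation local to
  this module (exhaustive window enumeration, thresholds restated here) —
  never by running the search/filter pipeline; and
* background safety is constructive, not probabilistic: at a 15/21 identity
  floor, chance matches between random sequence and ~750 fragment strands
  are common, so every transcript is iteratively repaired (offending windows
  re-drawn, planted bases frozen) until no window outside a planted
  footprint reaches the scan threshold on either strand.

Because fragments of one construct overlap each other, planting one 21-mer
locus necessarily also creates shifted high-identity placements for
neighbouring fragments and a reverse-orientation placement for the antisense
twin. Recovery is therefore scored on the exact (source fragment, position,
strand) placement, and a retained hit only counts as a false positive when
its placement does not overlap any planted footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .fragmentation import DsRNAConstruct, SirnaFragment, dice, enumerate_orientations
from .homology_search import TranscriptDb, encode, search_db
from .io_formats import NucleotideSequence, reverse_complement
from .offtarget_filter import FilterConfig, FilterDecision, apply_funnel

__all__ = [
    "PlantSpec",
    "TruthRecord",
    "RecoveryResult",
    "PATTERNS",
    "random_construct",
    "build_synthetic_db",
    "write_truth_tsv",
    "recovery_test",
    "expected_retention",
]

_BASES = "ACGT"
_N_CODE = 4

#: Seed region and stretch budget assumed by the truth oracle (the fixed
#: study conditions; the pipeline must be run with matching settings for the
#: truth flags to be meaningful).
_SEED_START, _SEED_END = 2, 8
_STRETCH_MM = 2

#: Filter thresholds restated locally so the truth oracle shares no code
#: with the filter implementation: preset -> (min identities, min stretch).
_ORACLE_PRESETS = {"text": (16, 18), "figure6": (15, 19), "chen": (16, 26)}
_COMBINE_MODES = ("or_then_seed", "and_chain")

#: Planting patterns: pattern name -> rule drawing guide-coordinate
#: substitution positions (documented in each drawing function).
PATTERNS = ("perfect", "one_mm_seed", "one_mm_nonseed", "two_mm_nonseed",
            "identity16", "near18_2mm", "decoy_identity14")


@dataclass(frozen=True)
class PlantSpec:
    """Request for ``count`` planted sites built by one pattern rule."""

    pattern: str
    count: int
    strand: Literal["forward", "reverse", "random"] = "random"

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; "
                             f"expected one of {PATTERNS}")
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted site.

    ``expected`` maps ``"<preset>:<combine_mode>"`` to the retention flag the
    funnel should produce for the exact source-fragment placement, computed
    by the local brute-force oracle from ``mismatch_positions`` alone.
    """

    transcript_id: str
    t_start: int
    t_end: int
    strand: Literal["forward", "reverse"]
    source_fragment_id: str
    source_residues: str
    planted_residues: str
    pattern: str
    mismatch_positions: tuple[int, ...]
    expected: dict[str, bool] = field(hash=False)


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of screening a synthetic database against its truth table."""

    sensitivity: Optional[float]  # None when no site is expected retained
    false_positives: int
    n_expected: int
    n_recovered: int
    n_retained: int
    unexpected_exact: int  # exact placements retained despite expected=False


def _brute_best_near_perfect(positions: Sequence[int], k: int, m: int) -> int:
    """Longest window with <= m mismatches, by exhaustive enumeration."""
    mm = set(positions)
    best = 0
    for a in range(1, k + 1):
        for b in range(a, k + 1):
            if sum(1 for p in mm if a <= p <= b) <= m:
                best = max(best, b - a + 1)
    return best


def expected_retention(mismatch_positions: Sequence[int], k: int = 21
                       ) -> dict[str, bool]:
    """Truth-side funnel evaluation for every preset and combine mode.

    Deliberately naive and self-contained: identities counted directly,
    the near-perfect stretch found by exhaustive window enumeration, the
    seed checked against the fixed nt 2-8 interval.
    """
    identities = k - len(mismatch_positions)
    seed_ok = not any(_SEED_START <= p <= _SEED_END
                      for p in mismatch_positions)
    best_near = _brute_best_near_perfect(mismatch_positions, k, _STRETCH_MM)
    out: dict[str, bool] = {}
    for preset, (c1_thr, c2_len) in _ORACLE_PRESETS.items():
        c1 = identities >= c1_thr
        c2 = best_near >= c2_len
        out[f"{preset}:or_then_seed"] = (c1 or c2) and seed_ok
        out[f"{preset}:and_chain"] = c1 and c2 and seed_ok
    return out


def _draw_pattern_positions(pattern: str, k: int,
                            rng: np.random.Generator) -> tuple[int, ...]:
    """Draw guide-coordinate substitution positions for one pattern.

    perfect: none. one_mm_seed: one position uniform on the seed [2, 8].
    one_mm_nonseed / two_mm_nonseed: one / two positions outside the seed
    (position 1 included: it lies outside the 2-8 seed). identity16: exactly
    five positions from [9, k] (16/21 identities, seed intact).
    near18_2mm: three positions from [9, k], redrawn until a stretch of
    >= 18 nt with <= 2 mismatches exists. decoy_identity14: seven positions
    anywhere (14/21 identities — below every preset's thresholds).
    """
    seed = list(range(_SEED_START, _SEED_END + 1))
    nonseed = [p for p in range(1, k + 1) if p not in seed]
    tail = list(range(_SEED_END + 1, k + 1))
    if pattern == "perfect":
        return ()
    if pattern == "one_mm_seed":
        return (int(rng.choice(seed)),)
    if pattern == "one_mm_nonseed":
        return (int(rng.choice(nonseed)),)
    if pattern == "two_mm_nonseed":
        return tuple(sorted(int(p) for p in
                            rng.choice(nonseed, size=2, replace=False)))
    if pattern == "identity16":
        return tuple(sorted(int(p) for p in
                            rng.choice(tail, size=5, replace=False)))
    if pattern == "near18_2mm":
        for _ in range(1000):
            pos = tuple(sorted(int(p) for p in
                               rng.choice(tail, size=3, replace=False)))
            if _brute_best_near_perfect(pos, k, _STRETCH_MM) >= 18:
                return pos
        raise RuntimeError("could not satisfy near18_2mm at k="
                           f"{k} within the retry budget")
    if pattern == "decoy_identity14":
        return tuple(sorted(int(p) for p in
                            rng.choice(np.arange(1, k + 1), size=7,
                                       replace=False)))
    raise ValueError(f"unknown pattern {pattern!r}")


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _decode(arr: np.ndarray) -> str:
    return "".join("ACGTN"[int(c)] for c in arr)


def random_construct(length: int, gc: float = 0.5, rng_seed: int = 0,
                     k: int = 21, distinct_kmers: bool = False,
                     identifier: str = "construct") -> DsRNAConstruct:
    """A reproducible random dsRNA construct (sense strand).

    With ``distinct_kmers`` the draw is repeated until all k-mers of the
    sequence are distinct, so the window-count law (L - k + 1 unique
    fragments, e.g. 378 at L=398) is exercisable.
    """
    if length < k:
        raise ValueError(f"length {length} shorter than k={k}")
    if not (0 < gc < 1):
        raise ValueError("gc must be strictly between 0 and 1")
    rng = np.random.default_rng(rng_seed)
    for _ in range(1000):
        seq = _decode(_random_bases(length, gc, rng))
        if not distinct_kmers:
            break
        kmers = {seq[i:i + k] for i in range(length - k + 1)}
        if len(kmers) == length - k + 1:
            break
    else:
        raise RuntimeError("could not draw a construct with distinct k-mers")
    return DsRNAConstruct(identifier=identifier, sense=seq)


def _fragment_matrix(fragments: Sequence[SirnaFragment]) -> np.ndarray:
    """(2F, k) uint8 matrix of all fragment strings and reverse complements.

    Covers both scan strands, so a window below threshold against every row
    can never produce a hit regardless of orientation policy.
    """
    rows = []
    for f in fragments:
        rows.append(encode(f.residues))
        rows.append(encode(reverse_complement(f.residues)))
    return np.stack(rows)


def _max_identity(windows: np.ndarray, frag_mat: np.ndarray,
                  chunk: int = 64) -> np.ndarray:
    """Per-window maximum identity against any fragment row."""
    W = windows.shape[0]
    maxid = np.zeros(W, dtype=np.int16)
    not_n = windows != _N_CODE
    for i in range(0, frag_mat.shape[0], chunk):
        block = frag_mat[i:i + chunk]
        eq = (windows[:, None, :] == block[None, :, :]) & not_n[:, None, :]
        np.maximum(maxid, eq.sum(axis=2, dtype=np.int16).max(axis=1),
                   out=maxid)
    return maxid


def _scrub(t_arr: np.ndarray, frozen: np.ndarray, frag_mat: np.ndarray,
           k: int, threshold: int, gc: float, rng: np.random.Generator,
           max_iter: int = 80) -> np.ndarray:
    """Re-draw windows matching any fragment at >= threshold identities.

    Windows overlapping a frozen (planted) footprint are left alone — hits
    there are attributable to the plant. Each pass re-draws every free base
    covered by an offending window; the expected number of offenders decays
    geometrically, so the loop converges in a few passes.
    """
    L = t_arr.shape[0]
    if L < k:
        return t_arr
    for _ in range(max_iter):
        windows = sliding_window_view(t_arr, k)
        overlap = sliding_window_view(frozen, k).max(axis=1).astype(bool)
        maxid = _max_identity(windows, frag_mat)
        bad = np.flatnonzero((maxid >= threshold) & ~overlap)
        if bad.size == 0:
            return t_arr
        redraw = np.zeros(L, dtype=bool)
        for w in bad:
            redraw[w:w + k] = True
        redraw &= ~frozen
        idx = np.flatnonzero(redraw)
        t_arr[idx] = _random_bases(idx.size, gc, rng)
    raise RuntimeError(
        "background scrubbing did not converge within the retry budget; "
        "use longer transcripts, fewer fragments or a higher identity "
        "threshold")


def _mutate(residues: str, positions: Sequence[int],
            rng: np.random.Generator) -> str:
    out = list(residues)
    for p in positions:
        current = out[p - 1]
        choices = [b for b in _BASES if b != current]
        out[p - 1] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def build_synthetic_db(construct: DsRNAConstruct,
                       specs: Sequence[PlantSpec],
                       n_background: int = 50,
                       len_range: tuple[int, int] = (200, 3000),
                       rng_seed: int = 0,
                       k: int = 21,
                       min_identities: int = 15,
                       gc: float = 0.5,
                       db_name: str = "synthetic_db"
                       ) -> tuple[TranscriptDb, list[TruthRecord]]:
    """Build a transcript database with planted sites and full ground truth.

    One planted site per transcript (so sites never overlap), plus
    ``n_background`` plant-free transcripts; every transcript is scrubbed so
    that no window outside a planted footprint matches any fragment (either
    strand) at ``min_identities`` or more.
    """
    if len_range[0] < k:
        raise ValueError(f"len_range minimum {len_range[0]} below k={k}")
    rng = np.random.default_rng(rng_seed)
    fragments = dice(construct, k=k, dedupe=True)
    frag_mat = _fragment_matrix(fragments)

    records: list[NucleotideSequence] = []
    truth: list[TruthRecord] = []
    plant_serial = 0
    for spec in specs:
        for _ in range(spec.count):
            plant_serial += 1
            frag = fragments[int(rng.integers(len(fragments)))]
            positions = _draw_pattern_positions(spec.pattern, k, rng)
            mutated = _mutate(frag.residues, positions, rng)
            strand = spec.strand
            if strand == "random":
                strand = "forward" if rng.integers(2) == 0 else "reverse"
            planted = (mutated if strand == "forward"
                       else reverse_complement(mutated))
            L = int(rng.integers(len_range[0], len_range[1] + 1))
            t0 = int(rng.integers(0, L - k + 1))  # 0-based plant start
            arr = _random_bases(L, gc, rng)
            arr[t0:t0 + k] = encode(planted)
            frozen = np.zeros(L, dtype=bool)
            frozen[t0:t0 + k] = True
            arr = _scrub(arr, frozen, frag_mat, k, min_identities, gc, rng)
            tid = f"plant{plant_serial:03d}_{spec.pattern}"
            records.append(NucleotideSequence(
                identifier=tid, residues=_decode(arr),
                description=f"planted {spec.pattern} site at "
                            f"{t0 + 1}-{t0 + k} ({strand})"))
            truth.append(TruthRecord(
                transcript_id=tid, t_start=t0 + 1, t_end=t0 + k,
                strand=strand, source_fragment_id=frag.fragment_id,
                source_residues=frag.residues, planted_residues=planted,
                pattern=spec.pattern, mismatch_positions=positions,
                expected=expected_retention(positions, k)))
    for i in range(n_background):
        L = int(rng.integers(len_range[0], len_range[1] + 1))
        arr = _random_bases(L, gc, rng)
        frozen = np.zeros(L, dtype=bool)
        arr = _scrub(arr, frozen, frag_mat, k, min_identities, gc, rng)
        records.append(NucleotideSequence(
            identifier=f"bg{i + 1:03d}", residues=_decode(arr),
            description="background (scrubbed)"))
    return TranscriptDb(records=tuple(records), db_name=db_name), truth


_TRUTH_COLUMNS = ["transcript_id", "t_start", "t_end", "strand",
                  "source_fragment_id", "source_residues",
                  "planted_residues", "pattern", "mismatch_positions"]


def write_truth_tsv(truth: Sequence[TruthRecord], path: Union[str, Path],
                    rng_seed: Optional[int] = None) -> None:
    """Write the truth table as TSV; expected flags become one column each."""
    import pandas as pd

    expected_keys = (sorted(truth[0].expected) if truth else
                     [f"{p}:{m}" for p in _ORACLE_PRESETS
                      for m in _COMBINE_MODES])
    rows = []
    for t in truth:
        row = {c: getattr(t, c) for c in _TRUTH_COLUMNS}
        row["mismatch_positions"] = ",".join(
            str(p) for p in t.mismatch_positions)
        for key in expected_keys:
            row[f"expected[{key}]"] = int(t.expected[key])
        rows.append(row)
    frame = pd.DataFrame(
        rows, columns=_TRUTH_COLUMNS + [f"expected[{k}]"
                                        for k in expected_keys])
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if rng_seed is not None:
            fh.write(f"# rng_seed={rng_seed}\n")
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def recovery_test(construct: DsRNAConstruct, db: TranscriptDb,
                  truth: Sequence[TruthRecord], config: FilterConfig,
                  orientation: Literal["both", "sense_only"] = "both",
                  k: int = 21,
                  hits=None) -> RecoveryResult:
    """Screen the synthetic database and score it against the truth table.

    Sensitivity is the fraction of expected-retained planted sites recovered
    by a retained hit at the exact (source fragment, position, strand)
    placement; ``false_positives`` counts retained hits whose placement does
    not overlap any planted footprint. ``hits`` may be supplied to reuse one
    search across several filter configurations.
    """
    if hits is None:
        fragments = enumerate_orientations(dice(construct, k=k),
                                           policy=orientation)
        hits = search_db(fragments, db, config)
    retained, _ = apply_funnel(hits, config)

    key = f"{config.preset}:{config.combine_mode}"
    retained_exact = {
        (d.hit.transcript_id, d.hit.t_start, d.hit.target_strand,
         d.hit.fragment.residues)
        for d in retained}
    n_expected = n_recovered = unexpected_exact = 0
    for t in truth:
        exact = (t.transcript_id, t.t_start, t.strand, t.source_residues)
        if t.expected.get(key, False):
            n_expected += 1
            n_recovered += exact in retained_exact
        elif exact in retained_exact:
            unexpected_exact += 1

    footprints: dict[str, list[tuple[int, int]]] = {}
    for t in truth:
        footprints.setdefault(t.transcript_id, []).append(
            (t.t_start, t.t_end))
    false_positives = 0
    for d in retained:
        spans = footprints.get(d.hit.transcript_id, [])
        if not any(d.hit.t_start <= e and d.hit.t_end >= s
                   for s, e in spans):
            false_positives += 1

    sensitivity = (n_recovered / n_expected) if n_expected else None
    return RecoveryResult(sensitivity=sensitivity,
                          false_positives=false_positives,
                          n_expected=n_expected, n_recovered=n_recovered,
                          n_retained=len(retained),
                          unexpected_exact=unexpected_exact)
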