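"""The three-tier off-target filter funnel.

A raw hit survives the funnel when it satisfies:

1. *overall identity* — at least ``min_total_identities`` matching positions
   over the full k-mer (the "~80% overall similarity" criterion; 16/21 by
   default);
2. *near-perfect stretch* — a contiguous stretch of at least
   ``min_near_perfect_len`` aligned positions containing at most
   ``max_mismatches_in_stretch`` mismatches (>=18 nt with one or two
   mismatches by default); and
3. *seed identity* — no mismatch within the seed region, guide positions
   2-8, where complementarity dominates both on- and off-target silencing.

How the three criteria combine is itself a modelling choice: the default
``or_then_seed`` mode retains hits passing (1 OR 2) AND 3 — the identity and
stretch criteria descend from disjunctive precedents, with the seed check as
a final filter — while ``and_chain`` requires all three. Both are first-class
and stamped into every report.

Three named threshold presets are shipped:

========  =====================  ========================
preset    min_total_identities   min_near_perfect_len
========  =====================  ========================
text      16                     18
figure6   15                     19
chen      16                     26
========  =====================  ========================

``chen`` records the original dsRNA-level criteria (16 bp perfect match OR
26 bp near-perfect match); its 26-nt stretch requirement can never fire on
21-nt fragments and is kept for documentation and comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from .homology_search import AlignmentHit, run_statistics

__all__ = [
    "FilterConfig",
    "FilterDecision",
    "FunnelCounts",
    "PRESETS",
    "seed_identical",
    "evaluate_criteria",
    "apply_funnel",
    "class_label",
]

#: preset name -> (min_total_identities, min_near_perfect_len)
PRESETS: dict[str, tuple[int, int]] = {
    "text": (16, 18),
    "figure6": (15, 19),
    "chen": (16, 26),
}

CombineMode = Literal["or_then_seed", "and_chain"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and combination mode for the filter funnel.

    ``min_identities`` is the scan-time floor (hits below it are never
    recorded); it defaults to 15, the loosest identity bound of any preset,
    so no funnel criterion can require a discarded hit.
    """

    min_total_identities: int = 16
    min_near_perfect_len: int = 18
    max_mismatches_in_stretch: int = 2
    seed_start: int = 2
    seed_end: int = 8
    preset: str = "text"
    combine_mode: CombineMode = "or_then_seed"
    min_identities: int = 15
    k: int = 21

    def __post_init__(self) -> None:
        if not (1 <= self.seed_start <= self.seed_end <= self.k):
            raise ValueError(
                f"seed interval [{self.seed_start}, {self.seed_end}] not "
                f"within 1..{self.k}")
        if self.combine_mode not in ("or_then_seed", "and_chain"):
            raise ValueError(f"unknown combine_mode {self.combine_mode!r}")
        if self.max_mismatches_in_stretch < 0:
            raise ValueError("max_mismatches_in_stretch must be >= 0")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "FilterConfig":
        """Build a config from a named preset; keyword overrides apply on top."""
        try:
            ident, stretch = PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; expected one of {sorted(PRESETS)}"
            ) from None
        base = dict(min_total_identities=ident, min_near_perfect_len=stretch,
                    preset=name)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class FilterDecision:
    """The funnel's verdict on one hit, with per-criterion flags."""

    hit: AlignmentHit
    passes_identity: bool
    passes_near_perfect: bool
    passes_seed: bool
    retained: bool
    class_label: str


@dataclass
class FunnelCounts:
    """Per-criterion survivor tally for auditing a funnel run."""

    input: int = 0
    crit1: int = 0
    crit2: int = 0
    crit1_or_2: int = 0
    seed: int = 0
    retained: int = 0

    def as_dict(self, config: FilterConfig) -> dict:
        return {"input": self.input, "crit1": self.crit1,
                "crit2": self.crit2, "crit1_or_2": self.crit1_or_2,
                "seed": self.seed, "retained": self.retained,
                "preset": config.preset, "combine_mode": config.combine_mode}


def seed_identical(hit: AlignmentHit, config: FilterConfig) -> bool:
    """True iff the hit has no mismatch in the seed region.

    Seed positions are guide coordinates (5' end = position 1) of the
    fragment as oriented in the hit; the interval is closed on both ends, so
    position 1 lies outside the default 2-8 seed.
    """
    return not any(config.seed_start <= p <= config.seed_end
                   for p in hit.mismatch_positions)


def class_label(hit: AlignmentHit) -> str:
    """Mismatch-class label: ``"<identities> bp (<start>–<end>), <n> mismatch(es)"``.

    The span is the aligned region after trimming terminal mismatches (the
    first to the last matching guide position, as a local aligner would
    report it); the mismatch count is the number of mismatches inside that
    span.
    """
    k = hit.fragment.k
    mm = set(hit.mismatch_positions)
    matches = [p for p in range(1, k + 1) if p not in mm]
    if not matches:
        return f"0 bp (0–0), {len(mm)} mismatches"
    span_start, span_end = matches[0], matches[-1]
    n_inside = sum(1 for p in mm if span_start <= p <= span_end)
    word = "mismatch" if n_inside == 1 else "mismatches"
    return (f"{hit.identities} bp ({span_start}–{span_end}), "
            f"{n_inside} {word}")


def evaluate_criteria(hit: AlignmentHit,
                      config: FilterConfig) -> FilterDecision:
    """Apply all three criteria to one hit (total function on valid hits).

    The near-perfect stretch statistic is recomputed from the mismatch
    positions with the config's own ``max_mismatches_in_stretch``, so a hit
    scanned under one stretch budget can be filtered under another.
    """
    k = hit.fragment.k
    _, best_near = run_statistics(hit.mismatch_positions, k,
                                  config.max_mismatches_in_stretch)
    passes_identity = hit.identities >= config.min_total_identities
    passes_near_perfect = best_near >= config.min_near_perfect_len
    passes_seed = seed_identical(hit, config)
    if config.combine_mode == "and_chain":
        retained = passes_identity and passes_near_perfect and passes_seed
    else:
        retained = (passes_identity or passes_near_perfect) and passes_seed
    return FilterDecision(hit=hit, passes_identity=passes_identity,
                          passes_near_perfect=passes_near_perfect,
                          passes_seed=passes_seed, retained=retained,
                          class_label=class_label(hit))


def apply_funnel(hits: Sequence[AlignmentHit], config: FilterConfig
                 ) -> tuple[list[FilterDecision], FunnelCounts]:
    """Run the funnel over deduplicated hits, preserving order.

    Returns the retained decisions and a :class:`FunnelCounts` audit tally
    (input, per-criterion survivors, retained).
    """
    counts = FunnelCounts(input=len(hits))
    retained: list[FilterDecision] = []
    for hit in hits:
        decision = evaluate_criteria(hit, config)
        counts.crit1 += decision.passes_identity
        counts.crit2 += decision.passes_near_perfect
        counts.crit1_or_2 += (decision.passes_identity
                              or decision.passes_near_perfect)
        counts.seed += decision.passes_seed
        counts.retained += decision.retained
        if decision.retained:
            retained.append(decision)
    return retained, counts
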