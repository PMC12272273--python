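"""Aggregation of retained hits into per-transcript tables and class tallies.

Two output shapes mirror the way off-target screens are reported: a
per-transcript table (which transcripts attract retained sites, how many,
from which fragments, at what best identity) and a mismatch-class
distribution (how retained hits partition over identity/span/mismatch
classes — the pie-chart view). Reports are written as TSV and versioned
JSON; output is byte-stable for identical inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .homology_search import TranscriptDb
from .offtarget_filter import FilterConfig, FilterDecision, FunnelCounts

__all__ = [
    "OffTargetReport",
    "PerTranscript",
    "aggregate",
    "class_distribution",
    "write_report",
    "read_report_json",
    "plot_class_distribution",
]

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class PerTranscript:
    transcript_id: str
    n_retained_sites: int
    fragment_ids: tuple[str, ...]
    best_identities: int
    description: str = ""


@dataclass(frozen=True)
class OffTargetReport:
    """Aggregated screening result for one database run."""

    db_name: str
    construct_id: str
    config: FilterConfig
    per_transcript: tuple[PerTranscript, ...]
    class_distribution: tuple[tuple[str, int], ...]
    totals: tuple[int, int, int]  # (n_fragments, n_hits_prefilter, n_retained)
    funnel: dict


def class_distribution(
        decisions: Sequence[FilterDecision]) -> list[tuple[str, int]]:
    """Group retained decisions by mismatch-class label.

    Counts partition the retained set; classes are ordered by count
    descending, then label, so the distribution is deterministic.
    """
    counts: dict[str, int] = {}
    for d in decisions:
        counts[d.class_label] = counts.get(d.class_label, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def aggregate(decisions: Sequence[FilterDecision], db: TranscriptDb,
              config: FilterConfig, *, construct_id: str = "",
              n_fragments: int = 0, n_hits_prefilter: Optional[int] = None,
              funnel_counts: Optional[FunnelCounts] = None
              ) -> OffTargetReport:
    """Build the per-transcript and class-distribution report.

    ``decisions`` must all come from one database run: a decision whose
    transcript is not in ``db`` raises (mixed-database aggregation would
    produce a silently wrong table). Transcript descriptions are joined from
    the database FASTA headers — the only annotation source supported.
    """
    known = {r.identifier: r.description for r in db.records}
    for d in decisions:
        if d.hit.transcript_id not in known:
            raise ValueError(
                f"decision for transcript '{d.hit.transcript_id}' does not "
                f"belong to database '{db.db_name}' (mixed databases?)")
    by_transcript: dict[str, list[FilterDecision]] = {}
    for d in decisions:
        by_transcript.setdefault(d.hit.transcript_id, []).append(d)
    per_transcript = tuple(sorted(
        (PerTranscript(
            transcript_id=tid,
            n_retained_sites=len(ds),
            fragment_ids=tuple(d.hit.fragment.fragment_id for d in ds),
            best_identities=max(d.hit.identities for d in ds),
            description=known[tid],
        ) for tid, ds in by_transcript.items()),
        key=lambda p: (-p.n_retained_sites, p.transcript_id)))
    n_retained = len(decisions)
    if n_hits_prefilter is None:
        n_hits_prefilter = n_retained
    funnel = (funnel_counts.as_dict(config) if funnel_counts is not None
              else {})
    return OffTargetReport(
        db_name=db.db_name,
        construct_id=construct_id,
        config=config,
        per_transcript=per_transcript,
        class_distribution=tuple(class_distribution(decisions)),
        totals=(n_fragments, n_hits_prefilter, n_retained),
        funnel=funnel,
    )


def _report_dict(report: OffTargetReport) -> dict:
    cfg = report.config
    return {
        "schema_version": SCHEMA_VERSION,
        "db_name": report.db_name,
        "construct_id": report.construct_id,
        "config": {
            "min_total_identities": cfg.min_total_identities,
            "min_near_perfect_len": cfg.min_near_perfect_len,
            "max_mismatches_in_stretch": cfg.max_mismatches_in_stretch,
            "seed_start": cfg.seed_start,
            "seed_end": cfg.seed_end,
            "preset": cfg.preset,
            "combine_mode": cfg.combine_mode,
            "min_identities": cfg.min_identities,
            "k": cfg.k,
        },
        "totals": {
            "n_fragments": report.totals[0],
            "n_hits_prefilter": report.totals[1],
            "n_retained": report.totals[2],
        },
        "funnel": report.funnel,
        "class_distribution": [
            {"class_label": label, "count": count}
            for label, count in report.class_distribution
        ],
        "per_transcript": [
            {"transcript_id": p.transcript_id,
             "n_retained_sites": p.n_retained_sites,
             "fragment_ids": list(p.fragment_ids),
             "best_identities": p.best_identities,
             "description": p.description}
            for p in report.per_transcript
        ],
    }


def write_report(report: OffTargetReport, out_dir: Union[str, Path],
                 formats: Iterable[str] = ("tsv", "json")) -> dict[str, Path]:
    """Write the report under ``out_dir`` as TSV and/or JSON.

    Returns a mapping format -> written path. Output bytes are a pure
    function of the report (UTF-8, LF, two-space JSON indent).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    formats = set(formats)
    unknown = formats - {"tsv", "json"}
    if unknown:
        raise ValueError(f"unknown report format(s): {sorted(unknown)}")
    written: dict[str, Path] = {}
    stem = f"{report.db_name}.offtarget_report"
    if "tsv" in formats:
        path = out_dir / f"{stem}.tsv"
        frame = pd.DataFrame(
            [{"transcript_id": p.transcript_id,
              "n_retained_sites": p.n_retained_sites,
              "best_identities": p.best_identities,
              "fragment_ids": ",".join(p.fragment_ids),
              "description": p.description}
             for p in report.per_transcript],
            columns=["transcript_id", "n_retained_sites", "best_identities",
                     "fragment_ids", "description"])
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written["tsv"] = path
    if "json" in formats:
        path = out_dir / f"{stem}.json"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(_report_dict(report), fh, indent=2, ensure_ascii=False)
            fh.write("\n")
        written["json"] = path
    return written


def read_report_json(path: Union[str, Path]) -> OffTargetReport:
    """Re-parse a JSON report into an equal :class:`OffTargetReport`."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if data.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported report schema {data.get('schema_version')!r}")
    cfg = FilterConfig(**data["config"])
    return OffTargetReport(
        db_name=data["db_name"],
        construct_id=data["construct_id"],
        config=cfg,
        per_transcript=tuple(
            PerTranscript(transcript_id=p["transcript_id"],
                          n_retained_sites=p["n_retained_sites"],
                          fragment_ids=tuple(p["fragment_ids"]),
                          best_identities=p["best_identities"],
                          description=p.get("description", ""))
            for p in data["per_transcript"]),
        class_distribution=tuple(
            (c["class_label"], c["count"])
            for c in data["class_distribution"]),
        totals=(data["totals"]["n_fragments"],
                data["totals"]["n_hits_prefilter"],
                data["totals"]["n_retained"]),
        funnel=data["funnel"],
    )


def plot_class_distribution(report: OffTargetReport,
                            path: Union[str, Path]) -> None:
    """Optional pie chart of the mismatch-class distribution.

    Rendering is a convenience; the numbers in the report, not the pixels,
    are the contract.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [label for label, _ in report.class_distribution]
    counts = [count for _, count in report.class_distribution]
    fig, ax = plt.subplots(figsize=(7, 7))
    if counts:
        ax.pie(counts, labels=labels, autopct=lambda pct: (
            f"{round(pct * sum(counts) / 100)}"))
    ax.set_title(f"Retained off-target sites by mismatch class "
                 f"({report.db_name}, preset {report.config.preset})")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
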