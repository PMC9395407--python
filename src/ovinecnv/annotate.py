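"""Interval arithmetic: CNVRs vs genes/QTLs, selection windows and
external CNVR sets.

All coordinates are 1-based inclusive; two intervals overlap when they
share at least one base, i.e. max(starts) <= min(ends), and the overlap is
min(ends) - max(starts) + 1. Gap distances between disjoint intervals on
one chromosome are max(starts) - min(ends) (without the +/-1), reported in
kb rounded half-up — the convention that reproduces printed cross-study
distance tables. Chromosome names are normalised by stripping a
"chr"/"Chr" prefix before joining.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._util import normalize_chrom, round_half_up_int

__all__ = [
    "GenomeInterval",
    "OverlapRecord",
    "intersect",
    "gap_distance",
    "gap_distance_kb",
    "selection_overlap",
    "cross_dataset_compare",
]


@dataclass(frozen=True)
class GenomeInterval:
    """A named 1-based inclusive genomic interval."""

    chromosome: str
    start_bp: int
    end_bp: int
    feature_id: str = ""
    feature_class: str = ""  # gene | QTL | CNVR | window

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))
        if self.start_bp > self.end_bp:
            raise ValueError(f"interval {self.feature_id!r} has start > end")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class OverlapRecord:
    query_id: str
    subject_id: str
    overlap_bp: int
    gap_bp: int
    relation: str  # overlap | proximal | distant


def _overlap_bp(a: GenomeInterval, b: GenomeInterval) -> int:
    return min(a.end_bp, b.end_bp) - max(a.start_bp, b.start_bp) + 1


def intersect(queries: Sequence[GenomeInterval], subjects: Sequence[GenomeInterval]) -> list[OverlapRecord]:
    """All query/subject pairs sharing >= 1 base, by chromosome sweep-line.

    Output is sorted by (chromosome, query start, subject start). Pairs on
    chromosomes absent from the other set simply produce no records.
    """
    by_chrom: dict[str, list[GenomeInterval]] = {}
    for s in subjects:
        by_chrom.setdefault(s.chromosome, []).append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda iv: (iv.start_bp, iv.end_bp))
    records: list[OverlapRecord] = []
    for q in sorted(queries, key=lambda iv: (iv.chromosome, iv.start_bp, iv.end_bp)):
        subs = by_chrom.get(q.chromosome, ())
        # sweep: subjects sorted by start; stop once start passes query end
        for s in subs:
            if s.start_bp > q.end_bp:
                break
            ov = _overlap_bp(q, s)
            if ov >= 1:
                records.append(OverlapRecord(q.feature_id, s.feature_id, ov, 0, "overlap"))
    return records


def gap_distance(a: GenomeInterval, b: GenomeInterval) -> int:
    """Gap in bp between two same-chromosome intervals; 0 when overlapping."""
    if a.chromosome != b.chromosome:
        raise ValueError("gap distance is undefined across chromosomes")
    if max(a.start_bp, b.start_bp) <= min(a.end_bp, b.end_bp):
        return 0
    return max(a.start_bp, b.start_bp) - min(a.end_bp, b.end_bp)


def gap_distance_kb(a: GenomeInterval, b: GenomeInterval) -> int:
    """Gap distance in kb, rounded half-up to an integer."""
    return round_half_up_int(gap_distance(a, b) / 1000.0)


def selection_overlap(
    cnvrs: Sequence[GenomeInterval],
    flagged_windows: Sequence[GenomeInterval],
) -> dict[str, list[str]]:
    """CNVRs overlapping at least one flagged selection window.

    Returns {cnvr id: [window ids]} for the overlapping subset; empty dict
    when no windows are flagged.
    """
    hits: dict[str, list[str]] = {}
    for rec in intersect(cnvrs, flagged_windows):
        hits.setdefault(rec.query_id, []).append(rec.subject_id)
    return hits


def cross_dataset_compare(
    cnvrs_a: Sequence[GenomeInterval],
    cnvrs_b: Sequence[GenomeInterval],
    proximity_kb: float = 1000.0,
) -> tuple[list[OverlapRecord], dict]:
    """Match each region of set B to its nearest region of set A.

    Relations: "overlap" (>= 1 shared base), "proximal" (gap within
    ``proximity_kb``), else "distant"; regions of B on chromosomes absent
    from A get no match record. The summary reports the matched (overlap or
    proximal) fraction of B as a half-up-rounded percentage — the
    "overlapped or located close" statistic of cross-study comparisons.
    """
    by_chrom: dict[str, list[GenomeInterval]] = {}
    for a in cnvrs_a:
        by_chrom.setdefault(a.chromosome, []).append(a)
    records: list[OverlapRecord] = []
    matched = 0
    for b in cnvrs_b:
        candidates = by_chrom.get(b.chromosome)
        if not candidates:
            continue
        nearest = min(candidates, key=lambda a: (gap_distance(a, b), a.start_bp))
        gap = gap_distance(nearest, b)
        if gap == 0:
            relation = "overlap"
        elif gap / 1000.0 <= proximity_kb:
            relation = "proximal"
        else:
            relation = "distant"
        if relation != "distant":
            matched += 1
        records.append(
            OverlapRecord(
                query_id=b.feature_id,
                subject_id=nearest.feature_id,
                overlap_bp=max(_overlap_bp(nearest, b), 0),
                gap_bp=gap,
                relation=relation,
            )
        )
    n_b = len(cnvrs_b)
    summary = {
        "n_b": n_b,
        "n_matched": matched,
        "percent_matched": round_half_up_int(100.0 * matched / n_b) if n_b else 0,
    }
    return records, summary
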