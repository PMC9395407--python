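"""CNV-region construction, classification and descriptive statistics.

A CNV region (CNVR) is the transitive closure of pairwise-overlapping CNV
calls (>= 1 shared base, 1-based inclusive) within a chromosome, spanning
the union of its supporting calls. Regions are classified **Loss** when
every supporting call is a deletion, **Gain** when every call is a
duplication, and **Both** otherwise. Copy-neutral LOH never contributes.

``summarize`` reproduces the descriptive rows of the standard CNV/CNVR
summary tables: counts, total/mean/median lengths in kb, size-class counts
and percentages for [20, 100) kb, [100, 500] kb and > 500 kb, and the
genome-proportion line total_length / (n_samples x genome_length) as a
percentage. Percentages are rounded half-up to integers as printed tables
round them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import round_half_up, round_half_up_int
from .hmm import CnvCall

__all__ = ["Cnvr", "CnvSummary", "merge_calls", "classify", "summarize", "venn_counts"]

#: Reference genome length used for the genome-proportion row (sheep, kb).
SHEEP_GENOME_KB = 2_500_000.0


@dataclass
class Cnvr:
    """A merged CNV region (1-based inclusive union span)."""

    chromosome: str
    start_bp: int
    end_bp: int
    status: str  # Loss | Gain | Both
    call_indices: list[int] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)
    breeds: list[str] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


@dataclass
class CnvSummary:
    """Descriptive statistics over a set of events (calls or regions)."""

    n_events: int
    total_length_kb: float
    mean_length_kb: float
    median_length_kb: float
    size_class_counts: tuple[int, int, int]  # [20,100) kb, [100,500] kb, >500 kb
    size_class_percent: tuple[int, int, int]
    genome_proportion_percent: float | None = None


def classify(copy_numbers) -> str:
    """Loss if all supporting copy numbers < 2, Gain if all > 2, else Both."""
    cns = list(copy_numbers)
    if not cns:
        raise ValueError("a CNVR needs at least one supporting call")
    if any(c == 2 for c in cns):
        raise ValueError("copy-neutral calls cannot support a CNVR")
    if all(c < 2 for c in cns):
        return "Loss"
    if all(c > 2 for c in cns):
        return "Gain"
    return "Both"


def merge_calls(
    calls: list[CnvCall],
    breed_of_sample: dict[str, str] | None = None,
    scope: str = "cohort",
) -> list[Cnvr] | dict[str, list[Cnvr]]:
    """Aggregate overlapping calls from different animals into CNVRs.

    ``scope="cohort"`` merges across all calls and returns one list;
    ``scope="per-breed"`` partitions calls by breed (via
    ``breed_of_sample``) and returns ``{breed: [Cnvr, ...]}`` — no
    cross-breed merging, matching per-breed region counts that sum to the
    study-wide total. Output order is deterministic (chromosome, start).
    """
    if scope == "per-breed":
        if breed_of_sample is None:
            raise ValueError("per-breed scope requires breed_of_sample")
        by_breed: dict[str, list[CnvCall]] = {}
        for c in calls:
            by_breed.setdefault(breed_of_sample[c.sample_id], []).append(c)
        return {b: merge_calls(cs, breed_of_sample, scope="cohort") for b, cs in sorted(by_breed.items())}
    if scope != "cohort":
        raise ValueError("scope must be 'cohort' or 'per-breed'")

    order = sorted(range(len(calls)), key=lambda i: (_chrom_key(calls[i].chromosome), calls[i].start_bp, calls[i].end_bp))
    regions: list[Cnvr] = []
    cluster: list[int] = []
    cur_chrom, cur_end = None, -1
    for i in order:
        c = calls[i]
        if c.start_bp > c.end_bp:
            raise ValueError("call with start > end")
        if cluster and c.chromosome == cur_chrom and c.start_bp <= cur_end:
            cluster.append(i)
            cur_end = max(cur_end, c.end_bp)
        else:
            if cluster:
                regions.append(_build_region(calls, cluster, breed_of_sample))
            cluster = [i]
            cur_chrom, cur_end = c.chromosome, c.end_bp
    if cluster:
        regions.append(_build_region(calls, cluster, breed_of_sample))
    return regions


def _chrom_key(chrom: str):
    s = str(chrom)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def _build_region(calls, cluster, breed_of_sample) -> Cnvr:
    members = [calls[i] for i in cluster]
    samples = sorted({c.sample_id for c in members})
    breeds = sorted({breed_of_sample[c.sample_id] for c in members}) if breed_of_sample else []
    return Cnvr(
        chromosome=members[0].chromosome,
        start_bp=min(c.start_bp for c in members),
        end_bp=max(c.end_bp for c in members),
        status=classify(c.copy_number for c in members),
        call_indices=list(cluster),
        samples=samples,
        breeds=breeds,
    )


def summarize(
    lengths_kb=None,
    events=None,
    n_samples: int | None = None,
    genome_length_kb: float = SHEEP_GENOME_KB,
) -> CnvSummary:
    """Descriptive statistics over events given as objects or lengths in kb.

    Size classes partition at 100 kb (exclusive) and 500 kb (inclusive);
    events shorter than 20 kb would fall in the first class, but the calling
    resolution of a 50k array makes them unreachable in practice. An empty
    input yields an all-zero summary.
    """
    if lengths_kb is None:
        lengths_kb = [e.length_bp / 1000.0 for e in (events or [])]
    lengths = np.asarray(list(lengths_kb), dtype=float)
    if lengths.size and np.any(lengths <= 0):
        raise ValueError("event lengths must be positive")
    n = int(lengths.size)
    if n == 0:
        return CnvSummary(0, 0.0, 0.0, 0.0, (0, 0, 0), (0, 0, 0), 0.0 if n_samples else None)
    total = float(lengths.sum())
    small = int((lengths < 100.0).sum())
    mid = int(((lengths >= 100.0) & (lengths <= 500.0)).sum())
    large = int((lengths > 500.0).sum())
    pct = tuple(round_half_up_int(100.0 * k / n) for k in (small, mid, large))
    genome_pct = None
    if n_samples:
        genome_pct = 100.0 * total / (n_samples * genome_length_kb)
    return CnvSummary(
        n_events=n,
        total_length_kb=total,
        mean_length_kb=total / n,
        median_length_kb=float(np.median(lengths)),
        size_class_counts=(small, mid, large),
        size_class_percent=pct,  # type: ignore[arg-type]
        genome_proportion_percent=genome_pct,
    )


def mean_length_kb(total_length_kb: float, n_events: int, ndigits: int = 0) -> float:
    """Mean event length from a printed total and count, table-rounded."""
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    return round_half_up(total_length_kb / n_events, ndigits)


def venn_counts(
    per_breed_regions: dict[str, list[Cnvr]],
    reciprocal_overlap: float = 0.0,
) -> dict[frozenset, int]:
    """Cross-breed sharing counts over per-breed CNVR sets.

    Each region is assigned to the combination of breeds (including its own)
    that have at least one region overlapping it — by >= 1 bp, or by the
    given reciprocal fraction of both lengths when ``reciprocal_overlap`` >
    0. The returned mapping from breed combinations to counts partitions
    every breed's set, as a Venn diagram does.
    """
    breeds = sorted(per_breed_regions)
    if len(breeds) < 2:
        raise ValueError("venn_counts needs at least two breeds")
    counts: dict[frozenset, int] = {}
    for b in breeds:
        for region in per_breed_regions[b]:
            combo = {b}
            for other in breeds:
                if other == b:
                    continue
                if any(_shares(region, r2, reciprocal_overlap) for r2 in per_breed_regions[other]):
                    combo.add(other)
            key = frozenset(combo)
            counts[key] = counts.get(key, 0) + 1
    return counts


def _shares(a: Cnvr, b: Cnvr, reciprocal: float) -> bool:
    if a.chromosome != b.chromosome:
        return False
    ov = min(a.end_bp, b.end_bp) - max(a.start_bp, b.start_bp) + 1
    if ov < 1:
        return False
    if reciprocal <= 0:
        return True
    return ov >= reciprocal * a.length_bp and ov >= reciprocal * b.length_bp
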