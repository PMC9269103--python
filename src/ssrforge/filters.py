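"""Seven-criterion selection cascade for SSR marker candidates.

Candidates (an SSR locus plus its host contig and mapping annotations) are
screened in a fixed order: (1) compound loci, (2) overlap with annotated
repetitive elements, (3) multi-mapping reads, (4) coverage / length /
flank, (5) number of occurrences in a draft genome, (6) motif unit length,
(7) GC content.  A failing candidate records the FIRST violated criterion,
making attrition accounting reproducible; survivors are ranked for primer
design (longer repeats first, then GC closest to the genome average).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .io import BlastHit, ContigRecord, RepeatAnnotation
from .mining import SSRLocus

__all__ = [
    "FilterParams",
    "MarkerCandidate",
    "gc_fraction",
    "count_genome_occurrences",
    "apply_filters",
    "rank_candidates",
    "ssr_summary",
]


@dataclass
class FilterParams:
    """Filter windows.

    expected_coverage
        Sequencing depth the library targeted (x); contigs outside
        ``coverage_window`` multiples of it fail criterion 4 (collapsed
        repeats sit high, chimeras low).
    min_length
        Smallest acceptable contig length in nt (131 = "more than 130").
    gc_center, gc_halfwidth
        The GC acceptance window, as fractions (0.43 +/- 0.10).
    max_genome_occurrences
        Largest acceptable copy number in the draft genome (single- or
        two-copy loci amplify cleanly).
    min_flank
        Minimum nt on each side of the SSR so primers are designable.
    allowed_unit_lens
        Motif unit sizes kept by criterion 6 (di- and trinucleotide).
    max_multimap_fraction
        Criterion 3 threshold on the contig's multi-mapping read share.
    """

    expected_coverage: float = 12.5
    coverage_window: tuple[float, float] = (0.5, 2.0)
    min_length: int = 131
    gc_center: float = 0.43
    gc_halfwidth: float = 0.10
    max_genome_occurrences: int = 2
    min_flank: int = 30
    allowed_unit_lens: frozenset[int] = frozenset({2, 3})
    max_multimap_fraction: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.coverage_window
        if not 0 < lo < hi:
            raise ValueError("coverage_window must be an increasing positive pair")
        if self.gc_halfwidth <= 0 or self.expected_coverage <= 0:
            raise ValueError("degenerate filter window")


@dataclass
class MarkerCandidate:
    """An SSR locus with every annotation the filter cascade consumes."""

    contig: ContigRecord
    ssr: SSRLocus
    gc: float = 0.0
    mean_coverage: float | None = None
    multimap_fraction: float | None = None
    repeat_hit: bool = False
    genome_occurrences: int | None = None
    status: str = "UNTESTED"  # "PASS" | "FAIL(k)" | "UNTESTED"
    rank_score: float = 0.0

    @property
    def left_flank(self) -> int:
        return self.ssr.start - 1

    @property
    def right_flank(self) -> int:
        return len(self.contig.seq) - self.ssr.end

    @property
    def passed(self) -> bool:
        return self.status == "PASS"

    @property
    def failed_criterion(self) -> int | None:
        if self.status.startswith("FAIL("):
            return int(self.status[5:-1])
        return None


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous bases; N excluded from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / acgt


def count_genome_occurrences(
    hits: list[BlastHit],
    query_len: int,
    min_identity: float = 90.0,
    min_query_cov: float = 0.8,
) -> int:
    """Number of distinct draft-genome occurrences supported by BLAST hits.

    A hit counts when identity >= ``min_identity`` and it covers at least
    ``min_query_cov`` of the query; hits landing on the same subject
    interval (>= 50% reciprocal overlap) collapse to one occurrence, so a
    split alignment is not double-counted.
    """
    strong = [
        h
        for h in hits
        if h.pct_identity >= min_identity
        and (h.q_end - h.q_start + 1) / query_len >= min_query_cov
    ]
    kept: list[BlastHit] = []
    for hit in sorted(strong, key=lambda h: (h.subject_id, h.s_start, h.s_end)):
        dup = False
        for other in kept:
            if other.subject_id != hit.subject_id:
                continue
            ov = min(hit.s_end, other.s_end) - max(hit.s_start, other.s_start) + 1
            if ov <= 0:
                continue
            len_a = hit.s_end - hit.s_start + 1
            len_b = other.s_end - other.s_start + 1
            if ov / len_a >= 0.5 and ov / len_b >= 0.5:
                dup = True
                break
        if not dup:
            kept.append(hit)
    return len(kept)


def _evaluate(
    cand: MarkerCandidate,
    annotations: dict[str, RepeatAnnotation],
    params: FilterParams,
) -> str:
    # criterion 1: compound microsatellite
    if cand.ssr.is_compound:
        return "FAIL(1)"
    # criterion 2: overlap with an annotated repetitive element
    ann = annotations.get(cand.contig.id)
    if cand.repeat_hit or (ann is not None and ann.overlaps(cand.ssr.start, cand.ssr.end)):
        return "FAIL(2)"
    # criterion 3: multi-mapping reads dominate the contig
    if cand.multimap_fraction is None:
        raise ValueError(f"candidate {cand.contig.id}: missing multimap annotation")
    if cand.multimap_fraction > params.max_multimap_fraction:
        return "FAIL(3)"
    # criterion 4: coverage near expectation, adequate length and flanks
    if cand.mean_coverage is None:
        raise ValueError(f"candidate {cand.contig.id}: missing coverage annotation")
    lo, hi = params.coverage_window
    cov_ok = (
        params.expected_coverage * lo <= cand.mean_coverage <= params.expected_coverage * hi
    )
    if (
        not cov_ok
        or len(cand.contig.seq) < params.min_length
        or cand.left_flank < params.min_flank
        or cand.right_flank < params.min_flank
    ):
        return "FAIL(4)"
    # criterion 5: one or two occurrences in the draft genome
    if cand.genome_occurrences is not None and not (
        1 <= cand.genome_occurrences <= params.max_genome_occurrences
    ):
        return "FAIL(5)"
    # criterion 6: di-/trinucleotide motifs only
    if cand.ssr.unit_len not in params.allowed_unit_lens:
        return "FAIL(6)"
    # criterion 7: GC inside the genome-typical window
    if abs(cand.gc - params.gc_center) > params.gc_halfwidth:
        return "FAIL(7)"
    return "PASS"


def apply_filters(
    candidates: list[MarkerCandidate],
    repeat_annotations: dict[str, RepeatAnnotation] | None = None,
    params: FilterParams | None = None,
) -> list[MarkerCandidate]:
    """Evaluate every candidate against criteria 1-7 in order.

    Returns new candidates with ``status`` set; a FAIL names the first
    violated criterion only, and the outcome for one candidate never
    depends on the others (order-stable, idempotent).
    """
    params = params or FilterParams()
    annotations = repeat_annotations or {}
    out = []
    for cand in candidates:
        cand = replace(cand, gc=gc_fraction(cand.contig.seq))
        out.append(replace(cand, status=_evaluate(cand, annotations, params)))
    return out


def rank_candidates(
    candidates: list[MarkerCandidate], params: FilterParams | None = None
) -> list[MarkerCandidate]:
    """Order passing candidates for primer design.

    Sort key: descending repeat count, then GC closest to the genome
    average, then contig id — fully deterministic.
    """
    params = params or FilterParams()
    if any(not c.passed for c in candidates):
        raise ValueError("rank_candidates expects PASS candidates only")
    ranked = sorted(
        candidates,
        key=lambda c: (-c.ssr.repeat_count, abs(c.gc - params.gc_center), c.contig.id),
    )
    return [replace(c, rank_score=float(i + 1)) for i, c in enumerate(ranked)]


def ssr_summary(loci: list[SSRLocus], contigs: list[ContigRecord]) -> dict:
    """Mining yield accounting.

    Reports total contigs, SSR-containing contigs, contigs with more than
    one SSR, total loci, and the percentage of SSR-containing contigs with
    a single locus (1-decimal).  Compound loci count via their members.
    """
    per_contig: dict[str, int] = {}
    total_loci = 0
    for locus in loci:
        n = len(locus.members) if locus.is_compound and locus.members else 1
        per_contig[locus.contig_id] = per_contig.get(locus.contig_id, 0) + n
        total_loci += n
    containing = len(per_contig)
    multi = sum(1 for v in per_contig.values() if v > 1)
    return {
        "total_contigs": len(contigs),
        "ssr_containing_contigs": containing,
        "contigs_with_multiple_ssrs": multi,
        "total_ssr_loci": total_loci,
        "single_ssr_percent": (
            round((containing - multi) / containing * 100, 1) if containing else None
        ),
    }


def single_ssr_percent(containing: int, multi: int) -> float | None:
    """Single-locus share of SSR-containing contigs, from counts alone."""
    if containing == 0:
        return None
    return round((containing - multi) / containing * 100, 1)


def summary_frame(candidates: list[MarkerCandidate]) -> pd.DataFrame:
    """Per-criterion attrition table for logging."""
    rows = []
    for k in range(1, 8):
        rows.append(
            {"criterion": k, "failed": sum(1 for c in candidates if c.failed_criterion == k)}
        )
    rows.append({"criterion": "PASS", "failed": sum(1 for c in candidates if c.passed)})
    return pd.DataFrame(rows)
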