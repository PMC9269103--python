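"""Contig fragments from overlapping read pairs, plus k-mer coverage.

This is the pipeline's second contig-generation route: paired-end reads
from short fragments are joined across their 3' overlap, the joined
sequences are strand-aware deduplicated, and the resulting contigs are
annotated with mean read coverage and a multi-mapping fraction via exact
k-mer pseudo-mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import ContigRecord, ReadPair

__all__ = ["MergeParams", "NO_MERGE", "merge_pair", "dedupe", "revcomp", "estimate_coverage"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Sentinel returned when a pair has no admissible (or an ambiguous) overlap.
NO_MERGE = None


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MergeParams:
    """Overlap-merging parameters.

    min_overlap
        Smallest admissible 3' overlap in nt (>= 10); short overlaps are
        too likely to be spurious in a repetitive genome.
    max_mismatch_rate
        Largest tolerated mismatch fraction inside the overlap.
    dedupe
        Whether to strand-aware deduplicate merged sequences afterwards.
    """

    min_overlap: int = 30
    max_mismatch_rate: float = 0.1
    dedupe: bool = True

    def __post_init__(self) -> None:
        if self.min_overlap < 10:
            raise ValueError("min_overlap must be >= 10")
        if not 0 <= self.max_mismatch_rate <= 1:
            raise ValueError("max_mismatch_rate must lie in [0, 1]")


def merge_pair(pair: ReadPair, params: MergeParams | None = None) -> str | None:
    """Join a standard FR read pair across its best 3' overlap.

    Read 2 is reverse-complemented, then the suffix of read 1 is aligned
    against the prefix of the reverse-complemented read 2 at every offset.
    The longest overlap with length >= ``min_overlap`` and mismatch rate
    <= ``max_mismatch_rate`` wins; inside the overlap the base with the
    higher Phred quality is kept (read 1 on ties).  Returns ``NO_MERGE``
    when no overlap is admissible or when the two best admissible overlaps
    tie on length (ambiguity guard).
    """
    params = params or MergeParams()
    s1, q1 = pair.seq1, pair.qual1
    s2 = revcomp(pair.seq2)
    q2 = pair.qual2[::-1]
    if not s1 or not s2:
        raise ValueError("empty read")
    len1, len2 = len(s1), len(s2)

    admissible: list[tuple[int, int, int]] = []  # (overlap_len, offset, mismatches)
    for offset in range(0, len1 - params.min_overlap + 1):
        ov = min(len1 - offset, len2)
        if ov < params.min_overlap:
            continue
        mism = sum(1 for a, b in zip(s1[offset : offset + ov], s2[:ov]) if a != b)
        if mism / ov <= params.max_mismatch_rate:
            admissible.append((ov, offset, mism))
    if not admissible:
        return NO_MERGE
    admissible.sort(key=lambda t: (-t[0], t[1]))
    if len(admissible) > 1 and admissible[0][0] == admissible[1][0]:
        return NO_MERGE  # two distinct overlaps of the same length: ambiguous
    ov, offset, _ = admissible[0]

    consensus = []
    for i in range(ov):
        a, b = s1[offset + i], s2[i]
        if a == b:
            consensus.append(a)
        else:
            consensus.append(a if q1[offset + i] >= q2[i] else b)
    return s1[:offset] + "".join(consensus) + s2[ov:]


def dedupe(sequences: Sequence[str]) -> list[str]:
    """Remove exact and exact-reverse-complement duplicates.

    The first occurrence is kept and input order is otherwise preserved.
    Idempotent by construction.
    """
    seen: set[str] = set()
    out: list[str] = []
    for seq in sequences:
        key = min(seq, revcomp(seq))
        if key not in seen:
            seen.add(key)
            out.append(seq)
    return out


def estimate_coverage(
    contigs: Sequence[ContigRecord],
    read_pairs: Iterable[ReadPair],
    k: int = 31,
) -> list[ContigRecord]:
    """Annotate contigs with mean coverage and multi-mapping fraction.

    A lightweight exact-k-mer pseudo-mapper: each read is assigned to every
    contig with which it shares at least one exact k-mer (either strand).
    A read assigned to more than one contig contributes to the multi-mapping
    fraction of each; mean coverage is assigned read bases over contig
    length.  ``k`` must not exceed the shortest read.
    """
    index: dict[str, set[int]] = {}
    for ci, contig in enumerate(contigs):
        seq = contig.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                index.setdefault(kmer, set()).add(ci)

    assigned_bases = [0] * len(contigs)
    n_assigned = [0] * len(contigs)
    n_multi = [0] * len(contigs)

    def _assign(seq: str) -> None:
        if len(seq) < k:
            raise ValueError(f"k={k} exceeds read length {len(seq)}")
        matches: set[int] = set()
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - k + 1):
                hit = index.get(strand_seq[i : i + k])
                if hit:
                    matches |= hit
        for ci in matches:
            assigned_bases[ci] += len(seq)
            n_assigned[ci] += 1
            if len(matches) > 1:
                n_multi[ci] += 1

    for pair in read_pairs:
        _assign(pair.seq1)
        _assign(pair.seq2)

    out: list[ContigRecord] = []
    for ci, contig in enumerate(contigs):
        out.append(
            ContigRecord(
                id=contig.id,
                seq=contig.seq,
                source=contig.source,
                mean_coverage=assigned_bases[ci] / len(contig.seq),
                multimap_fraction=(n_multi[ci] / n_assigned[ci]) if n_assigned[ci] else 0.0,
            )
        )
    return out
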