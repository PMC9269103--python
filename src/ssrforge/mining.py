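"""Perfect-microsatellite detection and motif canonicalization.

The miner reports maximal perfect tandem runs of 2-6 nt units (no
mononucleotides), each under its smallest true unit and leftmost phase,
using per-unit minimum repeat counts of 8/6/5/4/4 for unit sizes 2-6.
Motifs are grouped into strand- and rotation-neutral classes (e.g. both
``TG`` and ``CA`` belong to ``AC/GT``) for frequency reporting, and
neighbouring loci separated by a short interruption are flagged as one
compound locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import pandas as pd

from .io import ContigRecord
from .merge import revcomp

__all__ = [
    "MiningParams",
    "SSRLocus",
    "find_ssrs",
    "canonical_class",
    "mark_compound",
    "motif_frequency_table",
]

DEFAULT_MIN_REPEATS = {2: 8, 3: 6, 4: 5, 5: 4, 6: 4}


@dataclass
class MiningParams:
    """Mining thresholds: unit sizes 2-6 nt with per-size minimum repeat
    counts (defaults 2-8, 3-6, 4-5, 5-4, 6-4) and the maximum interruption
    (nt) under which adjacent loci form one compound locus."""

    min_repeats: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_REPEATS))
    max_interrupt: int = 100

    def __post_init__(self) -> None:
        if set(self.min_repeats) != {2, 3, 4, 5, 6}:
            raise ValueError("min_repeats must define unit sizes 2..6 exactly")
        if self.max_interrupt < 0:
            raise ValueError("max_interrupt must be non-negative")


@dataclass
class SSRLocus:
    """A detected perfect tandem repeat (coordinates 1-based inclusive)."""

    contig_id: str
    start: int
    end: int
    motif: str
    unit_len: int
    repeat_count: int
    canonical_class: str
    is_compound: bool = False
    members: list["SSRLocus"] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _is_primitive(motif: str) -> bool:
    """True iff the motif is not a whole-number repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_class(motif: str) -> str:
    """Strand/rotation-neutral class label for a primitive 2-6 nt motif.

    The class is the set of all cyclic rotations of the motif and of its
    reverse complement; the label is ``X/Y`` where X is the
    lexicographically smallest class member and Y the smallest rotation of
    X's reverse complement (e.g. ``TG`` -> ``AC/GT``, ``AT`` -> ``AT/AT``).
    """
    if not 2 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 2..6, got {motif!r}")
    if not _is_primitive(motif):
        raise ValueError(f"motif {motif!r} is a power of a shorter unit")
    rotations = {motif[i:] + motif[:i] for i in range(len(motif))}
    rc = revcomp(motif)
    rotations |= {rc[i:] + rc[:i] for i in range(len(rc))}
    x = min(rotations)
    xrc = revcomp(x)
    y = min(xrc[i:] + xrc[:i] for i in range(len(xrc)))
    return f"{x}/{y}"


def all_canonical_classes(unit_len: int) -> set[str]:
    """Every reachable class label for primitive motifs of one unit size."""
    return {
        canonical_class("".join(m))
        for m in product("ACGT", repeat=unit_len)
        if _is_primitive("".join(m))
    }


def find_ssrs(contig: ContigRecord, params: MiningParams | None = None) -> list[SSRLocus]:
    """Detect maximal perfect SSR runs in one contig, left to right.

    Each run is reported once, under its smallest true unit (``ACACACAC``
    is an (AC)4-type run, never (ACAC)2) and leftmost phase; a trailing
    partial unit is excluded.  Runs containing ``N`` are not reported.
    """
    params = params or MiningParams()
    seq = contig.seq
    n = len(seq)
    loci: list[SSRLocus] = []
    i = 0
    while i < n:
        found = None
        for u in sorted(params.min_repeats):
            motif = seq[i : i + u]
            if len(motif) < u or "N" in motif or not _is_primitive(motif):
                continue
            count = 1
            j = i + u
            while seq[j : j + u] == motif:
                count += 1
                j += u
            if count >= params.min_repeats[u]:
                found = SSRLocus(
                    contig_id=contig.id,
                    start=i + 1,
                    end=i + u * count,
                    motif=motif,
                    unit_len=u,
                    repeat_count=count,
                    canonical_class=canonical_class(motif),
                )
                break
        if found is not None:
            loci.append(found)
            i = found.end  # 0-based index just past the last complete unit
        else:
            i += 1
    return loci


def mark_compound(loci: list[SSRLocus], max_interrupt: int = 100) -> list[SSRLocus]:
    """Merge same-contig loci separated by <= ``max_interrupt`` nt.

    Chains propagate: three loci with short gaps collapse into a single
    compound locus carrying all members.  Input must be sorted by start
    within each contig.
    """
    out: list[SSRLocus] = []
    group: list[SSRLocus] = []

    def _flush() -> None:
        if not group:
            return
        if len(group) == 1:
            out.append(replace(group[0], is_compound=False, members=None))
        else:
            first, last = group[0], group[-1]
            out.append(
                SSRLocus(
                    contig_id=first.contig_id,
                    start=first.start,
                    end=last.end,
                    motif="+".join(m.motif for m in group),
                    unit_len=first.unit_len,
                    repeat_count=sum(m.repeat_count for m in group),
                    canonical_class="compound",
                    is_compound=True,
                    members=list(group),
                )
            )

    for locus in loci:
        if group and (
            locus.contig_id != group[-1].contig_id
            or locus.start - group[-1].end - 1 > max_interrupt
        ):
            _flush()
            group = []
        group.append(locus)
    _flush()
    return out


def motif_frequency_table(loci: list[SSRLocus]) -> pd.DataFrame:
    """Counts and percentages per (unit length, canonical class).

    Compound loci are excluded; percentages are over all simple loci and
    sum to 100.
    """
    simple = [l for l in loci if not l.is_compound]
    if not simple:
        return pd.DataFrame(columns=["unit_len", "canonical_class", "count", "percent"])
    df = (
        pd.DataFrame(
            {"unit_len": [l.unit_len for l in simple],
             "canonical_class": [l.canonical_class for l in simple]}
        )
        .value_counts(["unit_len", "canonical_class"])
        .rename("count")
        .reset_index()
        .sort_values(["unit_len", "count", "canonical_class"], ascending=[True, False, True])
        .reset_index(drop=True)
    )
    df["percent"] = df["count"] / df["count"].sum() * 100.0
    return df
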