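"""Readers and writers for the external formats the pipeline touches.

Sequence formats (FASTA, FASTQ) are parsed with Biopython; the tabular
annotation formats (RepeatMasker ``.out``, BLAST outfmt 6) and the diploid
genotype table are small line formats handled directly.  All user-facing
coordinates are 1-based inclusive, matching the RepeatMasker/BLAST
conventions consumed here.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
from Bio import SeqIO

__all__ = [
    "ContigRecord",
    "ReadPair",
    "RepeatAnnotation",
    "BlastHit",
    "GenotypeMatrix",
    "MISSING",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "parse_repeatmasker_out",
    "parse_blast_tab",
    "read_genotype_table",
    "write_genotype_table",
    "write_newick",
    "parse_newick",
    "write_boulder_io",
]

_DNA_ALPHABET = frozenset("ACGTN")

#: Sentinel for an untyped diploid call.
MISSING = None


class FormatError(ValueError):
    """A structural violation in an input file (readers reject, never repair)."""


@dataclass
class ContigRecord:
    """A DNA sequence with provenance and read-mapping metadata.

    ``mean_coverage`` (read depth, x) and ``multimap_fraction`` (share of
    assigned reads that also map elsewhere) are filled in by the coverage
    estimator and consumed by filter criteria 3 and 4.
    """

    id: str
    seq: str
    source: str = "denovo"  # "denovo" | "merged"
    mean_coverage: float | None = None
    multimap_fraction: float | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = set(self.seq) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.id!r}: non-IUPAC-DNA characters {sorted(bad)}"
            )
        if self.source not in ("denovo", "merged"):
            raise ValueError(f"contig {self.id!r}: unknown source {self.source!r}")
        if self.mean_coverage is not None and self.mean_coverage < 0:
            raise ValueError("mean_coverage must be non-negative")
        if self.multimap_fraction is not None and not 0 <= self.multimap_fraction <= 1:
            raise ValueError("multimap_fraction must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadPair:
    """A paired-end read with Phred+33 quality strings."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        for i, (s, q) in enumerate(((self.seq1, self.qual1), (self.seq2, self.qual2)), 1):
            if not s:
                raise ValueError(f"read pair {self.id!r}: read {i} is empty")
            if len(s) != len(q):
                raise FormatError(
                    f"read pair {self.id!r}: read {i} sequence/quality length mismatch"
                )


@dataclass
class RepeatAnnotation:
    """RepeatMasker intervals (1-based inclusive) on one contig."""

    contig_id: str
    intervals: list[tuple[int, int]] = field(default_factory=list)
    repeat_class: str = ""

    def overlaps(self, start: int, end: int) -> bool:
        return any(s <= end and start <= e for s, e in self.intervals)


@dataclass
class BlastHit:
    """One row of BLAST tabular output (outfmt 6).

    Query coordinates are normalized so ``q_start <= q_end``; a hit whose
    subject coordinates were reversed on input (minus strand) carries
    ``minus_strand=True``.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    minus_strand: bool = False


class GenotypeMatrix:
    """Diploid allele-size calls: individuals x loci, with missing data.

    Each cell is an unordered pair of positive integer allele sizes (bp),
    stored as a sorted tuple, or ``MISSING`` (None).  Individuals may carry
    an optional population label.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        loci: Sequence[str],
        calls: dict[tuple[str, str], tuple[int, int] | None],
        populations: Sequence[str] | None = None,
    ) -> None:
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate individual labels")
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus labels")
        self.individuals = list(individuals)
        self.loci = list(loci)
        self.populations = list(populations) if populations is not None else None
        if self.populations is not None and len(self.populations) != len(self.individuals):
            raise ValueError("populations length must match individuals")
        self._calls: dict[tuple[str, str], tuple[int, int] | None] = {}
        for ind in self.individuals:
            for loc in self.loci:
                call = calls.get((ind, loc))
                if call is not None:
                    a, b = call
                    if a <= 0 or b <= 0:
                        raise ValueError(f"non-positive allele size for {ind}/{loc}")
                    call = (min(a, b), max(a, b))
                self._calls[(ind, loc)] = call

    def call(self, individual: str, locus: str) -> tuple[int, int] | None:
        return self._calls[(individual, locus)]

    def typed_individuals(self, locus: str) -> list[str]:
        return [i for i in self.individuals if self._calls[(i, locus)] is not None]

    def population_of(self, individual: str) -> str | None:
        if self.populations is None:
            return None
        return self.populations[self.individuals.index(individual)]

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeMatrix":
        calls = {
            (i, l): self._calls[(i, l)] for i in self.individuals for l in loci
        }
        return GenotypeMatrix(self.individuals, loci, calls, self.populations)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path, source: str = "denovo") -> list[ContigRecord]:
    """Read a FASTA file into :class:`ContigRecord` objects, order preserved.

    Lowercase sequence is uppercased; duplicate ids are a format error.
    """
    path = Path(path)
    records: list[ContigRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises plain ValueError on bad syntax
        raise FormatError(f"{path}: not valid FASTA: {exc}") from exc
    if not parsed:
        raise FormatError(f"{path}: empty FASTA file")
    for rec in parsed:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(ContigRecord(id=rec.id, seq=str(rec.seq).upper(), source=source))
    return records


def write_fasta(records: Iterable[ContigRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")


_PAIR_SUFFIX = re.compile(r"[/ ]?[12]$")


def _strip_mate_suffix(read_id: str) -> str:
    return _PAIR_SUFFIX.sub("", read_id)


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Yield mated read pairs from two FASTQ files in file order.

    Record counts must match and ids must agree after stripping a trailing
    ``/1`` / ``/2`` mate suffix.
    """
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    k = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        k += 1
        if r1 is None or r2 is None:
            raise FormatError(
                f"{path1} / {path2}: unequal record counts (mismatch at record {k})"
            )
        id1, id2 = _strip_mate_suffix(r1.id), _strip_mate_suffix(r2.id)
        if id1 != id2:
            raise FormatError(
                f"read id mismatch at record {k}: {r1.id!r} vs {r2.id!r}"
            )
        yield ReadPair(
            id=id1,
            seq1=str(r1.seq).upper(),
            qual1="".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"]),
            seq2=str(r2.seq).upper(),
            qual2="".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"]),
        )


# ---------------------------------------------------------------------------
# RepeatMasker / BLAST


def parse_repeatmasker_out(path: str | Path) -> dict[str, RepeatAnnotation]:
    """Parse a RepeatMasker ``.out`` file into per-contig annotations.

    The standard layout has 3 header lines followed by whitespace-separated
    alignment rows; query begin/end (columns 6-7) are 1-based inclusive.
    Rows for the same contig are grouped into one annotation.
    """
    path = Path(path)
    annotations: dict[str, RepeatAnnotation] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, 1):
        fields = line.split()
        if not fields:
            continue
        # header lines start with "SW"/"score" or are the blank separator
        if fields[0] in ("SW", "score") or not fields[0][0].isdigit():
            if lineno <= 3:
                continue
        if len(fields) < 11:
            raise FormatError(f"{path}:{lineno}: too few columns for a RepeatMasker row")
        query = fields[4]
        try:
            start, end = int(fields[5]), int(fields[6])
        except ValueError as exc:
            raise FormatError(
                f"{path}:{lineno}: non-numeric query coordinates {fields[5]!r}/{fields[6]!r}"
            ) from exc
        if not 1 <= start <= end:
            raise FormatError(f"{path}:{lineno}: invalid interval ({start}, {end})")
        repeat_class = fields[10]
        ann = annotations.setdefault(query, RepeatAnnotation(query, [], repeat_class))
        ann.intervals.append((start, end))
    return annotations


def parse_blast_tab(path: str | Path) -> dict[str, list[BlastHit]]:
    """Parse 12-column BLAST tabular output, grouped per query.

    Minus-strand hits (subject start > end) are retained with normalized
    coordinates and ``minus_strand`` set.
    """
    path = Path(path)
    hits: dict[str, list[BlastHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                (qid, sid, ident, alen, _mism, _gaps,
                 qs, qe, ss, se, ev, bits) = fields
                ident_f = float(ident)
                alen_i = int(alen)
                qs_i, qe_i, ss_i, se_i = int(qs), int(qe), int(ss), int(se)
                ev_f, bits_f = float(ev), float(bits)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed numeric field") from exc
            minus = ss_i > se_i
            if qs_i > qe_i:
                qs_i, qe_i = qe_i, qs_i
                minus = not minus
            hit = BlastHit(
                query_id=qid, subject_id=sid, pct_identity=ident_f,
                align_len=alen_i, q_start=qs_i, q_end=qe_i,
                s_start=min(ss_i, se_i), s_end=max(ss_i, se_i),
                evalue=ev_f, bit_score=bits_f, minus_strand=minus,
            )
            hits.setdefault(qid, []).append(hit)
    return hits


# ---------------------------------------------------------------------------
# Genotype table


def read_genotype_table(path: str | Path, sep: str = ",") -> GenotypeMatrix:
    """Read a diploid genotype table (two allele-size columns per locus).

    Header: ``id,pop,<locus>.1,<locus>.2,...``; allele sizes are positive
    integers, missing coded as ``0`` or blank.  A cell with exactly one
    missing allele is coerced to fully missing with a warning, because the
    diploid statistics downstream assume complete calls.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cols = header.split(sep)
        if len(cols) < 4 or cols[0] != "id" or cols[1] != "pop":
            raise FormatError(f"{path}: header must start with 'id{sep}pop' and list loci")
        allele_cols = cols[2:]
        if len(allele_cols) % 2 != 0:
            raise FormatError(f"{path}: odd number of allele columns")
        loci: list[str] = []
        for i in range(0, len(allele_cols), 2):
            a, b = allele_cols[i], allele_cols[i + 1]
            base_a = a.rsplit(".", 1)[0]
            base_b = b.rsplit(".", 1)[0]
            if base_a != base_b:
                raise FormatError(f"{path}: allele columns {a!r}/{b!r} name different loci")
            loci.append(base_a)
        individuals: list[str] = []
        populations: list[str] = []
        calls: dict[tuple[str, str], tuple[int, int] | None] = {}
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(sep)
            if len(fields) != len(cols):
                raise FormatError(f"{path}:{lineno}: wrong number of fields")
            ind, pop = fields[0], fields[1]
            individuals.append(ind)
            populations.append(pop)
            for j, locus in enumerate(loci):
                tok_a, tok_b = fields[2 + 2 * j].strip(), fields[3 + 2 * j].strip()
                alleles = []
                for tok in (tok_a, tok_b):
                    if tok in ("", "0"):
                        alleles.append(None)
                    else:
                        try:
                            val = int(tok)
                        except ValueError as exc:
                            raise FormatError(
                                f"{path}:{lineno}: non-integer allele token {tok!r}"
                            ) from exc
                        if val <= 0:
                            raise FormatError(
                                f"{path}:{lineno}: non-positive allele size {val}"
                            )
                        alleles.append(val)
                if alleles[0] is None and alleles[1] is None:
                    calls[(ind, locus)] = MISSING
                elif None in alleles:
                    warnings.warn(
                        f"{path}:{lineno}: half-missing call at locus {locus!r} "
                        f"for {ind!r} coerced to missing",
                        stacklevel=2,
                    )
                    calls[(ind, locus)] = MISSING
                else:
                    calls[(ind, locus)] = (alleles[0], alleles[1])
    return GenotypeMatrix(individuals, loci, calls, populations)


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path, sep: str = ",") -> None:
    with open(path, "w") as fh:
        header = ["id", "pop"]
        for loc in matrix.loci:
            header += [f"{loc}.1", f"{loc}.2"]
        fh.write(sep.join(header) + "\n")
        for idx, ind in enumerate(matrix.individuals):
            pop = matrix.populations[idx] if matrix.populations else "NA"
            row = [ind, pop]
            for loc in matrix.loci:
                call = matrix.call(ind, loc)
                row += ["0", "0"] if call is None else [str(call[0]), str(call[1])]
            fh.write(sep.join(row) + "\n")


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick, bootstrap supports as internal node labels.

    Every leaf must be labelled; the output round-trips through
    :func:`parse_newick`.
    """
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("unlabeled leaf in tree")
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"


def parse_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


# ---------------------------------------------------------------------------
# Primer3 Boulder-IO


def write_boulder_io(
    candidates: Iterable[tuple[str, str, int, int]],
    product_size_range: tuple[int, int] = (100, 300),
) -> str:
    """Emit Primer3 Boulder-IO records, one primer pair requested per locus.

    ``candidates`` yields ``(id, template, ssr_start, ssr_end)`` with 1-based
    inclusive SSR coordinates on the template; the target is written as
    ``<start>,<length>``.
    """
    out: list[str] = []
    for cid, template, start, end in candidates:
        if not 1 <= start <= end <= len(template):
            raise ValueError(
                f"candidate {cid!r}: SSR interval ({start}, {end}) outside template"
            )
        out.append(f"SEQUENCE_ID={cid}")
        out.append(f"SEQUENCE_TEMPLATE={template}")
        out.append(f"SEQUENCE_TARGET={start},{end - start + 1}")
        out.append("PRIMER_NUM_RETURN=1")
        out.append(
            f"PRIMER_PRODUCT_SIZE_RANGE={product_size_range[0]}-{product_size_range[1]}"
        )
        out.append("=")
    return "\n".join(out) + ("\n" if out else "")
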