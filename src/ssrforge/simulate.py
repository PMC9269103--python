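"""Synthetic inputs with known truth for every pipeline stage.

Three generators: repetitive contigs with planted perfect SSRs (plus an
optional interspersed-repeat library for repeat-overlap fixtures),
paired-end reads sampled from fragments, and multi-population diploid
genotypes drawn under Hardy-Weinberg proportions from stated allele
frequencies, optionally with null alleles (one hidden allele per locus:
null homozygotes drop out as missing, null heterozygotes look homozygous)
and missing data.  A fixed seed makes every output byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ContigRecord, GenotypeMatrix, ReadPair
from .merge import revcomp
from .mining import MiningParams, find_ssrs

__all__ = [
    "PlantedSSR",
    "PopulationSpec",
    "SimulationSpec",
    "simulate_contigs",
    "simulate_read_pairs",
    "simulate_genotypes",
]

_BASES = np.array(list("ACGT"))


@dataclass
class PlantedSSR:
    """A perfect repeat to plant: motif x repeats on one contig.

    ``detectable`` marks whether the run meets the miner's thresholds;
    the generator does not second-guess the flag but the truth table
    carries it for recall/precision accounting.
    """

    contig_index: int
    motif: str
    repeats: int
    start: int | None = None  # 1-based; None = random placement
    detectable: bool = True


@dataclass
class PopulationSpec:
    """One population: sample size and per-locus allele-frequency vectors
    (allele size in bp -> frequency, summing to 1 per locus)."""

    name: str
    n_individuals: int
    allele_freqs: dict[str, dict[int, float]]


@dataclass
class SimulationSpec:
    """Study-condition bundle for the three generators.

    Defaults mirror the desk-scale shapes the pipeline is exercised on:
    short Illumina-like reads (100 nt) from small fragments, ~10x target
    coverage, and population samples of 10-20 diploid individuals.
    """

    seed: int
    # contigs
    n_contigs: int = 10
    contig_length: int | tuple[int, int] = 1000
    gc_target: float | None = None
    planted_ssrs: list[PlantedSSR] = field(default_factory=list)
    planted_repeats: list[tuple[int, str, int]] = field(default_factory=list)
    # reads
    read_length: int = 100
    fragment_length: int | tuple[int, int] = 150
    error_rate: float = 0.0
    coverage: float = 10.0
    # genotypes
    populations: list[PopulationSpec] = field(default_factory=list)
    null_allele_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for rate in (self.error_rate, self.null_allele_rate, self.missing_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


def _draw_length(rng: np.random.Generator, spec_len: int | tuple[int, int]) -> int:
    if isinstance(spec_len, tuple):
        return int(rng.integers(spec_len[0], spec_len[1] + 1))
    return int(spec_len)


def _random_seq(rng: np.random.Generator, n: int, gc: float | None) -> np.ndarray:
    if gc is None:
        return rng.choice(_BASES, size=n)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def simulate_contigs(spec: SimulationSpec) -> tuple[list[ContigRecord], pd.DataFrame]:
    """Contigs with planted SSRs plus an exact truth table.

    Background sequence is i.i.d. over {A,C,G,T} (GC-biased when
    ``gc_target`` is set).  Planted runs are boundary-fixed so they are
    exactly maximal, and any accidental background run that the miner
    would report is disrupted, so miner recall and precision against the
    truth table are exact by construction.
    """
    rng = np.random.default_rng(spec.seed)
    seqs: list[np.ndarray] = []
    for _ in range(spec.n_contigs):
        seqs.append(_random_seq(rng, _draw_length(rng, spec.contig_length), spec.gc_target))

    truth_rows = []
    planted_intervals: dict[int, list[tuple[int, int]]] = {}
    for planted in spec.planted_ssrs:
        seq = seqs[planted.contig_index]
        run = planted.motif * planted.repeats
        if len(run) + 2 > len(seq):
            raise ValueError("planted SSR longer than contig")
        if planted.start is None:
            start0 = int(rng.integers(1, len(seq) - len(run) - 1))
        else:
            start0 = planted.start - 1
            if start0 < 1 or start0 + len(run) >= len(seq):
                raise ValueError("planted SSR must leave at least 1 nt on each side")
        seq[start0 : start0 + len(run)] = list(run)
        # boundary-fix so the run is exactly maximal on both sides
        if seq[start0 - 1] == run[-1]:
            seq[start0 - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[run[-1]]
        after = start0 + len(run)
        if seq[after] == planted.motif[0]:
            seq[after] = {"A": "C", "C": "A", "G": "T", "T": "G"}[planted.motif[0]]
        planted_intervals.setdefault(planted.contig_index, []).append(
            (start0 + 1, start0 + len(run))
        )
        truth_rows.append(
            dict(
                contig=f"sim{planted.contig_index}",
                start=start0 + 1,
                end=start0 + len(run),
                motif=planted.motif,
                repeats=planted.repeats,
                detectable=planted.detectable,
            )
        )
    for contig_index, repeat_seq, start in spec.planted_repeats:
        seq = seqs[contig_index]
        start0 = start - 1
        if start0 + len(repeat_seq) > len(seq):
            raise ValueError("planted repeat element outside contig")
        seq[start0 : start0 + len(repeat_seq)] = list(repeat_seq)
        planted_intervals.setdefault(contig_index, []).append(
            (start, start + len(repeat_seq) - 1)
        )

    # disrupt accidental background runs the miner would otherwise report
    params = MiningParams()
    for ci, seq in enumerate(seqs):
        wanted = planted_intervals.get(ci, [])
        for _ in range(20):
            contig = ContigRecord(id=f"sim{ci}", seq="".join(seq))
            spurious = [
                l
                for l in find_ssrs(contig, params)
                if not any(s <= l.start and l.end <= e for s, e in wanted)
            ]
            if not spurious:
                break
            for locus in spurious:
                mid = (locus.start + locus.end) // 2 - 1
                current = seq[mid]
                seq[mid] = rng.choice([b for b in "ACGT" if b != current])

    contigs = [
        ContigRecord(id=f"sim{ci}", seq="".join(seq)) for ci, seq in enumerate(seqs)
    ]
    truth = pd.DataFrame(
        truth_rows, columns=["contig", "start", "end", "motif", "repeats", "detectable"]
    )
    return contigs, truth


def simulate_read_pairs(
    contigs: list[ContigRecord], spec: SimulationSpec
) -> tuple[list[ReadPair], pd.DataFrame]:
    """FR read pairs from uniformly drawn fragments, with truth coordinates.

    Read 1 is the fragment's 5' end, read 2 the reverse complement of its
    3' end; substitution errors land i.i.d. at ``error_rate`` and quality
    strings are constant at the Phred value that rate implies.  The number
    of pairs is set by the target ``coverage``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    rl = spec.read_length
    total_len = sum(len(c) for c in contigs)
    n_pairs = max(1, round(spec.coverage * total_len / (2 * rl)))
    weights = np.array([len(c) for c in contigs], dtype=float) / total_len
    q_char = (
        "I"
        if spec.error_rate == 0
        else chr(33 + min(40, max(2, round(-10 * np.log10(spec.error_rate)))))
    )

    pairs: list[ReadPair] = []
    rows = []
    for k in range(n_pairs):
        frag_len = _draw_length(rng, spec.fragment_length)
        if rl > frag_len:
            raise ValueError("read length exceeds fragment length")
        ci = int(rng.choice(len(contigs), p=weights))
        contig = contigs[ci]
        if frag_len > len(contig):
            frag_len = len(contig)
        start0 = int(rng.integers(0, len(contig) - frag_len + 1))
        frag = contig.seq[start0 : start0 + frag_len]
        r1, r2 = frag[:rl], revcomp(frag[-rl:])

        def _with_errors(read: str) -> str:
            if spec.error_rate == 0:
                return read
            bases = list(read)
            hits = np.nonzero(rng.random(len(bases)) < spec.error_rate)[0]
            for i in hits:
                bases[i] = rng.choice([b for b in "ACGT" if b != bases[i]])
            return "".join(bases)

        pairs.append(
            ReadPair(
                id=f"frag{k}",
                seq1=_with_errors(r1),
                qual1=q_char * rl,
                seq2=_with_errors(r2),
                qual2=q_char * rl,
            )
        )
        rows.append(
            dict(pair=f"frag{k}", contig=contig.id, start=start0 + 1,
                 end=start0 + frag_len, fragment=frag)
        )
    return pairs, pd.DataFrame(rows)


def simulate_genotypes(spec: SimulationSpec) -> tuple[GenotypeMatrix, dict]:
    """Multi-population diploid genotypes under within-population HWE.

    With ``null_allele_rate`` r a hidden null allele segregates at
    frequency r at every locus (visible frequencies rescaled by 1-r);
    null homozygotes become missing and null heterozygotes score as
    visible homozygotes.  Independent missingness is applied on top.
    Returns the matrix plus the true visible allele frequencies.
    """
    if not spec.populations:
        raise ValueError("no populations specified")
    rng = np.random.default_rng(spec.seed + 2)
    loci = list(spec.populations[0].allele_freqs)
    for pop in spec.populations:
        if list(pop.allele_freqs) != loci:
            raise ValueError("all populations must define the same loci")
        for locus, freqs in pop.allele_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{pop.name}/{locus}: frequencies sum to {total}")

    NULL = -1
    individuals: list[str] = []
    populations: list[str] = []
    calls: dict[tuple[str, str], tuple[int, int] | None] = {}
    r = spec.null_allele_rate
    for pop in spec.populations:
        for i in range(pop.n_individuals):
            ind = f"{pop.name}_{i:02d}"
            individuals.append(ind)
            populations.append(pop.name)
            for locus in loci:
                alleles = list(pop.allele_freqs[locus])
                p = np.array([pop.allele_freqs[locus][a] for a in alleles])
                if r > 0:
                    alleles = alleles + [NULL]
                    p = np.concatenate([p * (1 - r), [r]])
                a, b = rng.choice(alleles, size=2, p=p)
                if rng.random() < spec.missing_rate or (a == NULL and b == NULL):
                    calls[(ind, locus)] = None
                elif a == NULL:
                    calls[(ind, locus)] = (int(b), int(b))
                elif b == NULL:
                    calls[(ind, locus)] = (int(a), int(a))
                else:
                    calls[(ind, locus)] = (int(a), int(b))

    matrix = GenotypeMatrix(individuals, loci, calls, populations)
    truth = {
        pop.name: {locus: dict(freqs) for locus, freqs in pop.allele_freqs.items()}
        for pop in spec.populations
    }
    return matrix, truth
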