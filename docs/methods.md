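# Methods

This note records the models, definitions and numerical conventions behind
each stage of the pipeline, the defaults and why they were chosen, what
the synthetic-data generators do and do not emulate, and the known
limitations.

## Read merging and coverage

A standard FR (innie) library is assumed: read 2 is reverse-complemented
and its prefix aligned against the suffix of read 1 at every offset. An
overlap is admissible when it is at least `min_overlap` nt (default 30;
shorter overlaps are too likely to be spurious in a genome that is mostly
repeats) and its mismatch fraction is at most `max_mismatch_rate`
(default 0.1). The longest admissible overlap wins; if the two best
admissible overlaps tie on length the pair is rejected as ambiguous
rather than merged arbitrarily. Inside the overlap the base with the
higher Phred quality is kept, read 1 winning ties, so the merged length
is always `len1 + len2 − overlap`. Deduplication removes exact and exact
reverse-complement duplicates by canonical-strand keying
(`min(seq, revcomp(seq))`), keeping the first occurrence; it is
idempotent.

Coverage is estimated by exact-k-mer pseudo-mapping (default k = 31):
a read is assigned to every contig with which it shares at least one
exact k-mer on either strand, mean coverage is assigned read bases over
contig length, and the multi-mapping fraction of a contig is the share of
its assigned reads that also hit another contig. This deliberately trades
alignment accuracy for defined, fast semantics — the filter cascade only
needs a depth summary and a repetitiveness proxy, and an externally
computed coverage table can be substituted at the CLI.

## SSR mining

A microsatellite is a maximal perfect tandem run of a primitive 2–6 nt
unit, with minimum repeat counts 8/6/5/4/4 for unit sizes 2–6 and
mononucleotide runs excluded. The scanner proceeds left to right, trying
unit sizes in increasing order at each position, so every run is reported
exactly once, under its smallest true unit (ACACACAC is an (AC)₄-type
run, never (ACAC)₂) and in its leftmost phase; a trailing partial unit is
excluded (repeat counts floor at complete units) and runs containing N
are not reported.

Motifs are classed by the orbit of cyclic rotation and reverse
complementation: the label is `X/Y` with X the lexicographically smallest
orbit member and Y the smallest rotation of revcomp(X). Exhaustive
enumeration shows exactly 4 dinucleotide and 10 trinucleotide classes,
matching the standard frequency-reporting convention for SSR surveys.

Two loci on one contig separated by at most `max_interrupt` nt (default
100, the conventional compound-repeat window) merge into a compound locus
(chains propagate); compound loci are retained for accounting but
discarded by filter criterion 1, since interrupted repeats score poorly
and their fragment sizes are hard to interpret.

## The filter cascade

Criteria are evaluated in a fixed order, and a failing candidate records
only the first violated criterion, which makes attrition tables
reproducible and independent of input order:

1. compound microsatellite;
2. the SSR overlaps a RepeatMasker interval on its contig;
3. multi-mapping fraction > 0.5;
4. mean coverage outside 0.5×–2.0× the expected sequencing depth
   (default 12.5×) — a symmetric-in-log window that excludes collapsed
   repeats (high) and chimeric joins (low) — or contig shorter than
   131 nt, or either flank shorter than 30 nt (so primers are
   designable);
5. BLAST occurrences in the draft genome not in {1, 2}, counting hits
   with ≥ 90 % identity covering ≥ 80 % of the query and collapsing hits
   with ≥ 50 % reciprocal subject overlap (split alignments count once);
   candidates without BLAST annotation skip this criterion;
6. motif unit length not 2 or 3;
7. GC fraction (N excluded from the denominator) outside 0.43 ± 0.10.

"Preferred" properties that are not hard windows become the ranking key
for primer design: descending repeat count, then GC distance from the
window centre, then contig id — fully deterministic. The coverage window,
flank minimum and BLAST thresholds are judgement calls exposed as
`FilterParams`; the GC window centre (0.43) is likewise a parameter, and
is noticeably higher than typical whole-assembly GC for AT-rich plant
genomes (~0.34), so users calibrating to their own assembly should set it
to their measured value.

## Marker statistics

For each locus with n typed diploid individuals and allele frequencies
p̂ᵢ over the 2n gene copies:

- **Ho** — heterozygous individuals / n.
- **He** — unbiased gene diversity (2n/(2n−1))(1 − Σp̂ᵢ²); the biased
  form is available by flag.
- **F_IS** — the heterozygote-deficit form 1 − Ho/He (undefined and
  reported absent when He = 0). The variance-component (Weir &
  Cockerham) estimator is out of scope.
- **HWE** — the exact probability test: each genotype table with the
  observed allele counts has Levene's conditional probability
  P = n!·2^h·Πₐnₐ! / (Π_g n_g!·(2n)!), and the p-value sums the
  probabilities of all tables no more probable than the observed one.
  Tables are enumerated exhaustively when at most 10⁵ exist; otherwise
  the null is sampled by shuffling gene copies into random pairings
  (default 10⁵ replicates, fixed seed). Probabilities are compared in
  log space with a 10⁻⁹ slack to absorb float noise.
- **Null alleles** — both heterozygote-deficit estimators are reported:
  Chakraborty (He−Ho)/(He+Ho) and Brookfield-1 (He−Ho)/(1+He), negative
  estimates floored at zero. The two bracket most published estimators;
  which one a given legacy program used is often unclear, so neither is
  privileged.
- **PIC** — Botstein's 1 − Σp̂ᵢ² − Σᵢ<ⱼ2p̂ᵢ²p̂ⱼ², with the conventional
  informativeness bands: high > 0.70, moderate (0.44, 0.70], low < 0.29.
- **PI** — Σp̂ᵢ⁴ + Σᵢ<ⱼ(2p̂ᵢp̂ⱼ)²; the panel-level combined PI is the
  exact product of the per-locus values, never re-derived from pooled
  frequencies.

Multiple HWE tests across loci are corrected by the sequential-Bonferroni
(Holm) step-down at α = 0.05, applied to the testable (polymorphic)
subset and mapped back to input order.

Panel aggregation also accepts a pre-computed per-locus table (the layout
of a published characterization table), and one such table — the
17-marker Dalmatian pyrethrum panel scored on 20 individuals — ships with
the package as a fixed reference input. Its F_IS column is reproduced to
printed precision by 1 − Ho/He, which is why that form was adopted.

## Distances and trees

D_PSA between two individuals is 1 − Σ_l shared_l / (2L) over the L loci
typed in both (pairwise-complete normalization, the convention of classic
shared-allele software); shared_l ∈ {0, 1, 2} counts allele matches with
each allele matched at most once, so all values are multiples of 1/(2L).

Neighbor joining is the canonical Saitou–Nei agglomeration on the
Q-criterion, with ties broken by the lexicographically smallest pair of
subtree labels so output is bit-reproducible. Negative branch lengths are
clamped to zero for display with the raw value kept in the edge
annotation `raw_length` (PHYLIP-compatible output). On additive matrices
the tree reproduces all pairwise path lengths to 1e-9, which the tests
exploit as an oracle (plus an exhaustive least-squares topology search at
5–6 taxa).

Bootstrap support resamples loci with replacement (same count, default
1000 replicates, seeded generator), recomputes D_PSA and NJ, and reports
for each internal edge of the full-data tree the percentage of replicates
containing the same bipartition, written as the internal node label; the
majority-rule consensus of the replicates is returned alongside, since
either tree may be the one a user wants to display.

## Synthetic data

The generators define the study conditions the tests run under:

- **Contigs** — i.i.d. background sequence (optionally GC-biased),
  default 10 contigs of 1 kb, with planted perfect repeats whose
  boundaries are fixed so each run is exactly maximal; any accidental
  background run the miner would report is disrupted by a single-base
  change, so miner recall and precision against the truth table are exact
  by construction, not approximately.
- **Reads** — fragments drawn uniformly (length-weighted across contigs),
  default 100 nt reads from 150 nt fragments at 10× target coverage,
  read 2 reverse-complemented; substitution errors i.i.d. at the stated
  rate, quality strings constant at the Phred value that rate implies
  (the merger only consumes relative qualities).
- **Genotypes** — diploid draws under Hardy–Weinberg proportions within
  each population from stated allele-frequency vectors; sample shapes
  mirror the characterization designs used here (20 individuals × 1
  population; 10 × 3 populations × 12 loci). With null-allele rate r one
  hidden allele segregates at frequency r per locus (visible frequencies
  rescaled by 1 − r): null homozygotes drop out as missing, null
  heterozygotes score as visible homozygotes — the same model the
  deficit estimators assume. Independent missingness stacks on top.

The same seed yields byte-identical outputs. What the generators do NOT
emulate: transposon families and other structured repeats (background is
i.i.d., so criterion-2/3 behaviour on real repeat landscapes is only
exercised through explicit planted elements), instrument-specific error
and quality profiles, PCR stutter and large-allele dropout, linkage
between loci, and within-population structure. Passing tests therefore
demonstrate algorithmic correctness under the stated models, not robustness
to every artefact of real fragment-analysis data.

Under this null-allele model the Brookfield-1 estimator recovers r ≈ 0.2
as ~0.15 on average (the dropout of null homozygotes perturbs both Ho and
He relative to the estimator's idealized assumptions); the tests assert
recovery within ±0.07 accordingly.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale by design:
tens of contigs of a few hundred bp, ~100 read pairs per scenario, 5–8
taxa for tree oracles, 200–300 bootstrap replicates, 2·10⁴ Monte-Carlo
HWE replicates when cross-checking enumeration. These sizes are where the
exact oracles (full enumeration, exhaustive topology search, planted
truth) remain computable; all algorithms scale to realistic inputs
linearly in reads/loci and cubically in taxa for NJ.

Degenerate inputs have defined behaviour throughout: monomorphic loci
report He = PIC = 0, PI = 1 and no HWE p-value; He = 0 makes F_IS
absent; half-missing genotype calls are coerced to fully missing with a
warning (the diploid statistics assume complete calls); duplicated
individuals produce zero-length edges with well-defined supports; empty
mining input yields an empty frequency table.

## Scope limitations

De novo assembly (the first contig-generation route of the original
workflow) is out of scope — contigs are accepted as FASTA. RepeatMasker,
BLAST and Primer3 are not executed; their standard outputs are consumed
(.out, outfmt 6) or produced (Boulder-IO). Scoring-error/stutter
diagnostics, Weir & Cockerham F-statistics, FST, UPGMA/ML trees and
population-level (as opposed to individual-level) distances are not
implemented.
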