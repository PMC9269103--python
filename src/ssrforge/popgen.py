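"""Codominant-marker characterization statistics.

Per-locus descriptors for diploid microsatellite data: allele counts and
frequencies, observed and (small-sample-corrected) expected
heterozygosity, the heterozygote-deficit inbreeding coefficient
F_IS = 1 - Ho/He, an exact Hardy-Weinberg test (Levene's conditional
distribution, full enumeration or Monte-Carlo), two null-allele frequency
estimators (Chakraborty; Brookfield-1), polymorphic information content
(Botstein) and the probability of identity, with sequential-Bonferroni
(Holm) correction across loci and panel-level aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import GenotypeMatrix

__all__ = [
    "LocusSummary",
    "PanelSummary",
    "allele_frequencies",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "inbreeding_coefficient",
    "hwe_exact_test",
    "null_allele_frequency",
    "pic",
    "probability_of_identity",
    "combined_pi",
    "holm_correction",
    "genotype_counts",
    "summarize_loci",
    "summarize_panel",
    "summarize_panel_from_table",
]


@dataclass
class LocusSummary:
    """Per-locus characterization row (the marker-table layout)."""

    locus: str
    n_typed: int
    Na: int
    Ho: float
    He: float
    Fis: float | None
    hwe_p: float | None
    hwe_significant: bool
    F_null: dict[str, float]
    PIC: float
    PI: float


@dataclass
class PanelSummary:
    """Aggregates over a marker panel."""

    n_loci: int
    total_alleles: int
    mean_Na: float
    mean_Ho: float
    mean_He: float
    mean_PIC: float
    combined_PI: float
    n_high_PIC: int       # PIC > 0.70
    n_moderate_PIC: int   # 0.44 < PIC <= 0.70
    n_low_PIC: int        # PIC < 0.29


# ---------------------------------------------------------------------------
# Frequencies and heterozygosity


def allele_frequencies(matrix: GenotypeMatrix, locus: str) -> dict[int, float]:
    """Allele frequencies over the 2n gene copies of typed individuals."""
    counts: dict[int, int] = {}
    n_typed = 0
    for ind in matrix.individuals:
        call = matrix.call(ind, locus)
        if call is None:
            continue
        n_typed += 1
        for a in call:
            counts[a] = counts.get(a, 0) + 1
    if n_typed == 0:
        raise ValueError(f"locus {locus!r}: no typed individuals")
    total = 2 * n_typed
    return {a: c / total for a, c in sorted(counts.items())}


def observed_heterozygosity(matrix: GenotypeMatrix, locus: str) -> float:
    """Share of typed individuals carrying two distinct alleles."""
    typed = matrix.typed_individuals(locus)
    if not typed:
        raise ValueError(f"locus {locus!r}: no typed individuals")
    het = sum(1 for ind in typed if len(set(matrix.call(ind, locus))) == 2)
    return het / len(typed)


def expected_heterozygosity(
    freqs: dict[int, float] | np.ndarray, n_typed: int | None = None, unbiased: bool = True
) -> float:
    """Gene diversity 1 - sum(p_i^2), by default with the small-sample
    correction 2n/(2n-1)."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, dtype=float)
    h = 1.0 - float(np.sum(p ** 2))
    if not unbiased:
        return h
    if n_typed is None or n_typed < 2:
        raise ValueError("unbiased expected heterozygosity needs n_typed >= 2")
    return (2 * n_typed) / (2 * n_typed - 1) * h


def inbreeding_coefficient(Ho: float, He: float) -> float | None:
    """Heterozygote-deficit form F_IS = 1 - Ho/He; None when He = 0."""
    if He < 0:
        raise ValueError("He must be non-negative")
    if He == 0:
        return None
    return 1.0 - Ho / He


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Levene's conditional distribution)


def genotype_counts(matrix: GenotypeMatrix, locus: str) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for ind in matrix.typed_individuals(locus):
        counts[matrix.call(ind, locus)] = counts.get(matrix.call(ind, locus), 0) + 1
    return counts


def _log_table_prob(table: dict[tuple[int, int], int], allele_counts: dict[int, int]) -> float:
    """log P(table | allele counts) by Levene's formula:
    P = n! 2^h prod_a(n_a!) / (prod_g(n_g!) (2n)!)."""
    n = sum(table.values())
    h = sum(c for (a, b), c in table.items() if a != b)
    lp = math.lgamma(n + 1) + h * math.log(2.0)
    lp += sum(math.lgamma(c + 1) for c in allele_counts.values())
    lp -= sum(math.lgamma(c + 1) for c in table.values())
    lp -= math.lgamma(2 * n + 1)
    return lp


def _enumerate_tables(allele_counts: dict[int, int], cap: int):
    """Yield every diploid genotype table consistent with the allele counts,
    or None first if more than ``cap`` tables exist."""
    alleles = sorted(allele_counts)
    k = len(alleles)
    produced = 0

    def rec(i: int, remaining: list[int], table: dict):
        nonlocal produced
        if i == k - 1:
            c = remaining[k - 1]
            if c % 2 == 0:
                t = dict(table)
                if c:
                    t[(alleles[k - 1], alleles[k - 1])] = c // 2
                produced += 1
                if produced > cap:
                    raise _CapExceeded
                yield t
            return
        c = remaining[i]
        later = list(range(i + 1, k))
        for g_ii in range(c // 2, -1, -1):
            rem = c - 2 * g_ii
            # distribute rem heterozygous copies of allele i among alleles i+1..k
            def distribute(j_idx: int, left: int, het: dict):
                if j_idx == len(later):
                    if left == 0:
                        t = dict(table)
                        if g_ii:
                            t[(alleles[i], alleles[i])] = g_ii
                        new_remaining = list(remaining)
                        new_remaining[i] = 0
                        for jj, cnt in het.items():
                            t[(alleles[i], alleles[jj])] = cnt
                            new_remaining[jj] -= cnt
                        yield from rec(i + 1, new_remaining, t)
                    return
                j = later[j_idx]
                for g_ij in range(min(left, remaining[j]), -1, -1):
                    if g_ij:
                        het[j] = g_ij
                    yield from distribute(j_idx + 1, left - g_ij, het)
                    het.pop(j, None)

            yield from distribute(0, rem, {})

    class _CapExceeded(Exception):
        pass

    try:
        yield from rec(0, [allele_counts[a] for a in alleles], {})
    except _CapExceeded:
        yield None


def hwe_exact_test(
    observed: dict[tuple[int, int], int],
    method: str = "auto",
    mc_reps: int = 100_000,
    seed: int = 0,
    max_tables: int = 100_000,
) -> float | None:
    """Exact Hardy-Weinberg probability test at one locus.

    The p-value is the total conditional probability (Levene) of all
    genotype tables with the observed allele counts that are no more
    probable than the observed table.  Tables are fully enumerated when
    their number is at most ``max_tables``; otherwise (or with
    ``method="mc"``) the null is sampled by shuffling gene copies into
    random diploid pairings, ``mc_reps`` times with a fixed seed.

    Returns None for a monomorphic locus.
    """
    if method not in ("auto", "enum", "mc"):
        raise ValueError(f"unknown method {method!r}")
    allele_counts: dict[int, int] = {}
    for (a, b), c in observed.items():
        allele_counts[a] = allele_counts.get(a, 0) + c
        allele_counts[b] = allele_counts.get(b, 0) + c
    if len(allele_counts) < 2:
        return None
    obs_norm = {tuple(sorted(g)): c for g, c in observed.items() if c}
    lp_obs = _log_table_prob(obs_norm, allele_counts)
    tol = 1e-9  # float slack when comparing table probabilities

    if method in ("auto", "enum"):
        tables = list(_enumerate_tables(allele_counts, cap=max_tables))
        if None not in tables:
            p = 0.0
            for t in tables:
                lp = _log_table_prob(t, allele_counts)
                if lp <= lp_obs + tol:
                    p += math.exp(lp)
            return min(p, 1.0)
        if method == "enum":
            raise ValueError(f"more than {max_tables} tables; use method='mc'")

    rng = np.random.default_rng(seed)
    copies = np.repeat(
        list(allele_counts.keys()), list(allele_counts.values())
    )
    hits = 0
    for _ in range(mc_reps):
        rng.shuffle(copies)
        pairs = copies.reshape(-1, 2)
        table: dict[tuple[int, int], int] = {}
        for a, b in pairs:
            g = (a, b) if a <= b else (b, a)
            table[g] = table.get(g, 0) + 1
        if _log_table_prob(table, allele_counts) <= lp_obs + tol:
            hits += 1
    return hits / mc_reps


# ---------------------------------------------------------------------------
# Null alleles, PIC, PI


def null_allele_frequency(Ho: float, He: float, estimator: str = "chakraborty") -> float:
    """Null-allele frequency from the heterozygote deficit.

    ``chakraborty``: (He - Ho) / (He + Ho); ``brookfield1``:
    (He - Ho) / (1 + He).  Negative estimates are floored at zero.
    """
    if He + Ho <= 0:
        raise ValueError("He + Ho must be positive")
    if estimator == "chakraborty":
        est = (He - Ho) / (He + Ho)
    elif estimator == "brookfield1":
        est = (He - Ho) / (1.0 + He)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return max(est, 0.0)


def pic(freqs: dict[int, float] | np.ndarray) -> float:
    """Polymorphic information content (Botstein):
    1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, dtype=float)
    s2 = np.sum(p ** 2)
    s4 = np.sum(p ** 4)
    cross = (s2 ** 2 - s4)  # = sum_{i != j} p_i^2 p_j^2 = 2 sum_{i<j}
    return float(1.0 - s2 - cross)


def probability_of_identity(freqs: dict[int, float] | np.ndarray) -> float:
    """Chance two random individuals share a genotype:
    sum p_i^4 + sum_{i<j} (2 p_i p_j)^2."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, dtype=float)
    s2 = np.sum(p ** 2)
    s4 = np.sum(p ** 4)
    return float(s4 + 2.0 * (s2 ** 2 - s4))


def combined_pi(pi_values: list[float]) -> float:
    """Product of per-locus identity probabilities across a panel."""
    if not pi_values:
        raise ValueError("empty locus list")
    return float(np.prod(pi_values))


def holm_correction(p_values: list[float], alpha: float = 0.05) -> list[bool]:
    """Sequential-Bonferroni (Holm step-down) rejection flags, input order."""
    if not p_values:
        return []
    if any(not 0 <= p <= 1 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p_values, alpha=alpha, method="holm")
    return [bool(r) for r in reject]


# ---------------------------------------------------------------------------
# Summaries


def summarize_loci(
    matrix: GenotypeMatrix,
    alpha: float = 0.05,
    seed: int = 0,
    mc_reps: int = 100_000,
) -> list[LocusSummary]:
    """Full characterization of every locus, with Holm-corrected HWE flags."""
    rows: list[dict] = []
    for locus in matrix.loci:
        freqs = allele_frequencies(matrix, locus)
        n_typed = len(matrix.typed_individuals(locus))
        Ho = observed_heterozygosity(matrix, locus)
        He = expected_heterozygosity(freqs, n_typed)
        p = hwe_exact_test(genotype_counts(matrix, locus), seed=seed, mc_reps=mc_reps)
        f_null = (
            {
                "chakraborty": null_allele_frequency(Ho, He, "chakraborty"),
                "brookfield1": null_allele_frequency(Ho, He, "brookfield1"),
            }
            if He + Ho > 0
            else {"chakraborty": 0.0, "brookfield1": 0.0}
        )
        rows.append(
            dict(
                locus=locus,
                n_typed=n_typed,
                Na=len(freqs),
                Ho=Ho,
                He=He,
                Fis=inbreeding_coefficient(Ho, He),
                hwe_p=p,
                F_null=f_null,
                PIC=pic(freqs),
                PI=probability_of_identity(freqs),
            )
        )
    testable = [i for i, r in enumerate(rows) if r["hwe_p"] is not None]
    flags = holm_correction([rows[i]["hwe_p"] for i in testable], alpha) if testable else []
    significant = {i: f for i, f in zip(testable, flags)}
    return [
        LocusSummary(hwe_significant=significant.get(i, False), **row)
        for i, row in enumerate(rows)
    ]


def _classify_pic(values: list[float]) -> tuple[int, int, int]:
    high = sum(1 for v in values if v > 0.70)
    moderate = sum(1 for v in values if 0.44 < v <= 0.70)
    low = sum(1 for v in values if v < 0.29)
    return high, moderate, low


def summarize_panel(summaries: list[LocusSummary]) -> PanelSummary:
    """Panel aggregates; combined PI is the exact product of the inputs."""
    if not summaries:
        raise ValueError("empty panel")
    na = [s.Na for s in summaries]
    pic_vals = [s.PIC for s in summaries]
    high, moderate, low = _classify_pic(pic_vals)
    return PanelSummary(
        n_loci=len(summaries),
        total_alleles=sum(na),
        mean_Na=round(sum(na) / len(na), 3),
        mean_Ho=round(float(np.mean([s.Ho for s in summaries])), 3),
        mean_He=round(float(np.mean([s.He for s in summaries])), 3),
        mean_PIC=round(float(np.mean(pic_vals)), 3),
        combined_PI=combined_pi([s.PI for s in summaries]),
        n_high_PIC=high,
        n_moderate_PIC=moderate,
        n_low_PIC=low,
    )


def summarize_panel_from_table(table: pd.DataFrame) -> PanelSummary:
    """Panel aggregates from a pre-computed per-locus characterization
    table with columns locus, Na, Ho, He, PIC, PI (extra columns ignored)."""
    required = {"locus", "Na", "Ho", "He", "PIC", "PI"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"characterization table missing columns {sorted(missing)}")
    pic_vals = table["PIC"].tolist()
    high, moderate, low = _classify_pic(pic_vals)
    return PanelSummary(
        n_loci=len(table),
        total_alleles=int(table["Na"].sum()),
        mean_Na=round(float(table["Na"].mean()), 3),
        mean_Ho=round(float(table["Ho"].mean()), 3),
        mean_He=round(float(table["He"].mean()), 3),
        mean_PIC=round(float(table["PIC"].mean()), 3),
        combined_PI=combined_pi(table["PI"].tolist()),
        n_high_PIC=high,
        n_moderate_PIC=moderate,
        n_low_PIC=low,
    )
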