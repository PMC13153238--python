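"""Per-locus diversity statistics and Hardy-Weinberg testing.

Implements the classical single-locus summary for a biallelic SNP in a
cohort of n diploids with genotype counts (n0, n1, n2):

* allele frequencies         p = (2 n0 + n1) / 2n,  q = 1 - p
* observed heterozygosity    Ho = n1 / n
* expected heterozygosity    He = 1 - sum(p_i^2)        (no n/(n-1) correction)
* Wright's fixation index    FIS = (He - Ho) / He
* polymorphic information    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2
* HWE chi-square             chi2 = sum (O - E)^2 / E over the three genotype
  classes with E = n(p^2, 2pq, q^2), df = 1, upper-tail p-value.

``pic`` has a ``printed_compat`` mode that rounds allele frequencies to three
decimals before evaluating the formula; this mirrors how PIC is commonly
reported from frequencies that were themselves rounded for publication, and
is needed to match such tables digit-for-digit (He, by contrast, matches the
exact frequencies).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotypes import GenotypeMatrix, Variant

logger = logging.getLogger(__name__)

Counts = tuple[int, int, int]


@dataclass
class LocusSummary:
    """All per-locus diversity statistics for one biallelic SNP."""

    variant: Variant
    genotype_counts: Counts
    genotype_freqs: tuple[float, float, float]
    p_ref: float
    p_alt: float
    Ho: float
    He: float
    Fis: float  # NaN when He == 0 (monomorphic)
    PIC: float
    chi2: float
    df: int
    p_value: float
    monomorphic: bool = False


def _total(counts: Counts) -> int:
    n0, n1, n2 = counts
    if min(counts) < 0:
        raise ValueError("negative genotype count")
    total = n0 + n1 + n2
    if total == 0:
        raise ValueError("undefined locus: zero non-missing genotypes")
    return total


def allele_frequencies(counts: Counts) -> tuple[float, float]:
    """(p_ref, p_alt) from genotype counts; allele counting over 2n gametes."""
    total = _total(counts)
    p_ref = (2 * counts[0] + counts[1]) / (2 * total)
    return p_ref, 1.0 - p_ref


def observed_heterozygosity(counts: Counts) -> float:
    return counts[1] / _total(counts)


def expected_heterozygosity(p_ref: float, p_alt: float) -> float:
    return 1.0 - (p_ref ** 2 + p_alt ** 2)


def fixation_index(Ho: float, He: float) -> float:
    """FIS = (He - Ho)/He; NaN (undefined) for monomorphic loci."""
    if He == 0.0:
        return math.nan
    return (He - Ho) / He


def pic(p_ref: float, p_alt: float, rounding_mode: str = "exact") -> float:
    """Polymorphic information content of a biallelic marker.

    ``rounding_mode='printed_compat'`` rounds the frequencies to 3 decimals
    first, reproducing PIC values computed from published (rounded)
    frequencies.
    """
    if rounding_mode == "printed_compat":
        p_ref, p_alt = round(p_ref, 3), round(p_alt, 3)
    elif rounding_mode != "exact":
        raise ValueError(f"unknown rounding mode {rounding_mode!r}")
    p2, q2 = p_ref ** 2, p_alt ** 2
    return 1.0 - (p2 + q2) - 2.0 * p2 * q2


def hwe_chisq(counts: Counts) -> tuple[float, int, float]:
    """HWE goodness-of-fit chi-square over the three genotype classes.

    No continuity correction; all three classes are kept even when an
    expected count is < 1 (a warning is logged when any E < 5).  Monomorphic
    loci return (0, 1, 1) by convention.
    """
    total = _total(counts)
    p, q = allele_frequencies(counts)
    if p == 0.0 or q == 0.0:
        return 0.0, 1, 1.0
    expected = np.array([total * p * p, 2 * total * p * q, total * q * q])
    if (expected < 5).any():
        logger.warning("HWE chi-square with expected count < 5: %s", expected)
    observed = np.asarray(counts, dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, 1, float(stats.chi2.sf(chi2, df=1))


def summarize_locus(variant: Variant, counts: Counts,
                    rounding_mode: str = "exact") -> LocusSummary:
    total = _total(counts)
    p_ref, p_alt = allele_frequencies(counts)
    Ho = observed_heterozygosity(counts)
    He = expected_heterozygosity(p_ref, p_alt)
    chi2, df, p_value = hwe_chisq(counts)
    return LocusSummary(
        variant=variant,
        genotype_counts=counts,
        genotype_freqs=tuple(c / total for c in counts),
        p_ref=p_ref, p_alt=p_alt,
        Ho=Ho, He=He,
        Fis=fixation_index(Ho, He),
        PIC=pic(p_ref, p_alt, rounding_mode),
        chi2=chi2, df=df, p_value=p_value,
        monomorphic=(He == 0.0),
    )


def summarize_loci(g: GenotypeMatrix, rounding_mode: str = "exact") -> list[LocusSummary]:
    """One :class:`LocusSummary` per locus of the matrix."""
    if g.n_individuals == 0 or g.n_loci == 0:
        raise ValueError("empty genotype matrix")
    return [summarize_locus(v, g.genotype_counts(j), rounding_mode)
            for j, v in enumerate(g.variants)]


def loci_table(summaries: list[LocusSummary]) -> "pd.DataFrame":
    """Tabulate summaries with the standard diversity-table column names."""
    import pandas as pd

    return pd.DataFrame([{
        "rsid": s.variant.rsid,
        "cdna_label": s.variant.cdna_label,
        "n_hom_ref": s.genotype_counts[0],
        "n_het": s.genotype_counts[1],
        "n_hom_alt": s.genotype_counts[2],
        "p_ref": s.p_ref,
        "p_alt": s.p_alt,
        "Ho": s.Ho,
        "He": s.He,
        "FIS": s.Fis,
        "PIC": s.PIC,
        "chi2": s.chi2,
        "df": s.df,
        "p_value": s.p_value,
        "monomorphic": s.monomorphic,
    } for s in summaries])
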