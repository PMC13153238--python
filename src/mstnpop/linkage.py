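"""Pairwise linkage disequilibrium from inferred gamete counts.

LD is computed on the phased gamete pool (2n gametes), not on composite
genotype LD: each haplotype's integer gamete count is marginalized down to a
2x2 table of allele combinations for a pair of loci, and from the table

* D   = p_AB - p_A p_B, where A and B denote the alt (minor) alleles,
* D'  = D / D_max with the piecewise bound
        D_max = min(p_A (1-p_B), (1-p_A) p_B)          if D > 0
        D_max = min(p_A p_B, (1-p_A)(1-p_B))           if D < 0
        and D' defined as 0 when D = 0,
* r^2 = D^2 / (p_A (1-p_A) p_B (1-p_B)),

plus a two-sided Fisher exact test of non-random allelic association (sum of
hypergeometric probabilities of all tables, with the observed margins, whose
probability does not exceed the observed table's, within relative tolerance
1e-7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import Variant
from .phasing import HaplotypeTable


@dataclass
class LDPair:
    """LD summary for one unordered pair of biallelic loci.

    Allele A/B are the alt alleles at each locus; r^2 and |D'| are invariant
    to this orientation, D's sign is not.
    """

    locus_a: Variant
    locus_b: Variant
    gamete_table: np.ndarray        # 2x2 [[AB, Ab], [aB, ab]]
    p_A: float
    p_B: float
    p_AB: float
    D: float
    D_max: float
    D_prime: float
    r2: float
    fisher_p: float
    defined: bool                   # False when either locus is monomorphic


def gamete_counts(table: HaplotypeTable, locus_a: str, locus_b: str) -> np.ndarray:
    """2x2 gamete table [[AB, Ab], [aB, ab]] (A, B = alt alleles).

    Loci are addressed by rsID or c-dot label; counts are sums of the
    haplotypes' integer gamete counts, so margins equal per-locus allele
    counts in the phased pool.
    """
    def locate(key: str) -> int:
        for j, v in enumerate(table.variants):
            if key in (v.rsid, v.cdna_label):
                return j
        raise KeyError(f"locus {key!r} not found in haplotype table")

    ja, jb = locate(locus_a), locate(locus_b)
    out = np.zeros((2, 2), dtype=int)
    va, vb = table.variants[ja], table.variants[jb]
    for hap, count in zip(table.haplotypes, table.gamete_counts):
        ia = 0 if hap[ja] == va.alt_allele else 1
        ib = 0 if hap[jb] == vb.alt_allele else 1
        out[ia, ib] += count
    return out


def ld_coefficients(counts: np.ndarray) -> tuple[float, float, float]:
    """(D, D', r^2) from a 2x2 gamete table; NaNs if a locus is monomorphic."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty gamete table")
    p_A = counts[0].sum() / total
    p_B = counts[:, 0].sum() / total
    if p_A in (0.0, 1.0) or p_B in (0.0, 1.0):
        return math.nan, math.nan, math.nan
    p_AB = counts[0, 0] / total
    D = p_AB - p_A * p_B
    if D > 0:
        d_max = min(p_A * (1 - p_B), (1 - p_A) * p_B)
    elif D < 0:
        d_max = min(p_A * p_B, (1 - p_A) * (1 - p_B))
    else:
        d_max = math.nan
    d_prime = 0.0 if D == 0 else D / d_max
    r2 = D * D / (p_A * (1 - p_A) * p_B * (1 - p_B))
    return D, d_prime, r2


def fisher_exact(counts: np.ndarray, tie_rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p for a 2x2 table by hypergeometric enumeration.

    Tables whose probability is within ``tie_rel_tol`` (relative) of the
    observed table's probability are included in the two-sided sum.
    """
    counts = np.asarray(counts, dtype=int)
    if (counts < 0).any():
        raise ValueError("negative counts")
    n1 = counts[0].sum()          # margin of allele A
    k1 = counts[:, 0].sum()       # margin of allele B
    total = counts.sum()
    if total == 0 or n1 in (0, total) or k1 in (0, total):
        return 1.0
    support = np.arange(max(0, n1 + k1 - total), min(n1, k1) + 1)
    pmf = stats.hypergeom.pmf(support, total, k1, n1)
    p_obs = stats.hypergeom.pmf(counts[0, 0], total, k1, n1)
    p = float(pmf[pmf <= p_obs * (1.0 + tie_rel_tol)].sum())
    return min(p, 1.0)


def ld_pair(table: HaplotypeTable, locus_a: str, locus_b: str) -> LDPair:
    def locate(key: str) -> Variant:
        for v in table.variants:
            if key in (v.rsid, v.cdna_label):
                return v
        raise KeyError(key)

    counts = gamete_counts(table, locus_a, locus_b)
    D, d_prime, r2 = ld_coefficients(counts)
    total = counts.sum()
    d_max = math.nan
    if not math.isnan(D):
        d_max = D / d_prime if d_prime not in (0.0,) and not math.isnan(d_prime) else math.nan
    return LDPair(
        locus_a=locate(locus_a), locus_b=locate(locus_b),
        gamete_table=counts,
        p_A=counts[0].sum() / total, p_B=counts[:, 0].sum() / total,
        p_AB=counts[0, 0] / total,
        D=D, D_max=d_max, D_prime=d_prime, r2=r2,
        fisher_p=fisher_exact(counts),
        defined=not math.isnan(D),
    )


def ld_matrix(table: HaplotypeTable) -> list[LDPair]:
    """All unordered locus pairs of the haplotype table."""
    ids = [v.rsid for v in table.variants]
    return [ld_pair(table, a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]


def ld_long_table(pairs: list[LDPair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus_a": p.locus_a.rsid, "locus_b": p.locus_b.rsid,
        "n_AB": int(p.gamete_table[0, 0]), "n_Ab": int(p.gamete_table[0, 1]),
        "n_aB": int(p.gamete_table[1, 0]), "n_ab": int(p.gamete_table[1, 1]),
        "D": p.D, "D_prime": p.D_prime, "r2": p.r2, "fisher_p": p.fisher_p,
    } for p in pairs])


def r2_square_table(pairs: list[LDPair]) -> pd.DataFrame:
    """Symmetric r^2 matrix as a DataFrame with an empty diagonal."""
    ids: list[str] = []
    for p in pairs:
        for v in (p.locus_a, p.locus_b):
            if v.rsid not in ids:
                ids.append(v.rsid)
    mat = pd.DataFrame(np.nan, index=ids, columns=ids)
    for p in pairs:
        mat.loc[p.locus_a.rsid, p.locus_b.rsid] = p.r2
        mat.loc[p.locus_b.rsid, p.locus_a.rsid] = p.r2
    return mat
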