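"""EM haplotype-frequency estimation and most-probable phase assignment.

Haplotype phase is inferred from unphased diploid genotypes under the
standard multinomial Hardy-Weinberg model (Excoffier-Slatkin style EM):

* E-step: for each individual, the posterior of each compatible ordered-pair
  resolution is proportional to ``f_a * f_b`` (times 2 for a != b);
* M-step: haplotype frequencies are the expected gamete counts over 2n.

The log-likelihood is non-decreasing across iterations and every fixed point
satisfies per-locus allele-frequency consistency exactly.

Pure maximum likelihood can retain an implausible low-frequency haplotype
whose only support is an ambiguous multi-heterozygote, because splitting
that individual against the common haplotype buys a small likelihood gain.
Bayesian phasing methods with coalescent-flavoured priors (the field's
standard tools) resolve such individuals into haplotypes already present in
the sample.  To emulate that behaviour deterministically, ``em_phase``
applies by default a parsimony refinement after convergence: a haplotype is
removed (rarest first) whenever all genotypes remain explainable without it
and the log-likelihood loss is smaller than the BIC penalty of one frequency
parameter, 0.5 * ln(2n); EM is re-run after each removal.  Set
``parsimony=None`` for the plain maximum-likelihood fixed point.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, Variant

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeTable:
    """Inferred haplotypes with frequencies and integer gamete counts."""

    variants: list[Variant]
    haplotypes: list[str]          # allele-letter strings, one letter per locus
    frequencies: np.ndarray        # sums to 1
    gamete_counts: np.ndarray      # ints summing to total_gametes
    total_gametes: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.gamete_counts = np.asarray(self.gamete_counts, dtype=int)
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies do not sum to 1")
        if self.gamete_counts.sum() != self.total_gametes:
            raise ValueError("gamete counts do not sum to 2n")

    def frequency_of(self, hap: str) -> float:
        return float(self.frequencies[self.haplotypes.index(hap)])


@dataclass
class PhaseAssignment:
    """Maximum-posterior phase resolution for one individual."""

    individual: str
    pair: tuple[str, str]
    posterior: float
    ambiguous: bool           # posterior < 0.9
    had_missing: bool = False


@dataclass
class PhasingResult:
    table: HaplotypeTable
    assignments: list[PhaseAssignment]
    loglik: float
    converged: bool
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)


def enumerate_compatible_pairs(genotype_row, variants: list[Variant]
                               ) -> list[tuple[str, str]]:
    """All unordered haplotype pairs consistent with one unphased genotype.

    With h heterozygous loci (and no missing data) there are exactly
    ``max(1, 2**(h-1))`` distinct pairs.  Missing calls are expanded over
    both alleles on each of the two haplotypes.
    """
    row = list(genotype_row)
    missing_idx = [j for j, c in enumerate(row) if c == MISSING]
    if missing_idx:
        logger.warning("enumerating over %d missing call(s)", len(missing_idx))
    pairs: set[tuple[str, str]] = set()
    for combo in itertools.product((0, 1, 2), repeat=len(missing_idx)):
        concrete = row[:]
        for j, c in zip(missing_idx, combo):
            concrete[j] = c
        het = [j for j, c in enumerate(concrete) if c == 1]
        base_a = [v.alt_allele if c == 2 else v.ref_allele
                  for c, v in zip(concrete, variants)]
        base_b = base_a[:]
        if not het:
            pairs.add(("".join(base_a), "".join(base_b)))
            continue
        for bits in itertools.product((0, 1), repeat=len(het) - 1):
            a, b = base_a[:], base_b[:]
            for j, bit in zip(het, (0,) + bits):
                va = variants[j]
                a[j] = va.alt_allele if bit else va.ref_allele
                b[j] = va.ref_allele if bit else va.alt_allele
            pairs.add(tuple(sorted(("".join(a), "".join(b)))))
    return sorted(pairs)


def _round_gamete_counts(freqs: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of freq*total; ties go to the larger haplotype."""
    raw = freqs * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.lexsort((-freqs, -(raw - counts)))  # frac desc, then freq desc
    counts[order[:remainder]] += 1
    return counts


def _em_fit(pair_lists: list[list[tuple[int, int]]], n_haps: int,
            init: np.ndarray, tol: float, max_iter: int
            ) -> tuple[np.ndarray, float, bool, int, list[float]]:
    """Run EM to a fixed point over indexed pair lists. Returns freqs, loglik."""
    f = init.copy()
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts = np.zeros(n_haps)
        loglik = 0.0
        for pairs in pair_lists:
            w = np.array([(2.0 if a != b else 1.0) * f[a] * f[b] for a, b in pairs])
            tot = w.sum()
            if tot <= 0.0:
                # all compatible pairs have zero frequency; impossible genotype
                return f, -math.inf, False, it, trace
            loglik += math.log(tot)
            w /= tot
            for (a, b), wi in zip(pairs, w):
                counts[a] += wi
                counts[b] += wi
        trace.append(loglik)
        new_f = counts / counts.sum()
        delta = float(np.abs(new_f - f).max())
        f = new_f
        if delta < tol:
            converged = True
            break
    # loglik at the final frequencies
    loglik = _loglik(pair_lists, f)
    return f, loglik, converged, it, trace


def _loglik(pair_lists: list[list[tuple[int, int]]], f: np.ndarray) -> float:
    ll = 0.0
    for pairs in pair_lists:
        tot = sum((2.0 if a != b else 1.0) * f[a] * f[b] for a, b in pairs)
        if tot <= 0.0:
            return -math.inf
        ll += math.log(tot)
    return ll


def em_phase(g: GenotypeMatrix, tol: float = 1e-8, max_iter: int = 10_000,
             parsimony: str | None = "bic",
             prune_threshold: float | None = None) -> PhasingResult:
    """Infer haplotype frequencies and most-probable phases by EM.

    Parameters
    ----------
    tol : maximum absolute frequency change declaring convergence.
    parsimony : ``"bic"`` (default) applies the BIC-guided support
        refinement described in the module docstring; ``None`` returns the
        plain ML fixed point.
    prune_threshold : haplotypes below this frequency are pruned after
        convergence when removable; defaults to ``1/(4n)``.
    """
    if g.n_loci < 1:
        raise ValueError("need at least one locus")
    het_per_ind = (g.calls == 1).sum(axis=1) + (g.calls == MISSING).sum(axis=1)
    if het_per_ind.max(initial=0) > 20:
        raise ValueError("an individual has > 20 ambiguous loci; enumeration bound exceeded")

    n = g.n_individuals
    total_gametes = 2 * n
    if prune_threshold is None:
        prune_threshold = 1.0 / (4 * n)

    raw_pairs = [enumerate_compatible_pairs(g.calls[i], g.variants) for i in range(n)]
    had_missing = [(g.calls[i] == MISSING).any() for i in range(n)]
    haps = sorted({h for pl in raw_pairs for p in pl for h in p})
    index = {h: k for k, h in enumerate(haps)}
    pair_lists = [[(index[a], index[b]) for a, b in pl] for pl in raw_pairs]

    # near-uniform start; the tiny index-based tilt breaks the phase symmetry
    # of otherwise-equivalent resolutions (exact uniformity is a saddle point
    # of the likelihood for purely ambiguous data) and keeps runs deterministic
    init = 1.0 + 1e-3 * np.arange(len(haps)) / max(len(haps) - 1, 1)
    init /= init.sum()
    f, loglik, converged, n_iter, trace = _em_fit(pair_lists, len(haps), init, tol, max_iter)
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)

    keep = np.ones(len(haps), dtype=bool)

    def removable(k: int) -> bool:
        return all(any(a != k and b != k and keep[a] and keep[b] for a, b in pl)
                   for pl in pair_lists)

    def refit(mask: np.ndarray, start: np.ndarray):
        sub = [[(a, b) for a, b in pl if mask[a] and mask[b]] for pl in pair_lists]
        start = np.where(mask, start, 0.0)
        s = start.sum()
        start = start / s if s > 0 else mask / mask.sum()
        return _em_fit(sub, len(haps), start, tol, max_iter)

    if parsimony == "bic":
        penalty = 0.5 * math.log(total_gametes)
        improved = True
        while improved:
            improved = False
            for k in np.argsort(f):
                if not keep[k] or f[k] >= 0.5:
                    continue
                if not removable(k):
                    continue
                mask = keep.copy()
                mask[k] = False
                f_red, ll_red, conv_red, _, _ = refit(mask, f)
                if loglik - ll_red < penalty:
                    keep, f, loglik = mask, f_red, ll_red
                    improved = True
                    break
    elif parsimony is not None:
        raise ValueError(f"unknown parsimony mode {parsimony!r}")

    # prune numerically-dead and sub-threshold haplotypes, then refit on support
    for k in np.argsort(f):
        if keep[k] and f[k] < prune_threshold and removable(k):
            keep[k] = False
    if not keep.all():
        f, loglik, _, _, _ = refit(keep, f)

    kept_idx = [k for k in range(len(haps)) if keep[k] and f[k] > 0]
    order = sorted(kept_idx, key=lambda k: (-f[k], haps[k]))
    out_haps = [haps[k] for k in order]
    out_freqs = np.array([f[k] for k in order])
    out_freqs = out_freqs / out_freqs.sum()
    table = HaplotypeTable(
        variants=list(g.variants),
        haplotypes=out_haps,
        frequencies=out_freqs,
        gamete_counts=_round_gamete_counts(out_freqs, total_gametes),
        total_gametes=total_gametes,
    )

    assignments = []
    for i, (pl, raw) in enumerate(zip(pair_lists, raw_pairs)):
        weights = np.array([(2.0 if a != b else 1.0) * f[a] * f[b] for a, b in pl])
        tot = weights.sum()
        best = int(np.argmax(weights))
        post = float(weights[best] / tot) if tot > 0 else 0.0
        assignments.append(PhaseAssignment(
            individual=g.individuals[i],
            pair=raw[best],
            posterior=post,
            ambiguous=post < 0.9,
            had_missing=bool(had_missing[i]),
        ))

    return PhasingResult(table=table, assignments=assignments, loglik=loglik,
                         converged=converged, n_iter=n_iter, loglik_trace=trace)


def haplotype_report(table: HaplotypeTable, reference: str | None = None) -> "pd.DataFrame":
    """Name haplotypes Hap1..HapK by descending frequency and annotate
    per-row the loci whose allele differs from the reference haplotype."""
    import pandas as pd

    if not table.haplotypes:
        raise ValueError("empty haplotype table")
    if reference is None:
        reference = "".join(v.ref_allele for v in table.variants)
    rows = []
    order = np.lexsort((table.haplotypes, -table.frequencies))
    for rank, k in enumerate(order, start=1):
        hap = table.haplotypes[k]
        diffs = [f"{v.cdna_label.split('>')[0][:-1]}{a}"  # e.g. c.373+283C
                 for a, r, v in zip(hap, reference, table.variants) if a != r]
        rows.append({
            "name": f"Hap{rank}",
            "haplotype": hap,
            "frequency": float(table.frequencies[k]),
            "frequency_pct": float(table.frequencies[k]) * 100.0,
            "gamete_count": int(table.gamete_counts[k]),
            "n_diffs_from_reference": len(diffs),
            "diffs_from_reference": ";".join(diffs),
        })
    return pd.DataFrame(rows)
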