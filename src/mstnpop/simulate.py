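"""Deterministic cohort reconstruction and seeded simulators.

``reconstruct_ucm_fixture`` rebuilds, from published aggregate frequencies,
the exact 54-animal genotype matrix of the Ukrainian Carpathian Mountain
(UCM) sheep cohort genotyped at nine biallelic SNPs in intron 1 of the MSTN
gene.  The reconstruction is uniquely determined (see
:func:`reconstruct_ucm_fixture`), so every downstream statistic — diversity
table, ambiguity-motif tally, haplotype table, LD matrix — can be recomputed
from it without access to the raw data.

``simulate_cohort`` draws cohorts from arbitrary haplotype frequencies with
optional excess homozygosity (inbreeding coefficient F), and
``simulate_trajectory`` produces harmonic-mode synthetic trajectories with
known closed-form fluctuation amplitudes; both are the generative models
used by the parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, Variant
from .trajectory import Trajectory

#: The nine intron-1 SNP loci, in ascending intron offset (genomic order).
UCM_VARIANTS: list[Variant] = [
    Variant("rs119102826", "c.373+241T>C", 241, "T", "C"),
    Variant("rs427811339", "c.373+243G>A", 243, "G", "A"),
    Variant("rs406172342", "c.373+246T>C", 246, "T", "C"),
    Variant("rs417602601", "c.373+249T>C", 249, "T", "C"),
    Variant("rs119102828", "c.373+259G>T", 259, "G", "T"),
    Variant("rs7600797830", "c.373+283T>C", 283, "T", "C"),
    Variant("rs407388367", "c.373+323C>T", 323, "C", "T"),
    Variant("rs408710650", "c.373+563G>A", 563, "G", "A"),
    Variant("rs419902890", "c.373+607G>A", 607, "G", "A"),
]

#: The six haplotypes segregating in the cohort and their gamete counts
#: out of 2n = 108.
UCM_HAPLOTYPES: list[tuple[str, int]] = [
    ("TGTTGTCGG", 95),   # reference at every locus
    ("TGTTGCCGG", 6),    # C at c.373+283 only
    ("TGTTTTCGG", 4),    # T at c.373+259 only
    ("CATTTTCAG", 1),    # c.373+241C, +243A, +259T, +563A
    ("TATCTTTGG", 1),    # c.373+243A, +249C, +259T, +323T
    ("TACTTTCGA", 1),    # c.373+243A, +246C, +259T, +607A
]

#: Diplotypes of the 54 animals as (hap_index_a, hap_index_b, count).
_UCM_DIPLOTYPES: list[tuple[int, int, int]] = [
    (0, 0, 43),  # homozygous reference
    (0, 1, 3),   # het at +283 only
    (1, 1, 1),   # hom-alt at +283
    (1, 2, 1),   # het at +283 and +259
    (0, 2, 3),   # het at +259 only
    (0, 3, 1),   # multi-het carrying hap 4
    (0, 4, 1),   # multi-het carrying hap 5
    (0, 5, 1),   # multi-het carrying hap 6
]


@dataclass
class CohortSpec:
    """Generative model for a diploid cohort under HWE with inbreeding."""

    variants: list[Variant]
    haplotypes: list[str]
    frequencies: np.ndarray
    n: int
    inbreeding: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if not self.haplotypes:
            raise ValueError("empty haplotype set")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        if not 0.0 <= self.inbreeding < 1.0:
            raise ValueError("inbreeding coefficient must be in [0, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class TrajectorySpec:
    """Harmonic-mode synthetic trajectory: base + modes * sin + noise."""

    n_atoms: int
    n_frames: int
    mode_amplitudes: list[float] = field(default_factory=list)
    mode_displacements: list[np.ndarray] = field(default_factory=list)  # (A,3) unit patterns
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if any(a < 0 for a in self.mode_amplitudes):
            raise ValueError("amplitudes must be >= 0")
        if len(self.mode_amplitudes) != len(self.mode_displacements):
            raise ValueError("one displacement pattern per amplitude")


def reconstruct_ucm_fixture() -> GenotypeMatrix:
    """The 54 x 9 UCM cohort, reconstructed exactly from published aggregates.

    Inputs to the reconstruction are (a) per-locus genotype counts
    (hom-ref, het, hom-alt): (53,1,0) at six singleton loci, (51,3,0) at
    c.373+243, (47,7,0) at c.373+259 and (49,4,1) at c.373+283; (b) the six
    segregating haplotypes with gamete counts 95/6/4/1/1/1; and (c) the fact
    that exactly eight distinct unphased ambiguity motifs occur, the
    all-reference motif in 43 of 54 animals.

    Uniqueness argument.  The three haplotypes carrying 4 mutations each
    (gamete count 1) can only pair with the reference haplotype — any other
    partner would create a ninth motif or an extra haplotype.  The c.373+283
    hom-alt animal consumes two of the six +283-alt gametes; three het
    animals pair that allele with the reference haplotype (the motif tally
    demands three identical singleton-het motifs at +283); the remaining
    +283 gamete must ride with one +259 gamete in a single double-het
    animal, otherwise the animal total would be 55, not 54.  The three
    remaining +259 gametes pair with the reference haplotype.  That accounts
    for 11 non-reference animals and forces the other 43 to be homozygous
    reference.
    """
    rows: list[np.ndarray] = []
    haps = [h for h, _ in UCM_HAPLOTYPES]
    for ia, ib, count in _UCM_DIPLOTYPES:
        geno = _diplotype_to_codes(haps[ia], haps[ib], UCM_VARIANTS)
        rows.extend([geno] * count)
    individuals = [f"UCM{i:03d}" for i in range(1, len(rows) + 1)]
    return GenotypeMatrix(individuals, list(UCM_VARIANTS),
                          np.array(rows, dtype=np.int8))


def ucm_cohort_spec(n: int = 54, inbreeding: float = 0.0, seed: int = 0) -> CohortSpec:
    """CohortSpec with the UCM haplotype frequencies (for simulations)."""
    counts = np.array([c for _, c in UCM_HAPLOTYPES], dtype=float)
    return CohortSpec(variants=list(UCM_VARIANTS),
                      haplotypes=[h for h, _ in UCM_HAPLOTYPES],
                      frequencies=counts / counts.sum(),
                      n=n, inbreeding=inbreeding, seed=seed)


def _diplotype_to_codes(hap_a: str, hap_b: str, variants: list[Variant]) -> np.ndarray:
    codes = np.empty(len(variants), dtype=np.int8)
    for j, v in enumerate(variants):
        codes[j] = int(hap_a[j] == v.alt_allele) + int(hap_b[j] == v.alt_allele)
    return codes


def simulate_cohort(spec: CohortSpec) -> GenotypeMatrix:
    """Draw a cohort: two haplotypes i.i.d. from the frequency vector per
    individual; with probability F the second copies the first (standard
    inbreeding mixture).  Fully reproducible given the seed."""
    rng = np.random.default_rng(spec.seed)
    k = len(spec.haplotypes)
    first = rng.choice(k, size=spec.n, p=spec.frequencies)
    second = rng.choice(k, size=spec.n, p=spec.frequencies)
    autozygous = rng.random(spec.n) < spec.inbreeding
    second = np.where(autozygous, first, second)
    rows = [_diplotype_to_codes(spec.haplotypes[a], spec.haplotypes[b], spec.variants)
            for a, b in zip(first, second)]
    individuals = [f"SIM{i:05d}" for i in range(1, spec.n + 1)]
    return GenotypeMatrix(individuals, list(spec.variants),
                          np.array(rows, dtype=np.int8))


def default_atom_table(n_atoms: int) -> pd.DataFrame:
    """Minimal atom metadata: unit masses, 0.15 nm radii, all atoms both
    backbone and C1' so every selection is non-empty."""
    return pd.DataFrame({
        "name": [f"A{i}" for i in range(n_atoms)],
        "residue": np.arange(n_atoms),
        "mass": 1.0,
        "radius": 0.15,
        "backbone": True,
        "c1p": True,
        "donor": False,
        "hydrogen": False,
        "acceptor": False,
        "base_pairing": False,
        "parent": np.nan,
    })


def simulate_trajectory(spec: TrajectorySpec, base: np.ndarray | None = None,
                        atoms: pd.DataFrame | None = None) -> Trajectory:
    """Harmonic synthetic trajectory.

    Frame k displaces the base structure by
    ``sum_m amplitude_m * pattern_m * sin(2 pi (m+1) k / n_frames)`` plus
    isotropic Gaussian noise.  Phases cover whole periods, so a single mode
    of amplitude a gives the affected atoms an exact RMSF of a / sqrt(2)
    (without fitting).
    """
    rng = np.random.default_rng(spec.seed)
    if base is None:
        base = rng.normal(scale=1.0, size=(spec.n_atoms, 3))
    base = np.asarray(base, dtype=float)
    if atoms is None:
        atoms = default_atom_table(spec.n_atoms)
    frames = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    t = np.arange(spec.n_frames)
    for m, (amp, pattern) in enumerate(zip(spec.mode_amplitudes,
                                           spec.mode_displacements)):
        phase = np.sin(2.0 * np.pi * (m + 1) * t / spec.n_frames)
        frames += amp * phase[:, None, None] * np.asarray(pattern)[None, :, :]
    if spec.noise_sd > 0:
        frames += rng.normal(scale=spec.noise_sd, size=frames.shape)
    return Trajectory(coords=frames, atoms=atoms)
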