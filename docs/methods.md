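# Methods

## Cohort model and data representation

The unit of analysis is a cohort of n diploid individuals genotyped at m
biallelic SNP loci, stored as integer codes (0 hom-ref, 1 het, 2 hom-alt,
−1 missing). Loci are keyed by their intronic offset (`c.373+N`, the N-th
base downstream of the exon-1 donor site) and ordered by it; genomic
coordinates are optional and 1-based. Missing calls are excluded locus-wise
from allele counting. Unphased genotypes can be rendered as IUPAC
"ambiguity motifs" — one letter per locus, heterozygotes written as the
two-allele ambiguity code — which is the representation used to tally
genotype combinations before phasing.

The reference cohort (54 UCM sheep × 9 loci) is reconstructed exactly from
published aggregate frequencies; the uniqueness argument (why the published
per-locus counts, haplotype table and motif count admit exactly one
genotype matrix up to row order) is spelled out in
`mstnpop.simulate.reconstruct_ucm_fixture`. Sample IDs (UCM001–UCM054) and
row order are arbitrary but fixed, so the fixture is byte-reproducible.

## Diversity statistics

Ho, He, F_IS, PIC and the HWE χ² follow the classical textbook formulas
(see README). Numerical conventions:

* He is the plug-in estimator 1 − Σp²; no n/(n−1) small-sample correction.
* The χ² keeps all three genotype classes even when an expected count is
  below 1 (a warning is logged below 5); no continuity correction. This is
  deliberate: collapsing classes or correcting changes the statistic most
  where rare alleles make it most interesting.
* Monomorphic loci return He = 0, F_IS = NaN (flagged, never raised),
  χ² = 0, p = 1.
* `pic(..., rounding_mode="printed_compat")` rounds allele frequencies to
  three decimals before evaluating the formula. Published tables are often
  computed from the rounded frequencies they print; this mode reproduces
  such tables digit-for-digit (verified for all four frequency classes in
  the reference cohort), while the default mode keeps full precision. The
  two differ in the fourth decimal at p = 102/108.

## Haplotype phasing

Frequencies are estimated by EM under the multinomial Hardy–Weinberg
likelihood (Excoffier–Slatkin): the E-step weights each compatible
haplotype-pair resolution of an individual by f_a·f_b (×2 when a ≠ b), the
M-step sets frequencies to expected gamete counts over 2n. An individual
with h heterozygous loci has max(1, 2^(h−1)) compatible unordered pairs;
missing sites are enumerated over both alleles (bounded at 20 ambiguous
loci per individual). Initialization is near-uniform over the union of
compatible haplotypes, with a tiny (≤ 1e-3 relative) deterministic
index-based tilt: exact uniformity is a saddle point of the likelihood for
purely ambiguous data, and the tilt makes convergence deterministic without
random restarts. Convergence: max absolute frequency change < 1e-8, cap
10,000 iterations (non-convergence is flagged, not raised). The
log-likelihood is non-decreasing by construction and asserted in tests.

**Parsimony refinement.** Pure maximum likelihood can retain a spurious
low-frequency haplotype whose only support is one ambiguous
multi-heterozygote: splitting that individual against the dominant
haplotype buys a small likelihood gain (≈ +0.75 log-units in the reference
cohort) at the cost of a haplotype observed nowhere else. Bayesian phasing
tools, whose priors favour resolving ambiguous individuals into haplotypes
already present, do not report such haplotypes. To emulate that behaviour
deterministically, after convergence the rarest removable haplotype (one
whose removal leaves every genotype explainable) is dropped whenever the
log-likelihood loss is below the BIC penalty for one frequency parameter,
½·ln(2n); EM is re-run on the reduced support and the step repeats. On the
reference cohort this removes exactly one haplotype and yields the
six-haplotype spectrum with integer gamete counts 95/6/4/1/1/1. Plain ML
(`parsimony=None`) is retained and is what the grid-likelihood oracle test
checks. Haplotypes below 1/(4n) after refinement are pruned the same way.

Gamete counts are reported as largest-remainder roundings of freq·2n (ties
to the larger haplotype), so they always sum to 2n. Assignments with
maximum-posterior probability below 0.9 are flagged ambiguous rather than
dropped.

## Linkage disequilibrium

LD is computed from the *phased gamete pool* (2n gametes), not from
composite genotype LD: the haplotype table is marginalized to a 2×2 table
per locus pair, from which D, D′ (piecewise D_max; D′ ≡ 0 when D = 0) and
r² follow. A and B denote the alt alleles; r² and |D′| are
orientation-invariant, D's sign is not. The Fisher exact test enumerates
the hypergeometric distribution over the fixed margins and sums all tables
whose probability is ≤ the observed one within relative tolerance 1e-7
(floating-point tie safety). In a pool this small every pairwise
association is complete, so |D′| = 1 for all informative pairs and carries
no ranking information — r² is the interpretable statistic.

## PWM motif scanning

Motifs are letter-probability matrices (MEME minimal format). Scores are
log₂ odds against the background after pseudocount smoothing
p′ = (p + c)/(1 + 4c), default c = 0.001 (curated matrices contain zeros).
The p-value of a window is the exact tail probability of its score for a
background-distributed random word, computed by dynamic programming over
scores discretized to bin width 1e-3/width (total discretization error
< 1e-3 score units); reported scores live on the same grid, so p-values
are exactly monotone in score. Both strands are scanned; − strand hits are
reported in forward-strand coordinates (1-based inclusive) with
forward-strand letters. Benjamini–Hochberg q-values are computed over all
scored windows of one (motif, sequence) scan, matching per-motif reporting
granularity. The background defaults to uniform 0.25 and can be overridden
per motif file. The MEME reader validates row sums to 1e-4 and
renormalizes (published matrices printed to six decimals are not exact to
1e-6).

Allele comparison substitutes each allele at the SNP, scans a window of
±(max width − 1) plus configurable slack, and classifies each motif by the
presence of hits overlapping the SNP: gained / lost / unchanged /
absent-in-both. When neither allele has an overlapping hit but the motif
hits elsewhere in the window, the status is "unchanged" (those hits are
identical between alleles by construction).

Reproducing any published screen's exact p/q values requires that study's
genome sequence and motif-library versions; those are external inputs, so
this module is validated against closed forms and exhaustive enumeration
(widths ≤ 6) instead.

## Trajectory metrics

Trajectories are (frames × atoms × 3) coordinate arrays in nm with per-atom
roles (backbone, ribose C1′, H-bond donor/hydrogen/acceptor, base-pairing)
and masses/radii. Conventions and defaults:

* Superposition is Kabsch SVD with reflections excluded; collinear
  selections are rejected. RMSD uses the sugar-phosphate backbone
  selection by default, RMSF and PCA the C1′ atoms.
* RMSF fits every frame to the frame-0 structure, recomputes the mean, and
  re-fits once to that mean before taking fluctuations.
* SASA is Shrake–Rupley with probe 0.14 nm and 960 golden-spiral points;
  absolute values depend on the van-der-Waals radius table (a small
  built-in element table, overridable), so tests pin it to closed forms
  (isolated sphere, additivity, half-burial). Rotation invariance holds
  only to quadrature accuracy (~1 %).
* Hydrogen bonds: donor–acceptor distance ≤ 0.35 nm and
  hydrogen–donor–acceptor angle (vertex at the donor) ≤ 30°, the common
  MD-analysis convention; both cutoffs are parameters. Hydrogens are tied
  to donors through an explicit `parent` column — no bond inference. The
  base-pairing filter restricts donors and acceptors to atoms flagged
  `base_pairing`; which atoms carry that flag is the caller's convention
  (canonical/wobble/Hoogsteen edges), not something the module infers.
* PCA diagonalizes the 3k×3k covariance of fitted, centred selection
  coordinates (ddof 1); the FEL is −ln(count/max count) in kT over the
  (PC1, PC2) histogram, NaN for unsampled bins, 0 at the modal bin.
* No periodic-boundary handling: inputs are assumed whole-molecule and
  PBC-corrected upstream.

## Synthetic generators and what they do (not) show

`simulate_cohort` draws two haplotypes i.i.d. from a frequency vector per
individual; with probability F the second copies the first (the standard
inbreeding mixture), so per-locus F_IS concentrates near F. It emulates a
panmictic cohort with optional uniform inbreeding — not population
structure, genotyping error, or linkage beyond what the haplotype
frequencies encode. `simulate_trajectory` superposes harmonic modes
(sinusoids over whole periods, so a mode of amplitude a gives RMSF a/√2
exactly) and isotropic Gaussian noise on a base structure — it produces
known-variance ensembles for metric validation, not physically realistic
RNA dynamics (no bonded constraints, no solvent, no anharmonicity).
Passing tests therefore certify the *estimators* (statistics recovered
within 3·SE of generating values; metrics matching closed forms), not any
claim about real cohorts or real trajectories.

Analysis drivers 05 and 06 run on synthetic inputs for the same reason and
say so; the cohort drivers (01–04) run on the exactly reconstructed UCM
matrix, so their outputs are the cohort's actual statistics.

## Problem sizes

The default suite phases cohorts up to n = 2000 (seeded) for parameter
recovery, enumerates 4^6 words for PWM oracles, and keeps trajectory
fixtures at ≤ 30 atoms × ≤ 400 frames; the whole suite runs in well under a
minute on one CPU.

## Known limitations

* Biallelic SNPs only; no indels or multi-allelic sites.
* EM phasing assumes Hardy–Weinberg pairing of haplotypes; no
  recombination-aware or pedigree phasing, no imputation.
* The BIC refinement is a deterministic stand-in for Bayesian phasing
  priors; on cohorts where ML and parsimony disagree more strongly than
  one haplotype, results may differ from any particular sampler.
* Exact Fisher/χ² p-values are unconditional on the phasing: gamete counts
  are treated as observed, as is standard when LD is computed after
  phasing.
* SASA and H-bond absolute values depend on radius tables and role flags
  supplied with the trajectory.
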