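"""Domain types and I/O for biallelic SNP genotype data.

The objects here are deliberately small: a :class:`Variant` identifies one
biallelic intronic SNP by its HGVS-like c-dot label (``c.373+283T>C`` means
283 bp downstream of the exon-1 donor site, T replaced by C), and a
:class:`GenotypeMatrix` holds unphased diploid calls for a cohort as integer
codes (0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing).

Unphased multilocus genotypes can be rendered as IUPAC "ambiguity motifs":
one letter per locus, with heterozygous sites written as the two-allele
ambiguity code (Y = C/T, R = A/G, ...).  This is the representation used to
tally genotype combinations before phasing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: IUPAC two-letter ambiguity codes, keyed by frozenset of the two alleles.
IUPAC_AMBIGUITY = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

_CDNA_RE = re.compile(r"^c\.(\d+)\+(\d+)([ACGT])>([ACGT])$")


@dataclass(frozen=True)
class Variant:
    """One biallelic SNP locus."""

    rsid: str
    cdna_label: str
    intron_offset: int
    ref_allele: str
    alt_allele: str
    genomic_pos: int | None = None

    def __post_init__(self) -> None:
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in "ACGT" or len(allele) != 1:
                raise ValueError(f"{self.rsid}: allele {allele!r} is not one of A/C/G/T")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")
        if self.intron_offset < 1:
            raise ValueError(f"{self.rsid}: intron offset must be >= 1")

    @property
    def het_code(self) -> str:
        """IUPAC ambiguity letter for the ref/alt pair."""
        return IUPAC_AMBIGUITY[frozenset((self.ref_allele, self.alt_allele))]

    @classmethod
    def from_cdna_label(cls, label: str, rsid: str | None = None) -> "Variant":
        """Parse a ``c.373+283T>C``-style label into a Variant."""
        m = _CDNA_RE.match(label.strip())
        if m is None:
            raise ValueError(f"cannot parse c-dot label {label!r}")
        _, offset, ref, alt = m.groups()
        return cls(rsid=rsid or label, cdna_label=label, intron_offset=int(offset),
                   ref_allele=ref, alt_allele=alt)


@dataclass
class GenotypeMatrix:
    """n individuals x m biallelic loci of unphased genotype codes."""

    individuals: list[str]
    variants: list[Variant]
    calls: np.ndarray  # (n, m) int8, codes {0, 1, 2, -1}

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = len(self.individuals), len(self.variants)
        if self.calls.shape != (n, m):
            raise ValueError(f"calls shape {self.calls.shape} != ({n}, {m})")
        if len(set(self.individuals)) != n:
            raise ValueError("duplicated sample IDs")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes at {np.argwhere(bad)[:5]}")
        offsets = [v.intron_offset for v in self.variants]
        if offsets != sorted(offsets) or len(set(offsets)) != m:
            raise ValueError("variants must be ordered by strictly increasing intron offset")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.variants)

    def genotype_counts(self, locus: int) -> tuple[int, int, int]:
        """(hom-ref, het, hom-alt) counts at one locus, missing excluded."""
        col = self.calls[:, locus]
        return tuple(int((col == c).sum()) for c in (0, 1, 2))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.individuals == other.individuals
                and self.variants == other.variants
                and np.array_equal(self.calls, other.calls))


def encode_motifs(g: GenotypeMatrix) -> list[str]:
    """Render each individual's unphased genotype as an IUPAC motif string.

    Hom-ref -> ref letter, hom-alt -> alt letter, het -> the two-allele
    ambiguity code, missing -> ``N``.
    """
    letters = np.empty((4, g.n_loci), dtype="U1")
    for j, v in enumerate(g.variants):
        letters[:, j] = (v.ref_allele, v.het_code, v.alt_allele, "N")
    idx = np.where(g.calls == MISSING, 3, g.calls)
    return ["".join(letters[idx[i, j], j] for j in range(g.n_loci))
            for i in range(g.n_individuals)]


def tally_motifs(motifs: list[str]) -> pd.DataFrame:
    """Count distinct motif strings.

    Returns a DataFrame with columns ``motif, count, frequency``, ordered by
    descending count then lexicographically; frequencies sum to 1.
    """
    if not motifs:
        raise ValueError("empty motif list")
    counts = pd.Series(motifs).value_counts()
    df = counts.rename_axis("motif").reset_index(name="count")
    df = df.sort_values(["count", "motif"], ascending=[False, True], ignore_index=True)
    df["frequency"] = df["count"] / len(motifs)
    return df


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def write_genotypes_csv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the CSV genotype dialect.

    Header row is ``sample,<cdna_label_1>,...``; cells are 0/1/2/NA.  Variant
    metadata that the c-dot label cannot carry (rsID, genomic position) goes
    into ``#`` comment lines so the file round-trips losslessly.
    """
    path = Path(path)
    with path.open("w") as fh:
        for v in g.variants:
            pos = "" if v.genomic_pos is None else v.genomic_pos
            fh.write(f"#variant,{v.cdna_label},{v.rsid},{pos}\n")
        fh.write("sample," + ",".join(v.cdna_label for v in g.variants) + "\n")
        for i, sample in enumerate(g.individuals):
            cells = ["NA" if c == MISSING else str(int(c)) for c in g.calls[i]]
            fh.write(sample + "," + ",".join(cells) + "\n")


def _parse_csv_cell(cell: str, v: Variant) -> int:
    cell = cell.strip()
    if cell in {"NA", "", ".", "./."}:
        return MISSING
    if cell in {"0", "1", "2"}:
        return int(cell)
    if "/" in cell:  # "T/C"-style allele pair
        a, b = (x.strip().upper() for x in cell.split("/", 1))
        alleles = {v.ref_allele, v.alt_allele}
        if not {a, b} <= alleles:
            logger.warning("unparseable genotype %r at %s -> missing", cell, v.cdna_label)
            return MISSING
        return int(a == v.alt_allele) + int(b == v.alt_allele)
    logger.warning("unparseable genotype %r at %s -> missing", cell, v.cdna_label)
    return MISSING


def read_genotypes_csv(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    meta: dict[str, tuple[str, int | None]] = {}
    rows: list[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#variant,"):
                _, label, rsid, pos = line.split(",", 3)
                meta[label] = (rsid, int(pos) if pos else None)
            elif not line.startswith("#"):
                rows.append(line)
    if not rows:
        raise ValueError(f"{path}: no data")
    header = rows[0].split(",")
    variants = []
    for label in header[1:]:
        rsid, pos = meta.get(label, (None, None))
        v = Variant.from_cdna_label(label, rsid=rsid)
        if pos is not None:
            v = Variant(v.rsid, v.cdna_label, v.intron_offset, v.ref_allele,
                        v.alt_allele, genomic_pos=pos)
        variants.append(v)
    samples, calls = [], []
    for line in rows[1:]:
        cells = line.split(",")
        samples.append(cells[0])
        calls.append([_parse_csv_cell(c, v) for c, v in zip(cells[1:], variants)])
    return GenotypeMatrix(samples, variants, np.array(calls, dtype=np.int8))


# ---------------------------------------------------------------------------
# Minimal VCF 4.2 dialect (GT only), via pysam
# ---------------------------------------------------------------------------

def write_genotypes_vcf(g: GenotypeMatrix, path: str | Path, chrom: str = "2") -> None:
    """Write an uncompressed minimal VCF 4.2 with GT-only FORMAT."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(f"##contig=<ID={chrom}>")
    for s in g.individuals:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, v in enumerate(g.variants):
            rec = out.new_record(
                contig=chrom,
                start=(v.genomic_pos or v.intron_offset) - 1,
                alleles=(v.ref_allele, v.alt_allele),
                id=v.rsid,
            )
            for i, s in enumerate(g.individuals):
                c = int(g.calls[i, j])
                gt = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}[c]
                rec.samples[s]["GT"] = gt
                rec.samples[s].phased = False
            out.write(rec)


def read_genotypes_vcf(path: str | Path, variants: list[Variant] | None = None) -> GenotypeMatrix:
    """Read a minimal VCF (biallelic SNPs, GT field; ``|`` accepted, phase ignored).

    If ``variants`` is given it supplies c-dot labels/offsets; otherwise
    offsets fall back to POS and labels are synthesized from rsID/position.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(set(samples)) != len(samples):
            raise ValueError("duplicated sample IDs in VCF")
        by_id = {v.rsid: v for v in variants} if variants else {}
        out_variants, calls = [], []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"record {rec.id or rec.pos} is not biallelic")
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                raise ValueError(f"record {rec.id or rec.pos} is not a SNP")
            if rec.id in by_id:
                out_variants.append(by_id[rec.id])
            else:
                out_variants.append(Variant(
                    rsid=rec.id or f"pos{rec.pos}",
                    cdna_label=f"c.373+{rec.pos}{rec.ref}>{rec.alts[0]}",
                    intron_offset=rec.pos,
                    ref_allele=rec.ref, alt_allele=rec.alts[0],
                    genomic_pos=rec.pos))
            row = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt) or len(gt) != 2:
                    if gt is not None and gt != (None,) and gt != (None, None):
                        logger.warning("unparseable GT %r for %s -> missing", gt, s)
                    row.append(MISSING)
                else:
                    row.append(int(gt[0]) + int(gt[1]))
            calls.append(row)
    calls_arr = np.array(calls, dtype=np.int8).T if calls else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(samples, out_variants, calls_arr)


def read_genotypes(path: str | Path, dialect: str = "csv",
                   variants: list[Variant] | None = None) -> GenotypeMatrix:
    """Read genotypes from the CSV dialect or a minimal VCF."""
    if dialect == "csv":
        return read_genotypes_csv(path)
    if dialect == "vcf":
        return read_genotypes_vcf(path, variants=variants)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_summary(table: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write a tabular result; floats kept to 12 significant digits."""
    sep = {"csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise ValueError(f"unknown format {format!r}")
    table.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA sequences as an ordered name->sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
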