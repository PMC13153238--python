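"""Allele-aware PWM motif scanning with exact score-distribution p-values.

A motif is a position probability matrix (MEME minimal format).  Scanning
scores every window of the sequence, on both strands, with the log-odds sum

    score(window) = sum_i log2( p'_i(letter_i) / bg(letter_i) )

where p' are the motif probabilities smoothed with a small pseudocount
(JASPAR matrices contain zeros).  The p-value of a score is the exact tail
probability of that score for a random word drawn from the background,
computed by dynamic programming over scores discretized to a grid fine
enough that the total discretization error is below 1e-3 score units;
reported scores live on the same grid, so p-values are exactly monotone in
the reported score.  Benjamini-Hochberg q-values are computed over all
scored windows of one (motif, sequence) scan.

``scan_alleles`` applies the scan to the two allelic versions of a sequence
around a SNP and classifies each motif's hits overlapping the SNP as
gained / lost / unchanged / absent-in-both.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifMatrix:
    """Letter-probability matrix with background and pseudocount."""

    name: str
    probs: np.ndarray                     # (width, 4) row-stochastic
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.001

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 2:
            raise ValueError(f"{self.name}: matrix must be (width >= 2) x 4")
        rowsum = self.probs.sum(axis=1)
        if np.abs(rowsum - 1.0).max() > 1e-4:
            bad = int(np.argmax(np.abs(rowsum - 1.0)))
            raise ValueError(f"{self.name}: row {bad + 1} sums to {rowsum[bad]:.4g}, not 1")
        self.probs = self.probs / rowsum[:, None]
        if abs(self.background.sum() - 1.0) > 1e-4:
            raise ValueError(f"{self.name}: background does not sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """(width, 4) log2 odds with pseudocount smoothing."""
        smoothed = (self.probs + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        return np.log2(smoothed / self.background[None, :])


@dataclass
class MotifHit:
    motif: str
    strand: str                  # "+" or "-"
    start: int                   # 1-based inclusive, forward strand
    end: int
    score: float                 # log2-odds, on the discretization grid
    p_value: float
    q_value: float
    matched_sequence: str        # forward-strand letters of the span


@dataclass
class AlleleComparison:
    """Per-motif differential hit status around one SNP."""

    variant: object
    ref_hits: dict[str, list[MotifHit]]    # hits overlapping the SNP
    alt_hits: dict[str, list[MotifHit]]
    status: dict[str, str]       # gained | lost | unchanged | absent-in-both


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------

_BG_RE = re.compile(r"^Background letter frequencies")
_MOTIF_RE = re.compile(r"^MOTIF\s+(.*)$")
_MATRIX_RE = re.compile(r"^letter-probability matrix:")


def read_meme_motifs(source: str | Path) -> list[MotifMatrix]:
    """Parse motifs from MEME minimal-format text (a path or the text itself)."""
    text = Path(source).read_text() if isinstance(source, Path) else str(source)
    if "\n" not in text and Path(text).exists():
        text = Path(text).read_text()
    lines = text.splitlines()
    background = np.full(4, 0.25)
    motifs: list[MotifMatrix] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if _BG_RE.match(line):
            fields = lines[i + 1].split()
            freqs = {fields[j]: float(fields[j + 1]) for j in range(0, len(fields), 2)}
            background = np.array([freqs.get(a, 0.25) for a in ALPHABET])
            i += 2
            continue
        m = _MOTIF_RE.match(line)
        if m:
            name = m.group(1).strip()
            i += 1
            while i < len(lines) and not _MATRIX_RE.match(lines[i].strip()):
                if _MOTIF_RE.match(lines[i].strip()):
                    raise ValueError(f"motif {name!r}: no letter-probability matrix")
                i += 1
            if i == len(lines):
                raise ValueError(f"motif {name!r}: no letter-probability matrix")
            header = lines[i].strip()
            wm = re.search(r"w=\s*(\d+)", header)
            i += 1
            rows = []
            while i < len(lines):
                fields = lines[i].split()
                if len(fields) != 4:
                    break
                try:
                    rows.append([float(x) for x in fields])
                except ValueError:
                    break
                i += 1
            if wm and int(wm.group(1)) != len(rows):
                raise ValueError(
                    f"motif {name!r}: header says w={wm.group(1)} but "
                    f"{len(rows)} rows parsed (line {i + 1})")
            try:
                motifs.append(MotifMatrix(name, np.array(rows), background.copy()))
            except ValueError as err:
                raise ValueError(f"line {i}: {err}") from err
            continue
        i += 1
    return motifs


# ---------------------------------------------------------------------------
# Exact p-values by DP over discretized scores
# ---------------------------------------------------------------------------

def _discretize(motif: MotifMatrix) -> tuple[np.ndarray, float]:
    """Integer score matrix and bin width; total rounding error < 1e-3."""
    delta = 1e-3 / motif.width
    ints = np.rint(motif.log_odds() / delta).astype(np.int64)
    return ints, delta


def score_distribution(int_scores: np.ndarray, background: np.ndarray
                       ) -> tuple[np.ndarray, int]:
    """Exact distribution of the total integer score of a background word.

    Returns ``(probs, lo)`` where ``probs[k]`` is the probability of total
    score ``lo + k``.
    """
    # repeated shift-add convolution; ranges are small for practical widths
    acc = np.ones(1)
    acc_lo = 0
    for row in int_scores:
        new_lo = acc_lo + int(row.min())
        new_hi = acc_lo + len(acc) - 1 + int(row.max())
        new = np.zeros(new_hi - new_lo + 1)
        for j in range(4):
            shift = acc_lo + int(row[j]) - new_lo
            new[shift:shift + len(acc)] += background[j] * acc
        acc, acc_lo = new, new_lo
    return acc, acc_lo


def _survival(int_scores: np.ndarray, background: np.ndarray
              ) -> tuple[np.ndarray, int]:
    dist, lo = score_distribution(int_scores, background)
    sf = np.cumsum(dist[::-1])[::-1]
    return sf, lo


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int64)
    for j, a in enumerate(ALPHABET):
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(a)] = j
    return codes


def scan_sequence(seq: str, motif: MotifMatrix, p_threshold: float = 1e-3,
                  both_strands: bool = True) -> list[MotifHit]:
    """Scan one sequence with one motif; return hits with p < threshold.

    Windows containing non-ACGT letters are skipped.  Coordinates are
    1-based inclusive on the forward strand for both strands;
    ``matched_sequence`` is always the forward-strand letters.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    seq = seq.upper()
    w = motif.width
    if len(seq) < w:
        return []
    ints, delta = _discretize(motif)
    sf, lo = _survival(ints, motif.background)

    raw: list[tuple[str, int, int]] = []   # (strand, fwd_start0, int_score)
    pvals: list[float] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        s = seq if strand == "+" else reverse_complement(seq)
        codes = _encode(s)
        ok = codes >= 0
        for pos in range(len(s) - w + 1):
            window = codes[pos:pos + w]
            if not ok[pos:pos + w].all():
                continue
            total = int(ints[np.arange(w), window].sum())
            p = float(sf[total - lo]) if total - lo < len(sf) else 0.0
            fwd_start = pos if strand == "+" else len(seq) - pos - w
            raw.append((strand, fwd_start, total))
            pvals.append(p)
    if not raw:
        return []
    qvals = bh_qvalues(pvals)
    hits = []
    for (strand, start0, total), p, q in zip(raw, pvals, qvals):
        if p < p_threshold:
            hits.append(MotifHit(
                motif=motif.name, strand=strand,
                start=start0 + 1, end=start0 + w,
                score=total * delta, p_value=p, q_value=q,
                matched_sequence=seq[start0:start0 + w]))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_alleles(seq: str, variant, offset_in_seq: int,
                 motifs: list[MotifMatrix], p_threshold: float = 1e-3,
                 window: int = 0) -> AlleleComparison:
    """Compare motif hits overlapping a SNP between its two alleles.

    ``offset_in_seq`` is the 1-based position of the variant in ``seq``.  A
    window of +/- (max motif width - 1) around the SNP, plus ``window``
    extra slack, is scanned for each allelic sequence; only hits whose
    footprint covers the SNP are compared.
    """
    if not 1 <= offset_in_seq <= len(seq):
        raise ValueError(f"offset {offset_in_seq} outside sequence of length {len(seq)}")
    seq = seq.upper()
    w_max = max(m.width for m in motifs)
    lo = max(1, offset_in_seq - (w_max - 1) - window)
    hi = min(len(seq), offset_in_seq + (w_max - 1) + window)
    pos_local = offset_in_seq - lo  # 0-based within the window

    ref_hits: dict[str, list[MotifHit]] = {}
    alt_hits: dict[str, list[MotifHit]] = {}
    any_hit: dict[str, bool] = {m.name: False for m in motifs}
    status: dict[str, str] = {}
    for allele, store in ((variant.ref_allele, ref_hits), (variant.alt_allele, alt_hits)):
        sub = seq[lo - 1:offset_in_seq - 1] + allele + seq[offset_in_seq:hi]
        for m in motifs:
            all_hits = scan_sequence(sub, m, p_threshold)
            any_hit[m.name] |= bool(all_hits)
            hits = [h for h in all_hits if h.start <= pos_local + 1 <= h.end]
            for h in hits:   # shift to coordinates of the full sequence
                h.start += lo - 1
                h.end += lo - 1
            store[m.name] = hits
    for m in motifs:
        has_ref, has_alt = bool(ref_hits[m.name]), bool(alt_hits[m.name])
        if has_ref and has_alt:
            status[m.name] = "unchanged"
        elif has_ref:
            status[m.name] = "lost"
        elif has_alt:
            status[m.name] = "gained"
        else:
            # hits that never touch the SNP are identical between alleles
            status[m.name] = "unchanged" if any_hit[m.name] else "absent-in-both"
    return AlleleComparison(variant=variant, ref_hits=ref_hits,
                            alt_hits=alt_hits, status=status)


def bh_qvalues(p_values) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1].tolist()
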