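#!/usr/bin/env python
"""Allele-aware transcription-factor motif screen on a synthetic sequence.

The curated intron sequence and the exact motif-library versions behind the
original screen are external inputs, so this driver demonstrates the engine
on a synthetic sequence: a forkhead-like consensus (GTAAACA, as bound by
FOXO1) is embedded so that the reference T allele of a T>C SNP completes
the site and the C allele destroys it, alongside an E-box (CAGCTG) that no
allele touches.  Writes results/motif_allele_comparison.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mstnpop import MotifMatrix, Variant, scan_alleles, write_summary

RESULTS = Path(__file__).resolve().parent.parent / "results"


def consensus(word: str, name: str) -> MotifMatrix:
    probs = np.full((len(word), 4), 0.01)
    for i, a in enumerate(word):
        probs[i] = 0.01 / 3
        probs[i, "ACGT".index(a)] = 0.99
    return MotifMatrix(name, probs / probs.sum(axis=1, keepdims=True))


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(0)
    flank = "".join(rng.choice(list("ACGT"), size=30))
    # synthetic locus: SNP at the 2nd letter of the forkhead site
    seq = flank + "GTAAACA" + "CCG" + "CAGCTG" + flank
    snp_pos = len(flank) + 2          # the T of GTAAACA, 1-based
    variant = Variant("snp_demo", f"c.373+{snp_pos}T>C", snp_pos, "T", "C")

    motifs = [consensus("GTAAACA", "FOXO1-like"),
              consensus("CAGCTG", "E-box")]
    cmp = scan_alleles(seq, variant, snp_pos, motifs, p_threshold=1e-3,
                       window=20)

    rows = []
    for m in motifs:
        rows.append({
            "motif": m.name,
            "status": cmp.status[m.name],
            "ref_hits": len(cmp.ref_hits[m.name]),
            "alt_hits": len(cmp.alt_hits[m.name]),
            "best_ref_p": min((h.p_value for h in cmp.ref_hits[m.name]),
                              default=float("nan")),
        })
    table = pd.DataFrame(rows)
    write_summary(table, RESULTS / "motif_allele_comparison.csv")
    print(table.to_string(index=False))
    print("\nthe reference T allele completes the forkhead site "
          "(lost with the C allele); the E-box lies outside the SNP "
          "footprint and is unchanged")


if __name__ == "__main__":
    main()
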