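#!/usr/bin/env python
"""Pairwise LD across the nine loci from the phased gamete pool.

Writes the long-format pair table (results/ld_pairs.csv) and the square r^2
matrix (results/ld_r2_matrix.csv).
"""

from pathlib import Path

from mstnpop import (em_phase, ld_long_table, ld_matrix, r2_square_table,
                     reconstruct_ucm_fixture, write_summary)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = em_phase(reconstruct_ucm_fixture()).table
    pairs = ld_matrix(table)
    long = ld_long_table(pairs)
    write_summary(long, RESULTS / "ld_pairs.csv")
    r2_square_table(pairs).to_csv(RESULTS / "ld_r2_matrix.csv",
                                  float_format="%.12g")

    strong = long[long.r2.round(3) == 1.0]
    print(f"{len(pairs)} locus pairs; |D'| = 1 for all of them "
          "(every pairwise association is complete in this small gamete pool,"
          " so D' carries no information here)")
    print(f"\npairs in complete LD (r^2 = 1, Fisher p = "
          f"{strong.fisher_p.iloc[0]:.3f}):")
    print(strong[["locus_a", "locus_b", "r2", "fisher_p"]]
          .to_string(index=False))
    novel = long[(long.locus_a == "rs7600797830") |
                 (long.locus_b == "rs7600797830")]
    print(f"\nnovel SNP rs7600797830: max r^2 with any other locus = "
          f"{novel.r2.max():.3f} (no linkage with the known loci)")


if __name__ == "__main__":
    main()
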