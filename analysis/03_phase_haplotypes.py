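#!/usr/bin/env python
"""EM haplotype phasing of the reconstructed cohort.

Infers the haplotype spectrum with the parsimony-refined EM and writes the
named haplotype table (results/haplotypes.csv) and per-animal maximum-
posterior phase assignments (results/phase_assignments.csv).
"""

from pathlib import Path

import pandas as pd

from mstnpop import (em_phase, haplotype_report, reconstruct_ucm_fixture,
                     write_summary)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = reconstruct_ucm_fixture()
    result = em_phase(cohort, tol=1e-8)

    report = haplotype_report(result.table)
    write_summary(report, RESULTS / "haplotypes.csv")

    assignments = pd.DataFrame([{
        "individual": a.individual, "hap_a": a.pair[0], "hap_b": a.pair[1],
        "posterior": a.posterior, "ambiguous": a.ambiguous,
    } for a in result.assignments])
    write_summary(assignments, RESULTS / "phase_assignments.csv")

    print(report[["name", "haplotype", "frequency_pct", "gamete_count",
                  "diffs_from_reference"]].to_string(index=False))
    print(f"\nlog-likelihood {result.loglik:.4f}, "
          f"{int(assignments.ambiguous.sum())} ambiguous assignment(s)")
    print("the dominant haplotype carries the reference allele at every locus;")
    print("its frequency exceeds the unphased reference-motif rate because "
          "phasing splits heterozygous animals into one reference and one "
          "variant-bearing gamete")


if __name__ == "__main__":
    main()
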