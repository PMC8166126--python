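#!/usr/bin/env python
"""Filter loci and MAP-fit the beta-binomial selection model.

Reads the simulated cohort from results/demo/, applies the heterozygote
caller and the locus inclusion filters (population MAF >= 0.005, at least
10 heterozygous samples), fits (pi, delta, phi, theta) per SNP, and writes
fits.tsv plus the filter report.
"""

from pathlib import Path

import numpy as np

from aiselect import fit_cohort
from aiselect.cohort import (
    attach_locus_annotations,
    filter_loci,
    read_annotation_table,
    read_count_table,
    set_het_mask,
    write_count_table,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "demo"


def main() -> None:
    cohort = set_het_mask(read_count_table(OUT / "counts.tsv"))
    cohort = attach_locus_annotations(
        cohort, read_annotation_table(OUT / "annotations.tsv"))
    cohort, report = filter_loci(cohort, maf_min=0.005, min_het=10)
    report.to_frame().to_csv(OUT / "filter_report.tsv", sep="\t", index=False,
                             lineterminator="\n")
    write_count_table(cohort, OUT / "counts.filtered.tsv")

    fits = fit_cohort(cohort)
    fits.to_csv(OUT / "fits.tsv", sep="\t", index=False, float_format="%.8g",
                lineterminator="\n")

    print("locus filtering:")
    for stage, n in report.stages:
        print(f"  {stage:<18} {n}")
    print(f"fitted {len(fits)} loci; {int(fits['converged'].sum())} converged")
    print(f"  pi_hat    : mean {fits['pi_hat'].mean():.3f}, "
          f"spread {fits['pi_hat'].std():.3f}")
    print(f"  phi_hat   : mean {fits['phi_hat'].mean():.3f} "
          f"(simulated mapping bias 0.52)")
    print(f"  theta_hat : median {fits['theta_hat'].median():.1f}")
    top = fits.reindex(np.abs(fits['pi_hat'] - 0.5).sort_values().index[::-1])
    print("  strongest allelic preference:")
    print(top.head(5)[["snp_id", "pi_hat", "n_het"]].to_string(index=False))


if __name__ == "__main__":
    main()
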