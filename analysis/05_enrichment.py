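#!/usr/bin/env python
"""Downstream enrichment of the selection calls.

Asks three questions of the called alleles: are selected alleles enriched
for predicted-deleterious variants (CADD > 10); do their germline
frequencies differ between the case cohort and the control population; and
do genes carrying selected-for alleles skew toward stronger CRISPR
dependency (lower scores)?
"""

from pathlib import Path

import pandas as pd

from aiselect import (
    case_allele_frequencies,
    classify_deleterious,
    ks_dependency_test,
    stratified_fraction_comparison,
)
from aiselect.cohort import (
    read_annotation_table,
    read_count_table,
    read_dependency_table,
    set_het_mask,
)
from aiselect.enrichment import frequency_calls

OUT = Path(__file__).resolve().parents[1] / "results" / "demo"
SEED = 20240917


def main() -> None:
    calls = pd.read_csv(OUT / "calls.tsv", sep="\t")
    ann = read_annotation_table(OUT / "annotations.tsv")
    ann["deleterious"] = classify_deleterious(ann["cadd"].to_numpy())

    table, pairwise = stratified_fraction_comparison(
        calls, ann, n_boot=500, seed=SEED)
    table.to_csv(OUT / "enrichment.tsv", sep="\t", index=False,
                 float_format="%.6g", lineterminator="\n")
    if pairwise is not None:
        pairwise.to_csv(OUT / "enrichment_pairwise.tsv", sep="\t", index=False,
                        float_format="%.6g", lineterminator="\n")
    print("deleteriousness enrichment by stratum:")
    print(table[["direction", "level", "n_stratum", "fraction_selected",
                 "fraction_background", "ratio", "p"]].to_string(index=False))

    cohort = set_het_mask(read_count_table(OUT / "counts.filtered.tsv"))
    freq = frequency_calls(case_allele_frequencies(cohort), ann)
    freq.to_csv(OUT / "frequency_calls.tsv", sep="\t", index=False,
                float_format="%.6g", lineterminator="\n")
    merged = freq.merge(calls, on="snp_id")
    sel_for = merged[merged.direction == "selected_for"]
    print(f"\ncase/control frequency: {int((freq.freq_direction == 'higher').sum())} "
          f"alleles higher in cancer (q < 0.05), of which "
          f"{int((sel_for.freq_direction == 'higher').sum())} are selected-for")

    dep = read_dependency_table(OUT / "dependency.tsv")
    genes_sel = ann.merge(calls, on="snp_id")
    picked = genes_sel.loc[genes_sel["sig_0.05"]
                           & (genes_sel.direction == "selected_for"),
                           "gene"].unique()
    scores = dep.set_index("gene")["dependency_score"]
    d, p = ks_dependency_test(scores.reindex(picked).dropna(),
                              scores, alternative="less")
    print(f"gene dependency (selected-for vs background): "
          f"KS D = {d:.3f}, one-sided P = {p:.4g} "
          f"({len(picked)} genes vs {len(scores)})")


if __name__ == "__main__":
    main()
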