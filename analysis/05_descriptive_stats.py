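#!/usr/bin/env python
"""Descriptive tables and stratified correlation heatmap data.

Emits the per-gender numeric/categorical summary tables (normality-gated
mean±SD vs median(range) formatting, test-selection rule for p-values) and
the gender- and diabetes-stratified Pearson correlation matrices.
"""

from pathlib import Path

from safref.cohort import read_cohort
from safref.cohort_stats import correlation_matrix, summarize_cohort

OUT = Path("results/analysis")
CORR_VARS = ["age", "height", "weight", "bmi", "waist", "hip", "whr",
             "sbp", "dbp", "sr", "saf"]


def main() -> None:
    cohort = read_cohort(OUT / "cohort.tsv")
    tables = summarize_cohort(cohort)
    tables["numeric"].to_csv(OUT / "summary_numeric.tsv", sep="\t", index=False)
    tables["categorical"].to_csv(OUT / "summary_categorical.tsv", sep="\t",
                                 index=False)
    print(tables["numeric"].to_string(index=False))
    print()
    print(tables["categorical"].to_string(index=False))

    for split in ("gender", "diabetes"):
        cm = correlation_matrix(cohort, CORR_VARS, split_by=split)
        cm.to_frame().to_csv(OUT / f"correlation_{split}.tsv", sep="\t")
        cm.to_long().to_csv(OUT / f"correlation_{split}_long.tsv", sep="\t",
                            index=False)
    cm = correlation_matrix(cohort, ["weight", "bmi", "waist", "hip"])
    print(f"\nanthropometric block (upper = women, lower = men):\n"
          f"{cm.to_frame().round(2)}")


if __name__ == "__main__":
    main()
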