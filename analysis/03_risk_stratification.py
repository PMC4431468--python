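#!/usr/bin/env python
"""Gender/SR-specific CVD risk grouping and scheme comparison.

Builds the proposed mean+1SD / mean+2SD scheme from the simulated cohort's
own reference curves and contrasts its risk-group distribution with the
packaged *synthetic placeholder* conventional scheme (the published
conventional coefficients were never printed; the placeholder only
exercises the comparison machinery).  Writes risk_distribution.tsv.
"""

import importlib.resources
from pathlib import Path

from safref.cohort import read_cohort
from safref.reference import compute_stratum_stats, fit_reference_curve
from safref.risk import build_scheme, compare_schemes, read_scheme, write_scheme

OUT = Path("results/analysis")


def main() -> None:
    cohort = read_cohort(OUT / "cohort.tsv")
    by_sr = compute_stratum_stats(cohort, by="gender_sr")
    curves = {
        "men": fit_reference_curve(by_sr, gender="M", stratum_label="men"),
        "women_low_sr": fit_reference_curve(by_sr, gender="F", label="low_sr",
                                            stratum_label="women_low_sr"),
        "women_high_sr": fit_reference_curve(by_sr, gender="F", label="high_sr",
                                             stratum_label="women_high_sr"),
    }
    proposed = build_scheme(curves)
    write_scheme(proposed, OUT / "scheme_proposed.yaml")

    conventional = read_scheme(str(importlib.resources.files("safref.data")
                                   .joinpath("conventional_scheme_synthetic.yaml")))
    dist, migrations = compare_schemes(cohort, [proposed, conventional])
    dist.to_csv(OUT / "risk_distribution.tsv", sep="\t", index=False)

    for scheme in dist.scheme.unique():
        print(f"\n{scheme}:")
        sub = dist[dist.scheme == scheme]
        for stratum in sub.stratum.unique():
            row = sub[sub.stratum == stratum]
            parts = ", ".join(f"group {g}: {c} ({p:.0f}%)" for g, c, p in
                              zip(row.group, row["count"], row.percent))
            print(f"  {stratum:>14}: {parts}")
    (a, b), tab = next(iter(migrations.items()))
    print(f"\nmigration {a} → {b}:\n{tab}")
    print("\nunder a self-calibrated mean+kSD scheme the cohort lands near "
          "the normal-theory 84/14/2 split in every stratum, by construction")


if __name__ == "__main__":
    main()
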