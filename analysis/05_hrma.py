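"""HRMA of the simulated melt curves: normalization, difference curves, peaks.

Normalizes all replicate traces between the first and last 1 degC of the
acquisition range, subtracts the WT baseline (two WT samples in triplicate),
and reports each line's maximum fluorescence difference to WT and melt peak
temperatures.  Writes results/hrma_summary.tsv.
"""

import pandas as pd

from common import RESULTS, SCRATCH
from polyedit import difference_curves
from polyedit.datasets import example_cohort
from polyedit.io import read_melt_curves


def main() -> None:
    curves = read_melt_curves(SCRATCH / "melt_curves.csv", wt_sample_ids=["WT", "WT2"])
    res = difference_curves(curves)
    cohort = example_cohort()
    rows = []
    for sample in curves.samples:
        planted = 100 * sum(e.frequency for e in cohort[sample].edits) if sample in cohort else 0.0
        rows.append(
            (
                sample,
                round(res.max_fluor_diff[sample], 1),
                ", ".join(f"{t:.1f}" for t in res.melt_peak_temps[sample]),
                round(planted, 1),
            )
        )
    df = pd.DataFrame(rows, columns=["line_id", "max_fluor_diff", "melt_peak_temps_c", "planted_pct"])
    df.to_csv(RESULTS / "hrma_summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print("\nWT-vs-WT differences stay near zero; mutant lines separate from the")
    print("baseline with the difference growing with planted frequency.")


if __name__ == "__main__":
    main()
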