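"""Score the simulated RNP-digest gel lanes.

dGV (mean grey value of cleaved product(s) minus non-cleaved product) maps
to the categorical 0-5 score; the cohort lanes were simulated with the
cleaved fraction equal to each line's WT fraction.  Writes
results/rnp_scores.tsv.
"""

import pandas as pd

from common import RESULTS
from polyedit import delta_gv, score
from polyedit.datasets import example_cohort
from polyedit.io import read_gel_lanes


def main() -> None:
    cohort = example_cohort()
    lanes = read_gel_lanes(RESULTS / "data" / "gel_lanes.csv")
    rows = []
    for lane in lanes:
        res = score(lane)
        truth = 100 * sum(e.frequency for e in cohort[lane.sample].edits)
        rows.append((lane.sample, round(delta_gv(lane), 1), res.score, res.frequency_band, round(truth, 1)))
    df = pd.DataFrame(rows, columns=["line_id", "delta_gv", "score", "frequency_band", "planted_pct"])
    df.to_csv(RESULTS / "rnp_scores.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print("\nScores are semi-quantitative: the band maps onto the planted frequency,")
    print("with ~25%-wide bins and no indel-size information.")


if __name__ == "__main__":
    main()
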