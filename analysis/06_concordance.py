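"""Cross-method comparison, chimerism screen, and per-sample cost model.

Assembles one row per line from the sequencing, fragment-analysis, RNP and
HRMA outputs; screens a simulated chimeric event from three vegetative
progenies; and evaluates the cost model on a synthetic price table
(results/data/cost_table_synthetic.csv — synthetic prices, not a quote).
Writes results/concordance.tsv and results/cost_per_sample.tsv.
"""

import logging

import pandas as pd

from common import COHORT_SEED, RESULTS, SCRATCH, cohort_reads
from polyedit import (
    LineResult,
    SimulationConfig,
    concordance_table,
    cost_per_sample,
    cs_spectrum,
    define_wt_peaks,
    detect_chimerism,
    difference_curves,
    indel_frequencies,
    score,
    simulate_reads,
)
from polyedit.datasets import example_assay, example_cohort, chimeric_event
from polyedit.io import read_gel_lanes, read_melt_curves, read_peak_table
from polyedit.window_indel import spectrum_with_rerun


def main() -> None:
    logging.getLogger("polyedit").setLevel(logging.ERROR)
    cohort = example_cohort()
    reads = cohort_reads()
    assay = example_assay(R=35)
    lanes = {l.sample: l for l in read_gel_lanes(RESULTS / "data" / "gel_lanes.csv")}
    tables = {lid: read_peak_table(RESULTS / "data" / f"peaks_{lid}.csv")[0] for lid in cohort}
    ce_ref = define_wt_peaks(tables["WT"])
    hrma = difference_curves(read_melt_curves(SCRATCH / "melt_curves.csv", wt_sample_ids=["WT", "WT2"]))

    results = []
    for lid in cohort:
        line_assay = example_assay(R=35, dual=True) if lid == "L44" else assay
        results.append(
            LineResult(
                lid,
                cs=cs_spectrum(reads[lid], assay),
                window=spectrum_with_rerun(reads[lid], line_assay, rerun_R=70),
                ce=indel_frequencies(tables[lid], ce_ref),
                rnp=score(lanes[lid]),
                hrma_max_diff=hrma.max_fluor_diff[lid],
                melt_peak_temps=hrma.melt_peak_temps[lid],
            )
        )
    table = concordance_table(results)
    table.to_csv(RESULTS / "concordance.tsv", sep="\t", index=False)
    print(table.round(1).to_string(index=False))

    # chimerism screen on three vegetative progenies of one event
    progeny_results = []
    for i, (pid, pop) in enumerate(chimeric_event().items()):
        cfg = SimulationConfig(n_reads=5000, seed=COHORT_SEED + 1000 + i)
        prog_reads = [str(r.seq) for r in simulate_reads(pop, cfg)]
        progeny_results.append(LineResult(f"E1{pid}", cs=cs_spectrum(prog_reads, assay)))
    verdict = detect_chimerism(progeny_results)
    freqs = [round(100 * p.cs.overall_non_wt_frequency, 1) for p in progeny_results]
    print(f"\nChimerism screen: progenies at {freqs}% non-WT -> {verdict}")

    # synthetic cost table: plausible magnitudes, labelled synthetic
    cost = pd.DataFrame(
        [
            ("labelled primer + PCR", 45.0, 96, "ce", 1),
            ("fragment-analysis service", 280.0, 96, "ce", 1),
            ("hrm master mix", 250.0, 200, "hrma", 3),
            ("primers", 30.0, 300, "hrma", 3),
            ("cas9 protein", 650.0, 100, "rnp", 1),
            ("sgRNA synthesis", 380.0, 50, "rnp", 1),
            ("pcr + gel", 60.0, 96, "rnp", 1),
            ("amplicon sequencing service", 6000.0, 96, "ngs", 1),
        ],
        columns=["component", "pack_price", "reactions_per_pack", "method", "replicates_per_sample"],
    )
    cost.to_csv(RESULTS / "data" / "cost_table_synthetic.csv", index=False)
    costs = {m: cost_per_sample(cost, m) for m in ("ce", "hrma", "rnp", "ngs")}
    pd.DataFrame(sorted(costs.items()), columns=["method", "usd_per_sample"]).to_csv(
        RESULTS / "cost_per_sample.tsv", sep="\t", index=False
    )
    print("\nPer-sample cost (synthetic prices): "
          + ", ".join(f"{m} ${c:.2f}" for m, c in costs.items()))


if __name__ == "__main__":
    main()
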