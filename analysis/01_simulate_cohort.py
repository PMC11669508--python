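"""Simulate the study cohort: reads, peak tables, gel lanes, melt curves.

Writes the ground-truth table to results/cohort_truth.csv, the instrument
tables (CE peaks, gel lanes, melt curves) to results/data/, and the FASTQ
files (larger, regenerable) to scratch/fastq/.
"""

import pandas as pd

from common import COHORT_SEED, N_READS, RESULTS, SCRATCH, line_seed
from polyedit import SimulationConfig, simulate_gel_lane, simulate_melt_curves, simulate_peak_table, simulate_reads
from polyedit.datasets import default_tm_map, example_cohort
from polyedit.io import write_fastq, write_gel_lanes, write_melt_curves, write_peak_table


def main() -> None:
    (RESULTS / "data").mkdir(parents=True, exist_ok=True)
    (SCRATCH / "fastq").mkdir(parents=True, exist_ok=True)
    cohort = example_cohort()

    truth_rows = []
    lanes = []
    pops, tms = {}, {}
    for i, (line_id, pop) in enumerate(cohort.items()):
        cfg = SimulationConfig(n_reads=N_READS, seed=line_seed(i))
        write_fastq(simulate_reads(pop, cfg), SCRATCH / "fastq" / f"{line_id}.fastq")
        write_peak_table(simulate_peak_table(pop, cfg, line_id), RESULTS / "data" / f"peaks_{line_id}.csv")
        mutant_fraction = sum(e.frequency for e in pop.edits)
        lanes.append(simulate_gel_lane(1.0 - mutant_fraction, cfg=cfg, sample=line_id))
        pops[line_id] = pop
        tms[line_id] = default_tm_map(pop)
        for e in pop.edits:
            truth_rows.append((line_id, e.size_delta, e.frequency))
        truth_rows.append((line_id, 0, pop.wt_fraction))
    write_gel_lanes(lanes, RESULTS / "data" / "gel_lanes.csv")

    pops["WT2"] = pops["WT"]
    tms["WT2"] = tms["WT"]
    curves = simulate_melt_curves(pops, tms, SimulationConfig(seed=COHORT_SEED), wt_sample_ids=["WT", "WT2"])
    write_melt_curves(curves, SCRATCH / "melt_curves.csv")

    truth = pd.DataFrame(truth_rows, columns=["line_id", "size_delta", "frequency"])
    truth.to_csv(RESULTS / "cohort_truth.csv", index=False)
    print(f"Simulated {len(cohort)} lines x {N_READS} reads (seed {COHORT_SEED}).")
    print("Planted allele classes per line:")
    print(truth.to_string(index=False))


if __name__ == "__main__":
    main()
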