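"""Shared setup for the analysis drivers: the simulated cohort and its seeds.

The cohort (`polyedit.datasets.example_cohort`) is a panel of synthetic lines
whose planted indel spectra cover the frequency (~3%-100%) and size
(-54..+3 bp) ranges of interest.  Every driver derives its per-line seeds
from COHORT_SEED so the scripts agree on the same simulated experiment.
"""

from pathlib import Path

from polyedit import SimulationConfig, simulate_reads
from polyedit.datasets import example_cohort

COHORT_SEED = 20_240
N_READS = 20_000

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def line_seed(index: int) -> int:
    return COHORT_SEED + 97 * (index + 1)


def cohort_reads() -> dict[str, list[str]]:
    """Simulated amplicon reads per line, deterministic across drivers."""
    reads = {}
    for i, (line_id, pop) in enumerate(example_cohort().items()):
        cfg = SimulationConfig(n_reads=N_READS, seed=line_seed(i))
        reads[line_id] = [str(r.seq) for r in simulate_reads(pop, cfg)]
    return reads
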