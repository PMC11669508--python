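"""Ready-made synthetic assays and line populations.

A deterministic 227 bp reference amplicon stands in for a sugarcane target
region: primer at the 5' end, conserved sequence 160 bp downstream of the
primer, Cas9 cut site at position 110 (and a second site at 130 for the
dual-sgRNA amplicon).  The example populations plant indel spectra spanning
the ranges seen in polyploid editing experiments — frequencies from ~3% to
100%, sizes from -54 to +3 bp — including the configurations that expose
each method's documented failure mode.
"""

from __future__ import annotations

import numpy as np

from .assay import AssayDefinition
from .population import AllelePopulation, Edit

__all__ = [
    "example_reference",
    "example_assay",
    "single_wt_population",
    "recovery_population",
    "multi_wt_population",
    "large_deletion_population",
    "spanning_population",
    "low_frequency_population",
    "example_cohort",
    "chimeric_event",
    "default_tm_map",
    "CUT_SITE",
    "SECOND_CUT_SITE",
    "WT_DISTANCE",
    "AMPLICON_LENGTH",
]

AMPLICON_LENGTH = 227
PRIMER_LENGTH = 20
WT_DISTANCE = 160       # primer start to conserved-sequence start in WT reads
CS_LENGTH = 20
CUT_SITE = 110
SECOND_CUT_SITE = 130   # dual-sgRNA amplicon geometry (sites 20 bp apart)

_REFERENCE_SEED = 11


def example_reference(length: int = AMPLICON_LENGTH, seed: int = _REFERENCE_SEED) -> str:
    """Deterministic reference amplicon with unique anchor k-mers."""
    rng = np.random.default_rng(seed)
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=length))
        kmers = {seq[i : i + 12] for i in range(length - 11)}
        if len(kmers) == length - 11:  # every 12-mer unique -> unambiguous anchors
            return seq


def example_assay(
    R: int = 35,
    dual: bool = False,
    name: str | None = None,
    reference: str | None = None,
) -> AssayDefinition:
    ref = reference or example_reference()
    return AssayDefinition(
        name=name or ("demo_dual" if dual else "demo"),
        primer=ref[:PRIMER_LENGTH],
        conserved_seq=ref[WT_DISTANCE : WT_DISTANCE + CS_LENGTH],
        wt_distance=WT_DISTANCE,
        target_site=CUT_SITE,
        comparison_range_R=R,
        wt_sequence=ref,
        second_target_site=SECOND_CUT_SITE if dual else None,
        expected_wt_amplicon_lengths=(len(ref),),
    )


def single_wt_population() -> AllelePopulation:
    return AllelePopulation([(example_reference(), 1.0)], [], cut_site=CUT_SITE)


def recovery_population() -> AllelePopulation:
    """The parameter-recovery condition: planted {+1: 30%, -3: 15%}."""
    return AllelePopulation(
        [(example_reference(), 0.55)],
        [Edit(+1, "A", 0, 0.30), Edit(-3, "", -1, 0.15)],
        cut_site=CUT_SITE,
    )


def _flip(base: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[base]


def _substitute(seq: str, pos: int) -> str:
    return seq[:pos] + _flip(seq[pos]) + seq[pos + 1 :]


def multi_wt_population(minus1_fraction: float = 0.2) -> AllelePopulation:
    """Multi-length WT amplicons (227 main, 226 and 231 variants) plus a
    planted 1 bp deletion at the cut.

    The 226 bp WT variant sits exactly where a -1 mutant peak lands, so
    fragment analysis absorbs the planted deletion into the WT class.  The
    variants carry substitutions inside the conserved-sequence and indicator
    anchors, so — as for real intron-derived variants — the sequencing
    callers never see them.
    """
    ref = example_reference()
    var226 = _substitute(_substitute(ref[:200] + ref[201:], 170), 150)
    var231 = _substitute(_substitute(ref[:205] + "ACGT" + ref[205:], 170), 150)
    wt_total = 1.0 - minus1_fraction
    return AllelePopulation(
        [(ref, wt_total * 0.875), (var226, wt_total * 0.100), (var231, wt_total * 0.025)],
        [Edit(-1, "", 0, minus1_fraction)],
        cut_site=CUT_SITE,
    )


def large_deletion_population(deletion_fraction: float = 0.20) -> AllelePopulation:
    """A 54 bp deletion reaching across the left indicator (plus common small
    indels): invisible to the window caller at R = 35, recovered at R = 70."""
    return AllelePopulation(
        [(example_reference(), 1.0 - deletion_fraction - 0.29 - 0.13)],
        [
            Edit(-54, "", -40, deletion_fraction),
            Edit(+1, "T", 0, 0.29),
            Edit(-1, "", 0, 0.13),
        ],
        cut_site=CUT_SITE,
    )


def spanning_population() -> AllelePopulation:
    """Dual-sgRNA amplicon with a 43 bp deletion covering both cut sites."""
    return AllelePopulation(
        [(example_reference(), 0.34)],
        [Edit(-43, "", -10, 0.55), Edit(-2, "", 0, 0.11)],
        cut_site=CUT_SITE,
    )


def low_frequency_population(frequency: float = 0.028) -> AllelePopulation:
    """The detection floor: a +2 insertion at ~3% of the allele pool."""
    return AllelePopulation(
        [(example_reference(), 1.0 - frequency)],
        [Edit(+2, "TT", 0, frequency)],
        cut_site=CUT_SITE,
    )


def example_cohort() -> dict[str, AllelePopulation]:
    """A study-like panel of lines covering the frequency and size ranges."""
    ref = example_reference()
    return {
        "WT": single_wt_population(),
        "D1": recovery_population(),
        "N8": AllelePopulation(
            [(ref, 0.52)],
            [
                Edit(+1, "A", 0, 0.17),
                Edit(-1, "", 0, 0.02),
                Edit(-2, "", -1, 0.15),
                Edit(-12, "", -6, 0.14),
            ],
            cut_site=CUT_SITE,
        ),
        "T82": low_frequency_population(),
        "L11": large_deletion_population(),
        "L44": spanning_population(),
    }


def chimeric_event(mutant_fraction: float = 0.79) -> dict[str, AllelePopulation]:
    """Three vegetative progenies of one event: two uniformly mutated, one WT
    (the signature of a chimeric primary transformant)."""
    ref = example_reference()
    mutant = AllelePopulation(
        [(ref, 1.0 - mutant_fraction)],
        [Edit(+1, "A", 0, mutant_fraction * 0.6), Edit(-2, "", -1, mutant_fraction * 0.4)],
        cut_site=CUT_SITE,
    )
    return {"a": mutant, "b": mutant, "c": single_wt_population()}


def default_tm_map(pop: AllelePopulation, wt_tm: float = 82.3) -> dict[str, float]:
    """Melt temperatures per allele: edited alleles melt below WT, with the
    shift growing slowly with indel size (saturating at 3.4 degC)."""
    tms = {}
    for a in pop.alleles():
        if a.label.startswith("wt"):
            tms[a.label] = wt_tm
        else:
            tms[a.label] = wt_tm - (1.0 + 0.08 * min(abs(a.size_delta), 30))
    return tms
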