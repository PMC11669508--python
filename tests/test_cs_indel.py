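"""Conserved-sequence caller: anchor logic, the 1% filter, and oracle equivalence."""

import math
from collections import Counter

import pytest

from polyedit import AllelePopulation, Edit, SimulationConfig, cs_call_read, cs_spectrum, simulate_reads
from polyedit.cs_indel import UNCALLABLE, WT
from polyedit.datasets import CUT_SITE, WT_DISTANCE
from polyedit.spectrum import NoCallableReadsError


def brute_force_cs_histogram(reads, assay):
    """Independent oracle: enumerate all anchor positions with a plain scan
    and histogram the distance deviations."""
    hist = Counter()
    callable_reads = 0
    for read in reads:
        p_positions = [i for i in range(len(read)) if read.startswith(assay.primer, i)]
        if not p_positions:
            continue
        p = p_positions[0]
        c_positions = [
            i for i in range(p + len(assay.primer), len(read))
            if read.startswith(assay.conserved_seq, i)
        ]
        if not c_positions:
            continue
        callable_reads += 1
        delta = (c_positions[0] - p) - assay.wt_distance
        if delta != 0:
            hist[delta] += 1
    return hist, callable_reads


def test_wt_read_calls_wt(assay, reference):
    assert cs_call_read(reference, assay) == WT


def test_large_deletion_between_anchors(assay, reference):
    # a 28 bp deletion at the cut, the largest class seen at one target
    pop = AllelePopulation([(reference, 0.5)], [Edit(-28, "", -20, 0.5)], cut_site=CUT_SITE)
    read = pop.alleles()[1].sequence
    assert cs_call_read(read, assay) == -28


def test_deletion_spanning_conserved_sequence_is_uncallable(assay, reference):
    # delete a window covering the conserved sequence entirely
    start = WT_DISTANCE - 5
    read = reference[:start] + reference[start + 30:]
    assert assay.conserved_seq not in read  # direct string check
    assert cs_call_read(read, assay) == UNCALLABLE


def test_missing_primer_is_uncallable(assay, reference):
    assert cs_call_read(reference[25:], assay) == UNCALLABLE


def test_all_wt_spectrum_is_empty(assay, reference):
    spec = cs_spectrum([reference] * 1000, assay)
    assert spec.calls == []
    assert spec.overall_non_wt_frequency == 0.0
    assert spec.callable_reads == 1000


def test_no_callable_reads_raises_with_assay_name(assay):
    with pytest.raises(NoCallableReadsError, match=assay.name):
        cs_spectrum(["ACGT" * 40], assay)


def test_planted_spectrum_recovered_within_binomial_bounds(planted_reads, assay):
    spec = cs_spectrum(planted_reads, assay)
    n = spec.callable_reads
    for delta, truth in ((+1, 0.30), (-3, 0.15)):
        sd = math.sqrt(truth * (1 - truth) / n)
        assert abs(spec.frequency_of(delta) - truth) <= 3 * sd


def test_subthreshold_noise_in_overall_but_not_breakdown(planted_reads, assay):
    spec = cs_spectrum(planted_reads, assay)
    reported = {c.size_delta for c in spec.calls}
    assert reported == {+1, -3}  # background ±1-2 bp classes filtered out
    breakdown_sum = sum(c.frequency for c in spec.calls)
    assert spec.overall_non_wt_frequency > breakdown_sum


def test_no_subthreshold_classes_means_breakdown_equals_overall(assay, reference):
    # noiseless reads: the reported classes account for every non-WT read
    pop = AllelePopulation(
        [(reference, 0.4)], [Edit(+1, "A", 0, 0.35), Edit(-2, "", 0, 0.25)], cut_site=CUT_SITE
    )
    cfg = SimulationConfig(n_reads=2000, seed=5, substitution_rate=0.0, read_indel_rate=0.0)
    reads = [str(r.seq) for r in simulate_reads(pop, cfg)]
    spec = cs_spectrum(reads, assay)
    assert sum(c.frequency for c in spec.calls) == pytest.approx(spec.overall_non_wt_frequency)


def test_filter_monotonicity(planted_reads, assay):
    base = cs_spectrum(planted_reads, assay, min_report_freq=0.0)
    prev = len(base.calls)
    for thr in (0.001, 0.01, 0.1, 0.5):
        spec = cs_spectrum(planted_reads, assay, min_report_freq=thr)
        assert len(spec.calls) <= prev
        assert spec.overall_non_wt_frequency == base.overall_non_wt_frequency
        prev = len(spec.calls)


def test_substitutions_between_anchors_do_not_change_frequencies(assay, reference):
    pop = AllelePopulation([(reference, 0.7)], [Edit(+1, "A", 0, 0.3)], cut_site=CUT_SITE)
    clean_cfg = SimulationConfig(n_reads=3000, seed=3, substitution_rate=0.0, read_indel_rate=0.0)
    clean = [str(r.seq) for r in simulate_reads(pop, clean_cfg)]
    # substitute a base midway between the anchors in every read, away from both
    noisy = [r[:60] + ("A" if r[60] != "A" else "C") + r[61:] for r in clean]
    s_clean = cs_spectrum(clean, assay)
    s_noisy = cs_spectrum(noisy, assay)
    assert s_clean.frequency_of(+1) == s_noisy.frequency_of(+1)
    assert s_clean.callable_reads == s_noisy.callable_reads


def test_matches_brute_force_oracle_exactly(assay, planted_population):
    cfg = SimulationConfig(n_reads=200, seed=17)
    reads = [str(r.seq) for r in simulate_reads(planted_population, cfg)]
    hist, callable_reads = brute_force_cs_histogram(reads, assay)
    spec = cs_spectrum(reads, assay, min_report_freq=0.0)
    assert spec.callable_reads == callable_reads
    assert {c.size_delta: c.count for c in spec.calls} == dict(hist)


def test_mismatch_tolerance_rescues_snp_in_anchor(assay, reference):
    # one SNP inside the primer: uncallable exactly, callable at k=1
    snp = ("A" if reference[5] != "A" else "C")
    read = reference[:5] + snp + reference[6:]
    assert cs_call_read(read, assay) == UNCALLABLE
    assert cs_call_read(read, assay, max_anchor_mismatches=1) == WT
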