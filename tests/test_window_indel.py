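"""Indicator-window caller: bracketing, R limits, rerun merging, substitutions."""

import math
from collections import Counter

import pytest

from polyedit import (
    AllelePopulation,
    Edit,
    SimulationConfig,
    WindowCall,
    cs_spectrum,
    merge_rerun,
    simulate_reads,
    window_call_read,
    window_spectrum,
)
from polyedit.datasets import CUT_SITE, example_assay, spanning_population
from polyedit.spectrum import IndelCall, IndelSpectrum
from polyedit.window_indel import SUBSTITUTION, UNMATCHED, WT, spectrum_with_rerun


def brute_force_window_histogram(reads, assay):
    """Independent oracle: plain substring scan for both indicators and a
    histogram of inter-indicator segment length deviations."""
    left, right = assay.indicators()
    expected_len = 2 * assay.comparison_range_R
    hist = Counter()
    callable_reads = 0
    for read in reads:
        li = read.find(left)
        if li < 0:
            continue
        ri = read.find(right, li + len(left))
        if ri < 0:
            continue
        delta = (ri - li - len(left)) - expected_len
        if abs(delta) > assay.comparison_range_R:
            continue
        callable_reads += 1
        if delta != 0:
            hist[delta] += 1
    return hist, callable_reads


def test_wt_read_calls_wt(assay, reference):
    assert window_call_read(reference, assay) == WT


def test_planted_deletion_sequence_extracted(assay, reference):
    # a 12 bp deletion at the cut reports the deleted bases in lower case
    pop = AllelePopulation([(reference, 0.5)], [Edit(-12, "", -6, 0.5)], cut_site=CUT_SITE)
    read = pop.alleles()[1].sequence
    call = window_call_read(read, assay)
    assert isinstance(call, WindowCall)
    assert call.size_delta == -12
    start = CUT_SITE - 6
    assert call.indel_sequence == reference[start : start + 12].lower()


def test_insertion_sequence_extracted(assay, reference):
    pop = AllelePopulation([(reference, 0.5)], [Edit(+3, "GGG", 0, 0.5)], cut_site=CUT_SITE)
    read = pop.alleles()[1].sequence
    call = window_call_read(read, assay)
    assert call.size_delta == +3
    assert set(call.indel_sequence) == {"g"}
    assert len(call.indel_sequence) == 3


def test_large_deletion_unmatched_at_default_range_called_at_wide(reference):
    pop = AllelePopulation([(reference, 0.8)], [Edit(-54, "", -40, 0.2)], cut_site=CUT_SITE)
    read = pop.alleles()[1].sequence
    assert window_call_read(read, example_assay(R=35)) == UNMATCHED
    call = window_call_read(read, example_assay(R=70))
    assert call.size_delta == -54


def test_equal_length_substitution_is_separate_bucket(assay, reference):
    mutated = reference[:CUT_SITE] + ("A" if reference[CUT_SITE] != "A" else "C") + reference[CUT_SITE + 1 :]
    assert window_call_read(mutated, assay) == SUBSTITUTION
    spec = window_spectrum([reference, mutated], assay)
    assert spec.calls == []
    assert spec.substitution_frequency == pytest.approx(0.5)


def test_spanning_deletion_flagged():
    dual = example_assay(R=70, dual=True)
    pop = spanning_population()
    read = pop.alleles()[1].sequence  # the -43 spanning both cut sites
    call = window_call_read(read, dual)
    assert call.size_delta == -43
    assert call.spans_both_sites


def test_planted_spectrum_recovered_within_binomial_bounds(planted_reads, assay):
    spec = window_spectrum(planted_reads, assay)
    n = spec.callable_reads
    for delta, truth in ((+1, 0.30), (-3, 0.15)):
        sd = math.sqrt(truth * (1 - truth) / n)
        assert abs(spec.frequency_of(delta) - truth) <= 3 * sd


def test_cs_and_window_overall_agree_on_contained_indels(planted_reads, assay):
    cs = cs_spectrum(planted_reads, assay)
    win = window_spectrum(planted_reads, assay)
    # indels sit strictly between both anchor pairs, so up to each method's
    # noise filtering the two denominators see the same signal
    assert win.overall_non_wt_frequency == pytest.approx(cs.overall_non_wt_frequency, abs=0.01)


def test_merge_rerun_arithmetic():
    primary = IndelSpectrum(
        calls=[IndelCall(-1, 100, 0.1)], overall_non_wt_frequency=0.1,
        callable_reads=1000, total_reads=1500,
    )
    rerun = IndelSpectrum(
        calls=[IndelCall(-43, 50, 0.1)], overall_non_wt_frequency=0.1,
        callable_reads=500, total_reads=1500,
    )
    merged = merge_rerun(primary, rerun)
    assert merged.callable_reads == 1500
    assert merged.frequency_of(-1) == pytest.approx(100 / 1500)
    assert merged.frequency_of(-43) == pytest.approx(50 / 1500)
    assert merged.overall_non_wt_frequency == pytest.approx(150 / 1500)


def test_merge_rerun_empty_identity():
    primary = IndelSpectrum(
        calls=[IndelCall(-1, 100, 0.1)], overall_non_wt_frequency=0.1,
        callable_reads=1000, total_reads=1000,
    )
    empty = IndelSpectrum(calls=[], overall_non_wt_frequency=0.0, callable_reads=0, total_reads=0)
    assert merge_rerun(primary, empty) is primary


def test_rerun_recovers_large_deletions_and_raises_overall(reference):
    pop = AllelePopulation(
        [(reference, 0.6)],
        [Edit(-54, "", -40, 0.2), Edit(+1, "T", 0, 0.2)],
        cut_site=CUT_SITE,
    )
    cfg = SimulationConfig(n_reads=4000, seed=7)
    reads = [str(r.seq) for r in simulate_reads(pop, cfg)]
    assay = example_assay(R=35)
    primary = window_spectrum(reads, assay)
    assert primary.frequency_of(-54) == 0.0
    merged = spectrum_with_rerun(reads, assay, rerun_R=70)
    assert merged.frequency_of(-54) > 0.15
    assert merged.overall_non_wt_frequency > primary.overall_non_wt_frequency


def test_matches_brute_force_oracle_exactly(assay, planted_population):
    cfg = SimulationConfig(n_reads=200, seed=17)
    reads = [str(r.seq) for r in simulate_reads(planted_population, cfg)]
    hist, callable_reads = brute_force_window_histogram(reads, assay)
    spec = window_spectrum(reads, assay, min_freq=0.0)
    by_delta = Counter()
    for c in spec.calls:
        by_delta[c.size_delta] += c.count
    assert spec.callable_reads == callable_reads
    assert dict(by_delta) == dict(hist)
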