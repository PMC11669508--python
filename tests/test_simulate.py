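"""Generator contracts: noiseless identity, frequency conservation, determinism."""

import io
import math

import numpy as np
import pytest

from polyedit import (
    AllelePopulation,
    Edit,
    SimulationConfig,
    delta_gv,
    simulate_gel_lane,
    simulate_melt_curves,
    simulate_peak_table,
    simulate_reads,
)
from polyedit.datasets import CUT_SITE, example_reference, single_wt_population
from polyedit.io import write_fastq


def _noiseless(**kw):
    return SimulationConfig(
        substitution_rate=0.0, read_indel_rate=0.0,
        peak_height_noise_cv=0.0, peak_size_jitter_sd=0.0,
        gel_gv_noise_sd=0.0, melt_noise_sd=0.0, **kw,
    )


def test_noiseless_reads_are_identical_to_wt(wt_population, reference):
    reads = simulate_reads(wt_population, _noiseless(n_reads=100, seed=1))
    assert len(reads) == 100
    assert all(str(r.seq) == reference for r in reads)


def test_allele_sampling_within_binomial_bounds(reference):
    pop = AllelePopulation([(reference, 0.7)], [Edit(+1, "A", 0, 0.3)], cut_site=CUT_SITE)
    n = 20_000
    reads = simulate_reads(pop, _noiseless(n_reads=n, seed=1))
    frac = sum(len(r) == len(reference) + 1 for r in reads) / n
    sd = math.sqrt(0.3 * 0.7 / n)
    assert abs(frac - 0.3) <= 3 * sd


def test_read_ids_carry_allele_of_origin(reference):
    pop = AllelePopulation([(reference, 0.5)], [Edit(-3, "", 0, 0.5)], cut_site=CUT_SITE)
    for rec in simulate_reads(pop, _noiseless(n_reads=50, seed=2)):
        label = rec.id.split("|", 1)[1]
        expected = len(reference) if label == "wt0" else len(reference) - 3
        assert len(rec.seq) == expected


def test_same_seed_gives_byte_identical_fastq(planted_population):
    cfg = SimulationConfig(n_reads=300, seed=9)
    bufs = []
    for _ in range(2):
        buf = io.StringIO()
        from Bio import SeqIO

        SeqIO.write(simulate_reads(planted_population, cfg), buf, "fastq")
        bufs.append(buf.getvalue())
    assert bufs[0] == bufs[1]
    cfg2 = SimulationConfig(n_reads=300, seed=10)
    buf = io.StringIO()
    from Bio import SeqIO

    SeqIO.write(simulate_reads(planted_population, cfg2), buf, "fastq")
    assert buf.getvalue() != bufs[0]


def test_single_allele_peak_table_noiseless(wt_population, reference):
    table = simulate_peak_table(wt_population, _noiseless(seed=0))
    assert len(table.peaks) == 1
    assert table.peaks[0].size_bp == len(reference)
    assert table.peaks[0].height == pytest.approx(SimulationConfig().peak_scale)


def test_two_wt_lengths_give_two_equal_peaks_one_bp_apart(reference):
    # the primary-plus-secondary WT peak configuration (227/226)
    var = reference[:200] + reference[201:]
    pop = AllelePopulation([(reference, 0.5), (var, 0.5)], [], cut_site=CUT_SITE)
    table = simulate_peak_table(pop, _noiseless(seed=0))
    sizes = [p.size_bp for p in table.peaks]
    heights = [p.height for p in table.peaks]
    assert sizes == [len(reference) - 1, len(reference)]
    assert heights[0] == pytest.approx(heights[1])


def test_peak_size_jitter_unbiased(wt_population, reference):
    cfg = SimulationConfig(peak_size_jitter_sd=0.3, peak_height_noise_cv=0.0)
    sizes = []
    for seed in range(1000):
        cfg.seed = seed
        sizes.append(simulate_peak_table(wt_population, cfg).peaks[0].size_bp)
    assert abs(np.mean(sizes) - len(reference)) < 0.05


@pytest.mark.parametrize(
    "fraction,check",
    [(1.0, lambda d: d < -90), (0.0, lambda d: d > 90), (0.5, lambda d: -30 <= d <= 30)],
)
def test_gel_lane_delta_gv_by_cleaved_fraction(fraction, check):
    lane = simulate_gel_lane(fraction, cfg=_noiseless(seed=0))
    assert check(delta_gv(lane))


def test_gel_delta_gv_monotone_in_uncleaved_fraction():
    deltas = [delta_gv(simulate_gel_lane(f, cfg=_noiseless(seed=0))) for f in np.linspace(1, 0, 11)]
    assert all(b > a for a, b in zip(deltas, deltas[1:]))


def test_melt_mixture_frequency_conservation(reference):
    # expected curve of a 50/50 mixture is the average of the pure curves
    pop_mix = AllelePopulation([(reference, 0.5)], [Edit(-18, "", -9, 0.5)], cut_site=CUT_SITE)
    pure_wt = single_wt_population()
    tm = {"wt0": 85.0, "edit0(-18)": 80.0}
    cfg = _noiseless(seed=0, melt_replicates=1)
    curves = simulate_melt_curves(
        {"mix": pop_mix, "wt": pure_wt},
        {"mix": tm, "wt": {"wt0": 85.0}},
        cfg,
    )
    mix = curves.samples["mix"][0]
    wt = curves.samples["wt"][0]
    # at the WT Tm the pure-WT trace is at half its own transition; the
    # mixture only carries half that transition's weight
    t = curves.temperatures
    i80 = np.argmin(np.abs(t - 80.0))
    assert mix[i80] == pytest.approx(wt[i80] * 0.5 + 0.5 * 100 * 0.5, rel=0.02)


def test_melt_grid_must_be_increasing(wt_population):
    with pytest.raises(ValueError, match="increasing"):
        simulate_melt_curves(
            {"s": wt_population}, {"s": {"wt0": 82.0}}, _noiseless(seed=0),
            temps=np.array([90.0, 80.0, 70.0]),
        )
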