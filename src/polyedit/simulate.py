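"""Synthetic instrument models: reads, CE peak tables, gel lanes, melt curves.

Every generator is driven by a seeded :class:`numpy.random.Generator`, so a
fixed :class:`~polyedit.population.SimulationConfig` seed reproduces output
byte-for-byte.  Reads carry their allele of origin in the identifier, giving
downstream callers an exact oracle.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fragment_peaks import Peak, PeakTable
from .hrma import MeltCurveSet
from .population import AllelePopulation, SimulationConfig
from .rnp import GelLane

__all__ = [
    "simulate_reads",
    "simulate_peak_table",
    "simulate_gel_lane",
    "simulate_melt_curves",
    "GEL_GV_SCALE_SINGLE",
    "GEL_GV_SCALE_DUAL",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _mutate_read(seq: str, cfg: SimulationConfig, rng: np.random.Generator) -> str:
    """Apply the background error model: per-base substitutions plus a rare
    per-read ±1–2 bp slippage indel."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    if cfg.substitution_rate > 0:
        hits = np.nonzero(rng.random(arr.size) < cfg.substitution_rate)[0]
        for i in hits:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = choices[rng.integers(len(choices))]
    out = arr.tobytes().decode()
    if cfg.read_indel_rate > 0 and rng.random() < cfg.read_indel_rate:
        size = int(rng.integers(1, 3))  # 1 or 2 bp
        pos = int(rng.integers(0, len(out)))
        if rng.random() < 0.5 and len(out) > size:
            out = out[:pos] + out[pos + size:]
        else:
            ins = "".join(chr(b[0]) for b in _BASES[rng.integers(0, 4, size)])
            out = out[:pos] + ins + out[pos:]
    return out


def simulate_reads(pop: AllelePopulation, cfg: SimulationConfig) -> list[SeqRecord]:
    """Draw forward amplicon reads from the allele pool.

    Each read samples an allele by frequency, then passes through the error
    model.  Identifiers are ``read{i}|{allele label}``; qualities are fixed
    Phred 40 ('I') since the callers never consult them.
    """
    alleles = pop.alleles()
    if not alleles:
        raise ValueError("empty allele population")
    freqs = np.array([a.frequency for a in alleles], dtype=float)
    freqs = freqs / freqs.sum()
    rng = np.random.default_rng(cfg.seed)
    picks = rng.choice(len(alleles), size=cfg.n_reads, p=freqs)
    records = []
    for i, k in enumerate(picks):
        a = alleles[k]
        seq = _mutate_read(a.sequence, cfg, rng)
        rec = SeqRecord(Seq(seq), id=f"read{i}|{a.label}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    return records


def simulate_peak_table(pop: AllelePopulation, cfg: SimulationConfig, sample: str = "sample") -> PeakTable:
    """Fragment-analysis peak table: one peak per distinct amplicon length.

    Peak height is proportional to the summed frequency of alleles of that
    length (multiplicative log-normal-ish noise with CV ``peak_height_noise_cv``);
    peak size is the true length plus Gaussian sizing jitter.
    """
    rng = np.random.default_rng(cfg.seed)
    by_len: dict[int, float] = {}
    for a in pop.alleles():
        by_len[len(a.sequence)] = by_len.get(len(a.sequence), 0.0) + a.frequency
    peaks = []
    for length in sorted(by_len):
        height = by_len[length] * cfg.peak_scale
        if cfg.peak_height_noise_cv > 0:
            height *= max(1e-6, 1.0 + rng.normal(0.0, cfg.peak_height_noise_cv))
        size = length + (rng.normal(0.0, cfg.peak_size_jitter_sd) if cfg.peak_size_jitter_sd > 0 else 0.0)
        peaks.append(Peak(size_bp=size, height=height))
    return PeakTable(sample=sample, peaks=peaks)


# GV scales chosen so that the noiseless round trip through the printed
# threshold tables maps cleaved fractions 1.0/0.8/0.5/0.2/0.0 to scores
# 0/1/2/3/4 for both single- and dual-product assays.
GEL_GV_SCALE_SINGLE = 150.0
GEL_GV_SCALE_DUAL = 100.0


def simulate_gel_lane(
    cleaved_fraction: float,
    dual_cleaved: bool = False,
    cfg: SimulationConfig | None = None,
    sample: str = "lane",
) -> GelLane:
    """Synthetic RNP-digest gel lane.

    Mean grey value is modelled as inversely related to band DNA mass
    (GV = scale x (1 - mass fraction)), matching the published sign
    convention in which a fully cleaved WT lane gives dGV < -90.
    """
    if not 0.0 <= cleaved_fraction <= 1.0:
        raise ValueError("cleaved_fraction must lie in [0, 1]")
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    scale = GEL_GV_SCALE_DUAL if dual_cleaved else GEL_GV_SCALE_SINGLE
    noise = cfg.gel_gv_noise_sd

    def gv(mass_fraction: float) -> float:
        v = scale * (1.0 - mass_fraction)
        if noise > 0:
            v += rng.normal(0.0, noise)
        return max(v, 0.0)

    n_cleaved = 2 if dual_cleaved else 1
    cleaved_gvs = [gv(cleaved_fraction) for _ in range(n_cleaved)]
    uncleaved = gv(1.0 - cleaved_fraction)
    expected_cleaved = [500.0, 400.0][:n_cleaved]
    return GelLane(
        sample=sample,
        cleaved_gvs=cleaved_gvs,
        uncleaved_gv=uncleaved,
        expected_cleaved_sizes=expected_cleaved,
        expected_uncleaved_size=900.0,
    )


def _melt_sigmoid(temps: np.ndarray, tm: float, width: float = 0.6) -> np.ndarray:
    """Two-state melt transition: fluorescence 1 below Tm, 0 above."""
    return 1.0 / (1.0 + np.exp((temps - tm) / width))


def simulate_melt_curves(
    pop_by_sample: dict[str, AllelePopulation],
    tm_by_allele: dict[str, dict[str, float]],
    cfg: SimulationConfig,
    temps: np.ndarray | None = None,
    wt_sample_ids: list[str] | None = None,
) -> MeltCurveSet:
    """Saturating-dye melt curves for a set of samples.

    Each sample's fluorescence is a frequency-weighted mixture of two-state
    sigmoid transitions, one per allele (``tm_by_allele[sample][label]`` in
    degrees C), acquired ``melt_replicates`` times with additive noise and a
    small per-replicate gain/offset.
    """
    if temps is None:
        temps = np.arange(70.0, 95.0 + 1e-9, 0.1)
    temps = np.asarray(temps, dtype=float)
    if temps.size < 2:
        raise ValueError("temperature grid needs at least 2 points")
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    rng = np.random.default_rng(cfg.seed)
    samples: dict[str, np.ndarray] = {}
    for sample, pop in pop_by_sample.items():
        tms = tm_by_allele[sample]
        ideal = np.zeros_like(temps)
        for a in pop.alleles():
            ideal += a.frequency * _melt_sigmoid(temps, tms[a.label])
        reps = []
        for _ in range(cfg.melt_replicates):
            gain = 1.0 + rng.normal(0.0, 0.02)
            offset = rng.normal(0.0, 0.02)
            noise = rng.normal(0.0, cfg.melt_noise_sd * 0.01, temps.size)
            reps.append(100.0 * gain * ideal + 100.0 * offset + 100.0 * noise)
        samples[sample] = np.vstack(reps)
    return MeltCurveSet(temperatures=temps, samples=samples, wt_sample_ids=wt_sample_ids or [])
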