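"""File round trips for the pipeline's plain-text exchange formats.

FASTQ (4-line, Phred+33) via Biopython; peak tables
(``sample,size_bp,height``), gel lanes (``sample,band,expected_size_bp,mean_gv``)
and long-format melt curves (``sample,replicate,temp_c,fluorescence``) as CSV
via pandas; spectra as TSV.
"""

from __future__ import annotations

import gzip

import numpy as np
import pandas as pd
from Bio import SeqIO

from .fragment_peaks import Peak, PeakTable
from .hrma import MeltCurveSet
from .rnp import GelLane
from .spectrum import IndelSpectrum

__all__ = [
    "write_fastq",
    "read_fastq",
    "write_peak_table",
    "read_peak_table",
    "write_gel_lanes",
    "read_gel_lanes",
    "write_melt_curves",
    "read_melt_curves",
    "write_spectrum_tsv",
]


def write_fastq(records, path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path):
    """Yield reads as plain strings (gzip transparent)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq)


def write_peak_table(table: PeakTable, path) -> None:
    pd.DataFrame(
        {"sample": table.sample, "size_bp": [p.size_bp for p in table.peaks],
         "height": [p.height for p in table.peaks]}
    ).to_csv(path, index=False)


def read_peak_table(path) -> list[PeakTable]:
    df = pd.read_csv(path)
    return [
        PeakTable(sample=s, peaks=[Peak(r.size_bp, r.height) for r in g.itertuples()])
        for s, g in df.groupby("sample", sort=False)
    ]


def write_gel_lanes(lanes: list[GelLane], path) -> None:
    rows = []
    for lane in lanes:
        for i, gv in enumerate(lane.cleaved_gvs):
            size = lane.expected_cleaved_sizes[i] if i < len(lane.expected_cleaved_sizes) else np.nan
            rows.append((lane.sample, "cleaved", size, gv))
        if lane.uncleaved_gv is not None:
            rows.append((lane.sample, "uncleaved", lane.expected_uncleaved_size, lane.uncleaved_gv))
        for size, gv in lane.extra_bands:
            rows.append((lane.sample, "extra", size, gv))
    pd.DataFrame(rows, columns=["sample", "band", "expected_size_bp", "mean_gv"]).to_csv(path, index=False)


def read_gel_lanes(path) -> list[GelLane]:
    df = pd.read_csv(path)
    lanes = []
    for sample, g in df.groupby("sample", sort=False):
        cleaved = g[g["band"] == "cleaved"]
        uncleaved = g[g["band"] == "uncleaved"]
        extra = g[g["band"] == "extra"]
        lanes.append(
            GelLane(
                sample=sample,
                cleaved_gvs=list(cleaved["mean_gv"]),
                uncleaved_gv=None if uncleaved.empty else float(uncleaved["mean_gv"].iloc[0]),
                extra_bands=[(r.expected_size_bp, r.mean_gv) for r in extra.itertuples()],
                expected_cleaved_sizes=[s for s in cleaved["expected_size_bp"] if not np.isnan(s)],
                expected_uncleaved_size=None if uncleaved.empty else float(uncleaved["expected_size_bp"].iloc[0]),
            )
        )
    return lanes


def write_melt_curves(curves: MeltCurveSet, path) -> None:
    rows = []
    for sample, traces in curves.samples.items():
        for rep, trace in enumerate(traces):
            rows.extend(
                (sample, rep, t, f) for t, f in zip(curves.temperatures, trace)
            )
    pd.DataFrame(rows, columns=["sample", "replicate", "temp_c", "fluorescence"]).to_csv(path, index=False)


def read_melt_curves(path, wt_sample_ids: list[str] | None = None) -> MeltCurveSet:
    df = pd.read_csv(path)
    temps = np.sort(df["temp_c"].unique())
    samples = {}
    for sample, g in df.groupby("sample", sort=False):
        reps = []
        for _, rg in g.groupby("replicate", sort=True):
            rg = rg.sort_values("temp_c")
            reps.append(rg["fluorescence"].to_numpy())
        samples[sample] = np.vstack(reps)
    return MeltCurveSet(temperatures=temps, samples=samples, wt_sample_ids=wt_sample_ids or [])


def write_spectrum_tsv(spectrum: IndelSpectrum, path) -> None:
    df = spectrum.to_frame()
    df.to_csv(path, sep="\t", index=False)
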