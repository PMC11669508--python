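"""Indel spectra: the shared result container for all quantification methods."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["IndelCall", "IndelSpectrum", "NoCallableReadsError"]


class NoCallableReadsError(ValueError):
    """No read carried both anchors for the given assay."""


@dataclass(frozen=True)
class IndelCall:
    """One reported indel class.

    ``frequency`` is a fraction of callable reads (or of total peak signal for
    fragment analysis).  ``indel_sequence`` holds the inserted/deleted bases in
    lower case where the method can extract them.  ``spans_both_sites`` marks
    deletions covering both sgRNA sites of a dual-target amplicon.
    """

    size_delta: int
    count: int
    frequency: float
    indel_sequence: str | None = None
    spans_both_sites: bool = False

    def __post_init__(self) -> None:
        if self.size_delta == 0:
            raise ValueError("size_delta 0 is wild type, not an indel call")


@dataclass
class IndelSpectrum:
    """Per-sample indel size spectrum with the overall non-WT fraction.

    ``overall_non_wt_frequency`` counts every non-WT read/peak, including
    classes below the reporting threshold that are absent from ``calls``; the
    sum of call frequencies is therefore <= the overall figure.
    ``substitution_frequency`` is the window caller's equal-length-mismatch
    bucket (indel tables never include it).
    """

    calls: list[IndelCall]
    overall_non_wt_frequency: float
    callable_reads: int
    total_reads: int
    substitution_frequency: float = 0.0
    assay: str = ""

    def __post_init__(self) -> None:
        breakdown = sum(c.frequency for c in self.calls)
        if breakdown > self.overall_non_wt_frequency + 1e-9:
            raise ValueError("call frequencies exceed the overall non-WT frequency")

    def frequency_of(self, size_delta: int) -> float:
        return sum(c.frequency for c in self.calls if c.size_delta == size_delta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size_delta": [c.size_delta for c in self.calls],
                "count": [c.count for c in self.calls],
                "frequency": [c.frequency for c in self.calls],
                "indel_sequence": [c.indel_sequence for c in self.calls],
                "spans_both_sites": [c.spans_both_sites for c in self.calls],
            }
        )


def build_spectrum(
    counts: dict[tuple[int, str | None, bool], int],
    callable_reads: int,
    total_reads: int,
    min_report_freq: float,
    substitution_count: int = 0,
    assay: str = "",
) -> IndelSpectrum:
    """Assemble an :class:`IndelSpectrum` from per-class counts.

    Classes under ``min_report_freq`` stay out of the breakdown but remain in
    the overall non-WT figure.  Calls are sorted by descending frequency.
    """
    if callable_reads <= 0:
        raise NoCallableReadsError(f"no callable reads for assay {assay!r}")
    non_wt = sum(counts.values())
    calls = []
    for (delta, seq, spans), n in counts.items():
        freq = n / callable_reads
        if freq >= min_report_freq:
            calls.append(IndelCall(delta, n, freq, seq, spans))
    calls.sort(key=lambda c: (-c.frequency, c.size_delta))
    return IndelSpectrum(
        calls=calls,
        overall_non_wt_frequency=non_wt / callable_reads,
        callable_reads=callable_reads,
        total_reads=total_reads,
        substitution_frequency=substitution_count / callable_reads,
        assay=assay,
    )
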