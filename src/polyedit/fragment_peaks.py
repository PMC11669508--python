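"""Capillary-electrophoresis fragment-analysis quantification.

Peak tables (fragment size in bp, peak height) are classified against a WT
reference peak set: every peak within tolerance of a WT size — including
secondary WT length variants — is wild type, and the rest are indels whose
size is the rounded deviation from the main WT peak.  The estimated
co-editing percentage is

    100 x (sum of all peak heights - WT peak height) / (sum of all peak heights)

where the WT height sums all WT-size peaks.  Because a 1 bp deletion can
coincide with a secondary WT peak one base below the main peak, such alleles
are absorbed into the WT class: a documented undercall of this method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .spectrum import IndelCall, IndelSpectrum

__all__ = [
    "Peak",
    "PeakTable",
    "WTReference",
    "define_wt_peaks",
    "classify_peaks",
    "co_editing_percent",
    "indel_frequencies",
]


@dataclass(frozen=True)
class Peak:
    size_bp: float
    height: float

    def __post_init__(self) -> None:
        if self.size_bp <= 0 or self.height <= 0:
            raise ValueError("peak size and height must be positive")


@dataclass
class PeakTable:
    sample: str
    peaks: list[Peak]

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.size_bp)

    @property
    def total_height(self) -> float:
        return sum(p.height for p in self.peaks)


@dataclass(frozen=True)
class WTReference:
    """WT peak-size set: the tallest WT peak is the reference amplicon size."""

    wt_peak_sizes: tuple[float, ...]
    main_wt_size: float
    match_tolerance: float = 0.5

    def __post_init__(self) -> None:
        if self.match_tolerance <= 0:
            raise ValueError("match_tolerance must be positive")
        if not any(math.isclose(s, self.main_wt_size) for s in self.wt_peak_sizes):
            raise ValueError("main_wt_size must be one of wt_peak_sizes")

    def is_wt_size(self, size_bp: float) -> bool:
        return any(abs(size_bp - s) <= self.match_tolerance for s in self.wt_peak_sizes)


def define_wt_peaks(
    wt_table: PeakTable,
    min_rel_height: float = 0.02,
    match_tolerance: float = 0.5,
) -> WTReference:
    """Build the WT peak set from a wild-type sample.

    All peaks at least ``min_rel_height`` of the tallest peak become WT sizes
    (multi-length WT amplicons are common when primers anneal in introns);
    the tallest is the main WT size.
    """
    if not wt_table.peaks:
        raise ValueError("empty WT peak table")
    top = max(p.height for p in wt_table.peaks)
    sizes = tuple(p.size_bp for p in wt_table.peaks if p.height >= min_rel_height * top)
    main = max(wt_table.peaks, key=lambda p: p.height).size_bp
    return WTReference(wt_peak_sizes=sizes, main_wt_size=main, match_tolerance=match_tolerance)


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def classify_peaks(
    sample: PeakTable,
    ref: WTReference,
    min_height_frac: float = 0.01,
) -> list[tuple[Peak, object]]:
    """Label every peak ``"wt"`` or a signed indel size.

    Indel size is the deviation from the main WT size rounded half away from
    zero (a 7.56 bp deviation reports as 8).  Peaks below ``min_height_frac``
    of the total signal are baseline noise and dropped.
    """
    total = sample.total_height
    out = []
    for p in sample.peaks:
        if total > 0 and p.height < min_height_frac * total:
            continue
        if ref.is_wt_size(p.size_bp):
            out.append((p, "wt"))
        else:
            out.append((p, _round_half_away(p.size_bp - ref.main_wt_size)))
    return out


def co_editing_percent(
    sample: PeakTable,
    ref: WTReference,
    min_height_frac: float = 0.01,
) -> float:
    """Estimated co-editing percentage from relative peak heights."""
    labelled = classify_peaks(sample, ref, min_height_frac)
    total = sum(p.height for p, _ in labelled)
    if total <= 0:
        raise ValueError("zero total peak height")
    wt = sum(p.height for p, label in labelled if label == "wt")
    return 100.0 * (total - wt) / total


def indel_frequencies(
    sample: PeakTable,
    ref: WTReference,
    min_height_frac: float = 0.01,
) -> IndelSpectrum:
    """Per-indel-size frequencies (fractions of total peak signal).

    The overall non-WT fraction equals :func:`co_editing_percent` / 100 and,
    because peak heights partition exactly, also the sum of call frequencies.
    """
    labelled = classify_peaks(sample, ref, min_height_frac)
    total = sum(p.height for p, _ in labelled)
    if total <= 0:
        raise ValueError("zero total peak height")
    by_delta: dict[int, float] = {}
    for p, label in labelled:
        if label != "wt":
            by_delta[label] = by_delta.get(label, 0.0) + p.height
    calls = [
        IndelCall(delta, count=round(h), frequency=h / total)
        for delta, h in by_delta.items()
    ]
    calls.sort(key=lambda c: (-c.frequency, c.size_delta))
    non_wt = sum(h for h in by_delta.values())
    return IndelSpectrum(
        calls=calls,
        overall_non_wt_frequency=non_wt / total,
        callable_reads=round(total),
        total_reads=round(sample.total_height),
        assay=sample.sample,
    )
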