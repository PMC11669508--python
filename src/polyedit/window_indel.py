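"""Indicator-window indel calling (Cas-Analyzer-style).

Two conserved 12-nt indicator sequences bracket the sgRNA site at a distance
R (the comparison range).  Reads containing both indicators have the
inter-indicator segment compared to its wild-type counterpart: a length
difference is an indel (sequence extracted by common prefix/suffix trimming),
an equal-length mismatch is a substitution, and reads missing an indicator —
including those whose deletion destroyed one — are unmatched.  Large
deletions invisible at the default R are recovered by a rerun at a wider
range whose newly callable reads are merged into the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Union

from .assay import AssayDefinition
from .cs_indel import _read_str
from .spectrum import IndelCall, IndelSpectrum, build_spectrum

__all__ = [
    "WindowCall",
    "window_call_read",
    "window_spectrum",
    "merge_rerun",
    "spectrum_with_rerun",
    "WT",
    "UNMATCHED",
    "SUBSTITUTION",
]

logger = logging.getLogger(__name__)

WT = "wt"
UNMATCHED = "unmatched"
SUBSTITUTION = "substitution"


@dataclass(frozen=True)
class WindowCall:
    """One read's indel call from the indicator window."""

    size_delta: int
    indel_sequence: str
    count: int = 1
    spans_both_sites: bool = False

    def __post_init__(self) -> None:
        if self.size_delta == 0:
            raise ValueError("size_delta 0 is not an indel")


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _common_suffix(a: str, b: str, max_len: int) -> int:
    n = min(len(a), len(b), max_len)
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def window_call_read(read, assay: AssayDefinition, R: int | None = None) -> Union[WindowCall, str]:
    """Call one read: a :class:`WindowCall`, ``"wt"``, ``"substitution"`` or
    ``"unmatched"``.

    A first-occurrence rule resolves repeated indicator matches (logged).
    Indels larger than the comparison range cannot fit the window and come
    back ``"unmatched"``.
    """
    if R is not None and R != assay.comparison_range_R:
        assay = assay.with_comparison_range(R)
    R = assay.comparison_range_R
    left, right = assay.indicators()
    seq = _read_str(read)
    li = seq.find(left)
    if li < 0:
        return UNMATCHED
    ri = seq.find(right, li + len(left))
    if ri < 0:
        return UNMATCHED
    for anchor, pos in ((left, li), (right, ri)):
        if seq.find(anchor, pos + 1) >= 0:
            logger.warning("indicator %r matches more than once; using first occurrence (%s)", anchor, assay.name)
    segment = seq[li + len(left) : ri]
    expected = assay.wt_window_segment()
    delta = len(segment) - len(expected)
    if delta == 0:
        return WT if segment == expected else SUBSTITUTION
    if abs(delta) > R:
        return UNMATCHED
    pre = _common_prefix(segment, expected)
    suf = _common_suffix(segment, expected, min(len(segment), len(expected)) - pre)
    if delta > 0:
        indel_seq = segment[pre : len(segment) - suf].lower()
        start_abs = assay.target_site - R + pre
        covered = range(start_abs, start_abs + 1)
    else:
        indel_seq = expected[pre : len(expected) - suf].lower()
        start_abs = assay.target_site - R + pre
        covered = range(start_abs, start_abs - delta)
    spans = (
        assay.second_target_site is not None
        and delta < 0
        and assay.target_site in covered
        and assay.second_target_site in covered
    )
    return WindowCall(size_delta=delta, indel_sequence=indel_seq, spans_both_sites=spans)


class _Tally:
    """Aggregate per-read window calls into size classes.

    One reported class per indel size; the extracted sequences of a class are
    summarized as its dominant variants (``"a or t"`` style), and the class
    carries the spanning flag when most of its reads span both sites.
    """

    def __init__(self) -> None:
        self.counts: dict[int, int] = {}
        self.seqs: dict[int, dict[str, int]] = {}
        self.spans: dict[int, int] = {}
        self.callable_reads = 0
        self.substitutions = 0
        self.total = 0

    def add(self, res) -> None:
        self.total += 1
        if res == UNMATCHED:
            return
        self.callable_reads += 1
        if res == WT:
            return
        if res == SUBSTITUTION:
            self.substitutions += 1
            return
        d = res.size_delta
        self.counts[d] = self.counts.get(d, 0) + 1
        variants = self.seqs.setdefault(d, {})
        variants[res.indel_sequence] = variants.get(res.indel_sequence, 0) + 1
        self.spans[d] = self.spans.get(d, 0) + (1 if res.spans_both_sites else 0)

    def class_keys(self) -> dict[tuple[int, str | None, bool], int]:
        keyed = {}
        for d, n in self.counts.items():
            variants = sorted(self.seqs[d].items(), key=lambda kv: -kv[1])
            shown = [s for s, c in variants if c >= 0.1 * n][:3] or [variants[0][0]]
            keyed[(d, " or ".join(shown), self.spans[d] * 2 > n)] = n
        return keyed


def window_spectrum(
    reads: Iterable,
    assay: AssayDefinition,
    min_freq: float = 0.00015,
    R: int | None = None,
) -> IndelSpectrum:
    """Indel spectrum over reads containing both indicators.

    Classes (one per indel size) below ``min_freq`` — default 0.015%, the
    background floor of the WT sample — stay in the overall figure only.
    Equal-length mismatches go to the substitution bucket, never to the
    indel breakdown.
    """
    if R is not None:
        assay = assay.with_comparison_range(R)
    tally = _Tally()
    for read in reads:
        tally.add(window_call_read(read, assay))
    return build_spectrum(
        tally.class_keys(), tally.callable_reads, tally.total, min_freq,
        substitution_count=tally.substitutions, assay=assay.name,
    )


def merge_rerun(primary: IndelSpectrum, large_del: IndelSpectrum) -> IndelSpectrum:
    """Merge a wide-R rerun into the primary spectrum.

    The rerun's newly callable reads join the denominator and its calls are
    appended; identical classes found in both passes have their counts summed
    (logged).  All frequencies are recomputed over the union denominator.
    """
    if not large_del.calls and large_del.callable_reads == 0:
        return primary
    callable_reads = primary.callable_reads + large_del.callable_reads
    merged: dict[int, int] = {}
    seqs: dict[int, str | None] = {}
    spans: dict[int, bool] = {}
    for spec in (primary, large_del):
        for c in spec.calls:
            if c.size_delta in merged and spec is large_del:
                logger.warning("class %+d bp present in both passes; summing counts", c.size_delta)
            merged[c.size_delta] = merged.get(c.size_delta, 0) + c.count
            seqs.setdefault(c.size_delta, c.indel_sequence)
            spans[c.size_delta] = spans.get(c.size_delta, False) or c.spans_both_sites
    non_wt = (
        primary.overall_non_wt_frequency * primary.callable_reads
        + large_del.overall_non_wt_frequency * large_del.callable_reads
    )
    subst = (
        primary.substitution_frequency * primary.callable_reads
        + large_del.substitution_frequency * large_del.callable_reads
    )
    calls = [
        IndelCall(delta, n, n / callable_reads, seqs[delta], spans[delta])
        for delta, n in merged.items()
    ]
    calls.sort(key=lambda c: (-c.frequency, c.size_delta))
    return IndelSpectrum(
        calls=calls,
        overall_non_wt_frequency=non_wt / callable_reads,
        callable_reads=callable_reads,
        total_reads=max(primary.total_reads, large_del.total_reads),
        substitution_frequency=subst / callable_reads,
        assay=primary.assay,
    )


def spectrum_with_rerun(
    reads: Iterable,
    assay: AssayDefinition,
    min_freq: float = 0.00015,
    rerun_R: int = 70,
) -> IndelSpectrum:
    """Two-pass calling: default R first, then the wide-R rerun restricted to
    reads the first pass could not match, merged over the union denominator."""
    reads = [_read_str(r) for r in reads]
    primary = window_spectrum(reads, assay, min_freq=min_freq)
    unmatched = [r for r in reads if window_call_read(r, assay) == UNMATCHED]
    wide = assay.with_comparison_range(rerun_R)
    tally = _Tally()
    for r in unmatched:
        tally.add(window_call_read(r, wide))
    if tally.callable_reads == 0:
        return primary
    rerun = build_spectrum(
        tally.class_keys(), tally.callable_reads, len(reads), min_freq,
        substitution_count=tally.substitutions, assay=assay.name,
    )
    return merge_rerun(primary, rerun)
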