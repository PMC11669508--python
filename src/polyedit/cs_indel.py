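"""Conserved-sequence (CS) indel calling from amplicon reads.

Each forward read is searched for an exact primer match and, downstream of
it, an exact conserved-sequence match.  The deviation of the primer-to-CS
distance from its wild-type value is the indel size.  Reads lacking either
anchor are uncallable; deviation classes under the reporting threshold
(default 1% of callable reads, the background-noise floor of the WT sample)
stay out of the breakdown but count toward the overall non-WT figure.
"""

from __future__ import annotations

import logging
from typing import Iterable, Union

from .assay import AssayDefinition
from .spectrum import IndelSpectrum, build_spectrum

__all__ = ["cs_call_read", "cs_spectrum", "reverse_complement_reads", "WT", "UNCALLABLE"]

logger = logging.getLogger(__name__)

WT = "wt"
UNCALLABLE = "uncallable"

CallResult = Union[int, str]


def _read_str(read) -> str:
    # accept plain strings or Biopython SeqRecords
    return str(read.seq) if hasattr(read, "seq") else str(read)


def reverse_complement_reads(reads: Iterable) -> Iterable[str]:
    """Orient a reverse-read assay (e.g. a primer matched in R reads) into the
    forward frame expected by the callers."""
    from Bio.Seq import Seq

    for read in reads:
        yield str(Seq(_read_str(read)).reverse_complement())


def _find_with_mismatches(seq: str, pattern: str, start: int, k: int) -> int:
    """First position >= start where pattern matches with <= k mismatches."""
    if k == 0:
        return seq.find(pattern, start)
    m = len(pattern)
    for i in range(start, len(seq) - m + 1):
        mismatches = 0
        for a, b in zip(seq[i : i + m], pattern):
            if a != b:
                mismatches += 1
                if mismatches > k:
                    break
        else:
            return i
    return -1


def cs_call_read(read, assay: AssayDefinition, max_anchor_mismatches: int = 0) -> CallResult:
    """Call one read: signed size delta, ``"wt"`` or ``"uncallable"``.

    Anchor matching is exact by default (``max_anchor_mismatches`` relaxes it
    to a Hamming tolerance per anchor, off unless requested); on multiple
    conserved-sequence matches the first one downstream of the primer wins
    (logged).
    """
    seq = _read_str(read)
    if not seq:
        raise ValueError("empty read")
    k = max_anchor_mismatches
    p = _find_with_mismatches(seq, assay.primer, 0, k)
    if p < 0:
        return UNCALLABLE
    search_from = p + len(assay.primer)
    c = _find_with_mismatches(seq, assay.conserved_seq, search_from, k)
    if c < 0:
        return UNCALLABLE
    if _find_with_mismatches(seq, assay.conserved_seq, c + 1, k) >= 0:
        logger.warning("conserved sequence matches more than once in read; using first match (%s)", assay.name)
    delta = (c - p) - assay.wt_distance
    return WT if delta == 0 else delta


def cs_spectrum(
    reads: Iterable,
    assay: AssayDefinition,
    min_report_freq: float = 0.01,
    max_anchor_mismatches: int = 0,
) -> IndelSpectrum:
    """Size-deviation spectrum over reads carrying both anchors."""
    counts: dict[tuple[int, str | None, bool], int] = {}
    callable_reads = 0
    total = 0
    for read in reads:
        total += 1
        res = cs_call_read(read, assay, max_anchor_mismatches)
        if res == UNCALLABLE:
            continue
        callable_reads += 1
        if res != WT:
            key = (int(res), None, False)
            counts[key] = counts.get(key, 0) + 1
    return build_spectrum(counts, callable_reads, total, min_report_freq, assay=assay.name)
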