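"""Allele populations with planted indel spectra.

A transgenic polyploid line is modelled as a pool of amplicon alleles: one or
more wild-type length variants (intron-derived size polymorphisms produce
multi-length WT amplicons, e.g. 226/227/231 bp) plus a set of edited alleles,
each defined by a signed indel relative to the main WT sequence and a
population frequency.  Frequencies are fractions of the allele pool, the
polyploid proxy for co-editing frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["Edit", "Allele", "AllelePopulation", "SimulationConfig"]

_DNA = set("ACGT")


def _check_dna(seq: str, what: str) -> None:
    if not seq or not set(seq) <= _DNA:
        raise ValueError(f"{what} must be a non-empty uppercase ACGT string")


@dataclass(frozen=True)
class Edit:
    """One edited allele class: a signed indel planted at the cut site.

    size_delta > 0 inserts ``sequence`` at ``cut_site + offset``;
    size_delta < 0 deletes ``|size_delta|`` bases starting there.
    """

    size_delta: int
    sequence: str
    offset: int
    frequency: float

    def __post_init__(self) -> None:
        if self.size_delta == 0:
            raise ValueError("an edit must change length (size_delta != 0)")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("edit frequency must lie in [0, 1]")
        if self.size_delta > 0:
            _check_dna(self.sequence, "inserted sequence")
            if len(self.sequence) != self.size_delta:
                raise ValueError("inserted sequence length must equal size_delta")


@dataclass(frozen=True)
class Allele:
    """A concrete amplicon sequence with its pool frequency."""

    label: str
    sequence: str
    frequency: float
    size_delta: int  # vs the main WT amplicon; 0 for the main WT itself


@dataclass
class AllelePopulation:
    """Pool of WT and edited amplicon alleles for one target site.

    ``wt_sequences`` is a list of ``(sequence, abundance)``; the first entry is
    the main WT amplicon that edits are applied to.  Edit frequencies plus WT
    abundances must sum to 1.
    """

    wt_sequences: list[tuple[str, float]]
    edits: list[Edit] = field(default_factory=list)
    cut_site: int = 0

    def __post_init__(self) -> None:
        if not self.wt_sequences:
            raise ValueError("population must contain at least one WT sequence")
        for seq, frac in self.wt_sequences:
            _check_dna(seq, "WT sequence")
            if frac < 0:
                raise ValueError("WT abundance must be non-negative")
        ref = self.reference
        if not 0 <= self.cut_site <= len(ref):
            raise ValueError("cut_site outside the reference amplicon")
        total = sum(f for _, f in self.wt_sequences) + sum(e.frequency for e in self.edits)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"allele frequencies sum to {total!r}, expected 1.0")
        for e in self.edits:
            pos = self.cut_site + e.offset
            if e.size_delta < 0:
                if pos < 0 or pos - e.size_delta > len(ref):
                    raise ValueError(f"deletion {e.size_delta:+d} at offset {e.offset} exceeds the reference")
            elif not 0 <= pos <= len(ref):
                raise ValueError(f"insertion offset {e.offset} outside the reference")

    @property
    def reference(self) -> str:
        """The main WT amplicon sequence."""
        return self.wt_sequences[0][0]

    @property
    def wt_fraction(self) -> float:
        return sum(f for _, f in self.wt_sequences)

    def apply_edit(self, edit: Edit) -> str:
        pos = self.cut_site + edit.offset
        ref = self.reference
        if edit.size_delta > 0:
            return ref[:pos] + edit.sequence + ref[pos:]
        return ref[:pos] + ref[pos - edit.size_delta:]

    def alleles(self) -> list[Allele]:
        """Expand the population into labelled concrete alleles.

        Labels carry the allele class so downstream callers can be checked
        against exact ground truth.
        """
        main_len = len(self.reference)
        out = []
        for i, (seq, frac) in enumerate(self.wt_sequences):
            out.append(Allele(f"wt{i}", seq, frac, len(seq) - main_len))
        for i, e in enumerate(self.edits):
            out.append(Allele(f"edit{i}({e.size_delta:+d})", self.apply_edit(e), e.frequency, e.size_delta))
        return out

    def true_spectrum(self) -> dict[int, float]:
        """Planted size-delta -> frequency map (edited classes only)."""
        spec: dict[int, float] = {}
        for e in self.edits:
            spec[e.size_delta] = spec.get(e.size_delta, 0.0) + e.frequency
        return spec


@dataclass
class SimulationConfig:
    """Knobs of the synthetic instrument models.

    Defaults emulate the study conditions: sub-1% background length deviations
    from sequencing error (a per-read ±1–2 bp slippage model at 0.2% plus
    0.1% per-base substitutions), ~5% CV on fragment-analysis peak heights,
    sub-0.5 bp sizing scatter, and triplicate melt curves.
    """

    n_reads: int = 20_000
    substitution_rate: float = 0.001
    read_indel_rate: float = 0.002
    seed: int = 0
    peak_scale: float = 10_000.0
    peak_size_jitter_sd: float = 0.15
    peak_height_noise_cv: float = 0.05
    melt_replicates: int = 3
    melt_noise_sd: float = 0.3
    gel_gv_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")
        for name in ("substitution_rate", "read_indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.melt_replicates < 1:
            raise ValueError("melt_replicates must be positive")
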