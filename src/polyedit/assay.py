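"""Assay definitions: anchors, offsets, and WT geometry for one target site."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

__all__ = ["AssayDefinition", "load_assay", "save_assay"]

_DNA = set("ACGT")

INDICATOR_LENGTH = 12  # the flanking anchors of the window caller are 12-mers


@dataclass(frozen=True)
class AssayDefinition:
    """One sgRNA target's anchors and expected WT geometry.

    The conserved-sequence caller matches ``primer`` and ``conserved_seq``
    exactly and compares their distance (match start to match start) against
    ``wt_distance``.  The window caller brackets the cut with two 12-nt
    indicator sequences ``comparison_range_R`` bp either side of
    ``target_site``; if ``wt_sequence`` is given the indicators are derived
    from it, otherwise they must be supplied explicitly.
    ``second_target_site`` marks amplicons carrying two sgRNA sites so that
    spanning deletions can be flagged.
    """

    name: str
    primer: str
    conserved_seq: str
    wt_distance: int
    target_site: int
    comparison_range_R: int = 35
    wt_sequence: str | None = None
    left_indicator: str | None = None
    right_indicator: str | None = None
    second_target_site: int | None = None
    expected_wt_amplicon_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for label, seq in (("primer", self.primer), ("conserved_seq", self.conserved_seq)):
            if not seq or not set(seq) <= _DNA:
                raise ValueError(f"{label} must be a non-empty uppercase ACGT string")
        if self.wt_distance <= len(self.primer):
            raise ValueError("wt_distance must exceed the primer length")
        if self.comparison_range_R < 1:
            raise ValueError("comparison_range_R must be positive")
        if self.wt_sequence is not None:
            lo = self.target_site - self.comparison_range_R - INDICATOR_LENGTH
            hi = self.target_site + self.comparison_range_R + INDICATOR_LENGTH
            if lo < 0 or hi > len(self.wt_sequence):
                raise ValueError(
                    f"comparison range R={self.comparison_range_R} does not fit the WT amplicon "
                    f"around target_site {self.target_site}"
                )

    def indicators(self) -> tuple[str, str]:
        """The two 12-nt anchors bracketing the comparison range."""
        if self.left_indicator and self.right_indicator:
            return self.left_indicator, self.right_indicator
        if self.wt_sequence is None:
            raise ValueError("indicators require either explicit anchors or a WT sequence")
        cut, R = self.target_site, self.comparison_range_R
        left = self.wt_sequence[cut - R - INDICATOR_LENGTH : cut - R]
        right = self.wt_sequence[cut + R : cut + R + INDICATOR_LENGTH]
        return left, right

    def wt_window_segment(self) -> str:
        """WT sequence between the indicators (length 2R)."""
        if self.wt_sequence is None:
            raise ValueError("wt_window_segment requires a WT sequence")
        cut, R = self.target_site, self.comparison_range_R
        return self.wt_sequence[cut - R : cut + R]

    def with_comparison_range(self, R: int) -> "AssayDefinition":
        """Re-derive the assay with a different comparison range (e.g. the
        large-deletion rerun at R = 70)."""
        return replace(self, comparison_range_R=R, left_indicator=None, right_indicator=None)


def load_assay(path) -> AssayDefinition:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "expected_wt_amplicon_lengths" in data:
        data["expected_wt_amplicon_lengths"] = tuple(data["expected_wt_amplicon_lengths"])
    return AssayDefinition(**data)


def save_assay(assay: AssayDefinition, path) -> None:
    data = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in assay.__dict__.items()
        if v is not None and v != ()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
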