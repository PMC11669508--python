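"""Cas9 RNP cleavage-assay scoring from gel-band densitometry.

The in-vitro digest leaves WT alleles cleaved and edited alleles intact;
ImageJ-style mean grey values (GV) of the expected bands give

    dGV = mean GV of cleaved product(s) - GV of the non-cleaved product

which maps onto a categorical 0-5 co-mutation score.  The published sign
convention is implemented literally: a fully cleaved (unedited) lane scores
0 at dGV < -90.  When the assay produces two cleaved products their GVs are
averaged, which compresses dGV, so the thresholds shrink to two thirds.
Score 5 marks lanes whose product sizes do not match the expected cleaved
amplicons at all (100% mutated with a large indel shifting the amplicon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GelLane",
    "RNPScore",
    "delta_gv",
    "score",
    "SINGLE_PRODUCT_THRESHOLDS",
    "DUAL_PRODUCT_THRESHOLDS",
    "FREQUENCY_BANDS",
]

# Score thresholds on dGV. Each entry is (upper bound exclusive, score); the
# printed integer ranges leave unit gaps (e.g. -31 to -30) which resolve to
# the lower score, hence the half-open bounds below.
SINGLE_PRODUCT_THRESHOLDS = ((-90, 0), (-30, 1), (31, 2), (91, 3), (float("inf"), 4))
DUAL_PRODUCT_THRESHOLDS = ((-60, 0), (-20, 1), (21, 2), (61, 3), (float("inf"), 4))

FREQUENCY_BANDS = {
    0: "0%",
    1: "<40%",
    2: "~50%",
    3: ">60%",
    4: "100%",
    5: "100% large indel",
}

SIZE_MATCH_TOLERANCE = 0.05  # +/-5% when matching band sizes to expected products


@dataclass
class GelLane:
    """Densitometry of one sample's digest lane.

    ``cleaved_gvs`` holds one or two mean grey values for the expected
    cleaved product(s); ``uncleaved_gv`` is ``None`` when no band appears at
    the un-cleaved size.  ``extra_bands`` lists (size bp, GV) of bands not at
    any expected size.
    """

    sample: str
    cleaved_gvs: list[float]
    uncleaved_gv: float | None = None
    extra_bands: list[tuple[float, float]] = field(default_factory=list)
    expected_cleaved_sizes: list[float] = field(default_factory=list)
    expected_uncleaved_size: float | None = None

    def __post_init__(self) -> None:
        if not self.cleaved_gvs and self.uncleaved_gv is None and not self.extra_bands:
            raise ValueError("gel lane contains no bands")
        if any(g < 0 for g in self.cleaved_gvs) or (self.uncleaved_gv or 0) < 0:
            raise ValueError("grey values must be non-negative")
        if len(self.cleaved_gvs) > 2:
            raise ValueError("at most two cleaved products are expected")


@dataclass(frozen=True)
class RNPScore:
    score: int
    delta_gv: float | None
    frequency_band: str

    def __post_init__(self) -> None:
        if FREQUENCY_BANDS[self.score] != self.frequency_band:
            raise ValueError("score and frequency band disagree")


def delta_gv(lane: GelLane) -> float | None:
    """dGV = mean cleaved GV minus non-cleaved GV; an absent band contributes
    GV 0; ``None`` when no cleaved band exists to compare."""
    if not lane.cleaved_gvs:
        return None
    cleaved = sum(lane.cleaved_gvs) / len(lane.cleaved_gvs)
    uncleaved = lane.uncleaved_gv if lane.uncleaved_gv is not None else 0.0
    return cleaved - uncleaved


def _matches_expected(size: float, expected: list[float]) -> bool:
    return any(abs(size - e) <= SIZE_MATCH_TOLERANCE * e for e in expected)


def score(lane: GelLane) -> RNPScore:
    """Categorical 0-5 co-mutation score for one lane."""
    expected = list(lane.expected_cleaved_sizes)
    if lane.expected_uncleaved_size is not None:
        expected.append(lane.expected_uncleaved_size)
    if lane.extra_bands:
        ambiguous = [b for b in lane.extra_bands if expected and _matches_expected(b[0], expected)]
        if ambiguous:
            raise ValueError(
                f"lane {lane.sample!r}: extra bands {ambiguous} match expected product sizes; "
                "reassign them to cleaved/uncleaved before scoring"
            )
        # product at an unexpected size: fully mutated with a large indel
        return RNPScore(score=5, delta_gv=None, frequency_band=FREQUENCY_BANDS[5])
    d = delta_gv(lane)
    if d is None:
        raise ValueError(
            f"lane {lane.sample!r}: no cleaved band and no unexpected product; cannot score"
        )
    thresholds = DUAL_PRODUCT_THRESHOLDS if len(lane.cleaved_gvs) == 2 else SINGLE_PRODUCT_THRESHOLDS
    for bound, s in thresholds:
        if d < bound:
            return RNPScore(score=s, delta_gv=d, frequency_band=FREQUENCY_BANDS[s])
    raise AssertionError("unreachable")
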