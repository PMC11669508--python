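"""Cross-method comparison, chimerism detection, and the per-sample cost model.

One :class:`LineResult` gathers everything measured for a transgenic line:
the two sequencing-based indel spectra (conserved-sequence and indicator
window), the fragment-analysis spectrum, the RNP score, and the HRMA
summary.  The concordance table lines them up per line, matching indel sizes
across methods within a +/-1 bp drift and flagging the known method-specific
failure modes (fragment analysis absorbing -1 alleles into a secondary WT
peak; the window caller missing deletions that span both sgRNA sites or
exceed its comparison range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .rnp import RNPScore
from .spectrum import IndelSpectrum

__all__ = [
    "LineResult",
    "concordance_table",
    "detect_chimerism",
    "cost_per_sample",
    "CHIMERIC",
    "UNIFORM",
    "INSUFFICIENT",
]

CHIMERIC = "chimeric"
UNIFORM = "uniform"
INSUFFICIENT = "insufficient replicates"


@dataclass
class LineResult:
    line_id: str
    cs: IndelSpectrum | None = None
    window: IndelSpectrum | None = None
    ce: IndelSpectrum | None = None
    rnp: RNPScore | None = None
    hrma_max_diff: float | None = None
    melt_peak_temps: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if all(v is None for v in (self.cs, self.window, self.ce, self.rnp, self.hrma_max_diff)):
            raise ValueError(f"line {self.line_id!r} has no method results")

    def overall_frequency(self) -> float | None:
        """Overall non-WT fraction, preferring sequencing over fragment peaks."""
        for spec in (self.cs, self.window, self.ce):
            if spec is not None:
                return spec.overall_non_wt_frequency
        return None


def _deltas(spec: IndelSpectrum | None, min_freq: float = 0.0) -> list[int]:
    if spec is None:
        return []
    return [c.size_delta for c in spec.calls if c.frequency >= min_freq]


def _match_within(a: list[int], b: list[int], tol: int) -> bool:
    """Every size in ``a`` has a partner in ``b`` within ``tol`` bp and vice versa."""
    return all(any(abs(x - y) <= tol for y in b) for x in a) and all(
        any(abs(x - y) <= tol for x in a) for y in b
    )


def _spanning_reconciled(cs: IndelSpectrum | None, window: IndelSpectrum | None, tol: int) -> bool:
    """A large CS deletion is explained by a window call flagged as spanning
    both sgRNA sites."""
    if cs is None or window is None:
        return False
    spanning = [c.size_delta for c in window.calls if c.spans_both_sites]
    missing = [
        d for d in _deltas(cs)
        if not any(abs(d - w) <= tol for w in _deltas(window))
    ]
    return bool(spanning) and all(any(abs(d - s) <= tol for s in spanning) for d in missing)


def concordance_table(
    results: list[LineResult],
    size_tolerance: int = 1,
    compare_min_freq: float = 0.01,
) -> pd.DataFrame:
    """Per-line method comparison in the layout of the study tables.

    Overall frequencies are percentages; ``sizes_agree`` marks agreement of
    the reported indel sizes across all present sequencing/fragment methods
    within ``size_tolerance`` bp; the flag columns mark the documented
    failure modes.  Methods filter at different floors, so only classes at or
    above ``compare_min_freq`` enter the size comparison.
    """
    if not results:
        raise ValueError("no line results")
    rows = []
    for r in results:
        cs_d = _deltas(r.cs, compare_min_freq)
        win_d = _deltas(r.window, compare_min_freq)
        ce_d = _deltas(r.ce, compare_min_freq)
        pairs = ((cs_d, win_d), (cs_d, ce_d), (win_d, ce_d))
        sizes_agree = all(
            _match_within(a, b, size_tolerance) for a, b in pairs if a and b
        )
        ce_absorbed_minus1 = (
            r.ce is not None
            and any(d == -1 for d in cs_d + win_d)
            and not any(d == -1 for d in ce_d)
        )
        window_missed_large = (
            r.cs is not None
            and r.window is not None
            and any(
                not any(abs(d - w) <= size_tolerance for w in win_d)
                for d in cs_d
            )
            and not _spanning_reconciled(r.cs, r.window, size_tolerance)
        )
        rows.append(
            {
                "line_id": r.line_id,
                "cs_overall_pct": None if r.cs is None else 100 * r.cs.overall_non_wt_frequency,
                "window_overall_pct": None if r.window is None else 100 * r.window.overall_non_wt_frequency,
                "ce_overall_pct": None if r.ce is None else 100 * r.ce.overall_non_wt_frequency,
                "rnp_score": None if r.rnp is None else r.rnp.score,
                "rnp_band": None if r.rnp is None else r.rnp.frequency_band,
                "hrma_max_fluor_diff": r.hrma_max_diff,
                "melt_peak_temps": ", ".join(f"{t:.1f}" for t in r.melt_peak_temps),
                "sizes_agree": sizes_agree,
                "spanning_deletion": _spanning_reconciled(r.cs, r.window, size_tolerance),
                "ce_absorbed_minus1": ce_absorbed_minus1,
                "window_missed_size": window_missed_large,
            }
        )
    return pd.DataFrame(rows)


def detect_chimerism(
    progeny: list[LineResult],
    mutant_threshold: float = 0.05,
) -> str:
    """Classify one transformation event from its vegetative progenies.

    Each progeny is WT (overall non-WT fraction below the threshold) or
    mutant; an event whose progenies disagree is chimeric.  Order-invariant.
    """
    if len(progeny) < 2:
        return INSUFFICIENT
    classes = set()
    for p in progeny:
        overall = p.overall_frequency()
        if overall is None:
            raise ValueError(f"progeny {p.line_id!r} has no frequency-bearing result")
        classes.add(overall >= mutant_threshold)
    return CHIMERIC if len(classes) > 1 else UNIFORM


def cost_per_sample(
    table: pd.DataFrame,
    method: str,
    required_components: list[str] | None = None,
) -> float:
    """Per-sample cost of one method: sum over components of pack price
    divided by reactions per pack, times the per-sample replicate count
    (triplicate methods flag it in ``replicates_per_sample``)."""
    needed = {"component", "pack_price", "reactions_per_pack", "method"}
    missing_cols = needed - set(table.columns)
    if missing_cols:
        raise ValueError(f"cost table missing columns: {sorted(missing_cols)}")
    rows = table[table["method"] == method]
    if rows.empty:
        raise ValueError(f"no cost components for method {method!r}")
    if required_components:
        absent = sorted(set(required_components) - set(rows["component"]))
        if absent:
            raise ValueError(f"missing components for {method!r}: {absent}")
    if (rows["pack_price"] < 0).any() or (rows["reactions_per_pack"] < 1).any():
        raise ValueError("pack prices must be >= 0 and reactions per pack >= 1")
    reps = rows["replicates_per_sample"] if "replicates_per_sample" in rows else 1
    return float((rows["pack_price"] / rows["reactions_per_pack"] * reps).sum())
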