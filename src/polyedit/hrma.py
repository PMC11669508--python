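"""Melt-curve and high-resolution melt analysis (HRMA).

Raw fluorescence-vs-temperature traces are (i) differentiated to find melt
peak temperatures (maxima of -dF/dT after light smoothing), and (ii)
two-point normalized — the mean fluorescence in a pre-melt window maps to 100
and in a post-melt window to 0 — before subtracting the mean of the WT
replicates to produce per-sample difference curves.  The summary statistic is
the maximum absolute fluorescence difference to WT over the temperature grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = ["MeltCurveSet", "HRMAResult", "melt_peaks", "normalize", "difference_curves"]


@dataclass
class MeltCurveSet:
    """Per-sample replicate traces on one shared temperature grid.

    ``samples[name]`` is an array of shape (replicates, n_temperatures).
    """

    temperatures: np.ndarray
    samples: dict[str, np.ndarray]
    wt_sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        n = self.temperatures.size
        for name, traces in self.samples.items():
            traces = np.atleast_2d(np.asarray(traces, dtype=float))
            if traces.shape[1] != n:
                raise ValueError(f"sample {name!r} traces do not match the temperature grid")
            self.samples[name] = traces
        missing = [w for w in self.wt_sample_ids if w not in self.samples]
        if missing:
            raise ValueError(f"WT samples missing from the set: {missing}")


@dataclass
class HRMAResult:
    temperatures: np.ndarray
    normalized: dict[str, np.ndarray]       # mean normalized trace per sample
    differences: dict[str, np.ndarray]      # normalized minus WT baseline
    max_fluor_diff: dict[str, float]        # max |difference| per sample
    melt_peak_temps: dict[str, list[float]]


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")
    return out[pad : pad + y.size] if pad else out


def melt_peaks(
    temperatures: np.ndarray,
    trace: np.ndarray,
    smoothing_window: int = 5,
    min_prominence_frac: float = 0.05,
    min_height_frac: float = 0.2,
) -> list[float]:
    """Melt peak temperatures: maxima of -dF/dT, reported to 0.1 degC.

    A peak must exceed ``min_prominence_frac`` of the maximum derivative in
    prominence and ``min_height_frac`` of it in height — the height floor
    keeps replicate noise on the flat pre/post-melt shoulders from
    registering as transitions.  A trace with no qualifying peak (e.g. flat)
    returns an empty list.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    trace = np.asarray(trace, dtype=float)
    deriv = -np.gradient(trace, temperatures)
    deriv = _smooth(deriv, smoothing_window)
    top = deriv.max()
    if top <= 0:
        return []
    idx, _ = find_peaks(deriv, prominence=min_prominence_frac * top, height=min_height_frac * top)
    return [round(float(temperatures[i]), 1) for i in idx]


def normalize(
    temperatures: np.ndarray,
    trace: np.ndarray,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
) -> np.ndarray:
    """Two-point normalization: affine map sending the pre-melt window mean to
    100 and the post-melt window mean to 0.  Invariant to per-trace gain and
    offset by construction."""
    temperatures = np.asarray(temperatures, dtype=float)
    trace = np.asarray(trace, dtype=float)
    pre = (temperatures >= pre_window[0]) & (temperatures <= pre_window[1])
    post = (temperatures >= post_window[0]) & (temperatures <= post_window[1])
    if not pre.any() or not post.any():
        raise ValueError("normalization windows must contain grid points")
    hi = trace[pre].mean()
    lo = trace[post].mean()
    if np.isclose(hi, lo):
        raise ValueError("degenerate normalization windows (equal means)")
    return 100.0 * (trace - lo) / (hi - lo)


def _default_windows(temperatures: np.ndarray) -> tuple[tuple[float, float], tuple[float, float]]:
    t0, t1 = float(temperatures[0]), float(temperatures[-1])
    return (t0, t0 + 1.0), (t1 - 1.0, t1)


def difference_curves(
    curves: MeltCurveSet,
    pre_window: tuple[float, float] | None = None,
    post_window: tuple[float, float] | None = None,
    smoothing_window: int = 5,
    min_prominence_frac: float = 0.05,
) -> HRMAResult:
    """Normalize all replicates, average them per sample, subtract the WT
    baseline (mean over all WT replicates), and report the maximum absolute
    fluorescence difference plus melt peak temperatures per sample."""
    if not curves.wt_sample_ids:
        raise ValueError("difference curves require at least one WT sample")
    temps = curves.temperatures
    if pre_window is None or post_window is None:
        default_pre, default_post = _default_windows(temps)
        pre_window = pre_window or default_pre
        post_window = post_window or default_post

    normalized: dict[str, np.ndarray] = {}
    for name, traces in curves.samples.items():
        norm = np.vstack([normalize(temps, t, pre_window, post_window) for t in traces])
        normalized[name] = norm.mean(axis=0)
    baseline = np.mean([normalized[w] for w in curves.wt_sample_ids], axis=0)

    differences = {name: normalized[name] - baseline for name in curves.samples}
    max_diff = {name: float(np.abs(d).max()) for name, d in differences.items()}
    peaks = {
        name: melt_peaks(temps, curves.samples[name].mean(axis=0), smoothing_window, min_prominence_frac)
        for name in curves.samples
    }
    return HRMAResult(
        temperatures=temps,
        normalized=normalized,
        differences=differences,
        max_fluor_diff=max_diff,
        melt_peak_temps=peaks,
    )
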