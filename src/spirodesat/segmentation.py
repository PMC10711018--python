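"""Rule-based Supine/Trendelenburg position separation on the PIP channel.

The peak-inspiratory-pressure channel is Gaussian-smoothed (sigma = 60 s
worth of samples), min-max normalized to [0, 1], and the two position
sections are located with a four-rule threshold scheme:

* Supine start: first sample at/above 0.3 whose successive differences
  stay within 0.1 for the following 5 minutes.
* Supine end: first subsequent sample exceeding 0.7.
* Trendelenburg start: first sample opening a run in which the signal
  stays at/above 0.7 for 5 minutes.
* Trendelenburg end: first subsequent pair of two consecutive samples
  below 0.5 (record end if none).

Only the center 80% of each detected section is retained downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import DegenerateSignalError, SegmentationError
from .simulate import SpirometryRecord

__all__ = [
    "SegmentationConfig",
    "Interval",
    "PositionSegments",
    "gaussian_smooth",
    "minmax_normalize",
    "segment_positions",
    "trim_center",
    "preprocess_pip",
    "segment_record",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds of the position-separation rule base.

    ``sigma_s`` is the smoothing width in seconds; the kernel width in
    samples is ``sigma_s * fs`` (60 s at 15 Hz = 900 samples).
    """

    sigma_s: float = 60.0
    supine_level: float = 0.3
    stability_delta: float = 0.1
    stability_duration_s: float = 300.0
    trend_level: float = 0.7
    trend_duration_s: float = 300.0
    trend_end_level: float = 0.5
    trend_end_consecutive: int = 2
    trim_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.supine_level < self.trend_level <= 1:
            raise ValueError("need 0 < supine_level < trend_level <= 1")
        if not 0 < self.trim_fraction <= 1:
            raise ValueError("trim_fraction must be in (0, 1]")
        if min(self.sigma_s, self.stability_duration_s,
               self.trend_duration_s) <= 0:
            raise ValueError("durations must be positive")


@dataclass(frozen=True)
class Interval:
    """Half-open sample-index interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("interval end precedes start")

    def __len__(self) -> int:
        return self.end - self.start

    def slice(self) -> slice:
        return slice(self.start, self.end)


@dataclass(frozen=True)
class PositionSegments:
    supine: Interval
    trendelenburg: Interval

    def __post_init__(self) -> None:
        if self.supine.end > self.trendelenburg.start:
            raise ValueError("supine section must precede trendelenburg")


def gaussian_smooth(signal: np.ndarray, sigma_samples: float) -> np.ndarray:
    """Convolve with a truncated Gaussian (4 sigma, reflect padding)."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise DegenerateSignalError("cannot smooth an empty signal")
    if sigma_samples <= 0:
        raise ValueError("sigma_samples must be positive")
    return gaussian_filter1d(signal, sigma_samples, mode="reflect", truncate=4.0)


def minmax_normalize(signal: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; raises on constant input."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise DegenerateSignalError("cannot normalize an empty signal")
    lo, hi = signal.min(), signal.max()
    if hi <= lo:
        raise DegenerateSignalError("constant signal cannot be min-max scaled")
    return (signal - lo) / (hi - lo)


def _sliding_all(mask: np.ndarray, width: int) -> np.ndarray:
    """ok[t] is True iff mask[t:t+width] is all True; O(n) via cumsum."""
    if width > mask.size:
        return np.zeros(0, dtype=bool)
    cs = np.concatenate(([0], np.cumsum(mask.astype(np.int64))))
    return (cs[width:] - cs[:-width]) == width


def segment_positions(pip_norm: np.ndarray, fs: float,
                      cfg: SegmentationConfig | None = None) -> PositionSegments:
    """Apply the four-rule separator to a smoothed, normalized PIP series."""
    cfg = cfg or SegmentationConfig()
    pip = np.asarray(pip_norm, dtype=float)
    w_stab = int(round(cfg.stability_duration_s * fs))
    w_trend = int(round(cfg.trend_duration_s * fs))
    if pip.size < 2 * w_stab:
        raise SegmentationError(
            f"signal too short ({pip.size} samples) for the "
            f"{cfg.stability_duration_s:.0f}-s stability rule")

    # Supine start: level >= 0.3 with a 5-min stable run of small diffs.
    stable = np.abs(np.diff(pip)) <= cfg.stability_delta
    run = _sliding_all(stable, w_stab)
    cand = (pip[: run.size] >= cfg.supine_level) & run
    starts = np.flatnonzero(cand)
    if starts.size == 0:
        raise SegmentationError("supine-start rule not satisfied: no stable "
                                f"run at level >= {cfg.supine_level}")
    supine_start = int(starts[0])

    # Supine end: first sample after the start exceeding the high level.
    above = np.flatnonzero(pip[supine_start + 1:] > cfg.trend_level)
    if above.size == 0:
        raise SegmentationError("supine-end rule not satisfied: signal never "
                                f"exceeds {cfg.trend_level}")
    supine_end = supine_start + 1 + int(above[0])

    # Trendelenburg start: first 5-min run at/above the high level.
    high = pip[supine_end:] >= cfg.trend_level
    run_t = _sliding_all(high, w_trend)
    starts_t = np.flatnonzero(run_t)
    if starts_t.size == 0:
        raise SegmentationError(
            "trendelenburg-start rule not satisfied: no "
            f"{cfg.trend_duration_s:.0f}-s run at level >= {cfg.trend_level}")
    trend_start = supine_end + int(starts_t[0])

    # Trendelenburg end: two consecutive samples below 0.5 (else record end).
    below = pip < cfg.trend_end_level
    k = cfg.trend_end_consecutive
    pair = _sliding_all(below, k)
    drops = np.flatnonzero(pair[trend_start + 1:])
    trend_end = (trend_start + 1 + int(drops[0])) if drops.size else pip.size

    return PositionSegments(
        supine=Interval(supine_start, supine_end),
        trendelenburg=Interval(trend_start, trend_end),
    )


def trim_center(segment: Interval, fraction: float) -> Interval:
    """Centered sub-interval of length floor(fraction * L).

    Of the L - floor(f*L) dropped samples, ceil(.../2) come off the head.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    L = len(segment)
    if L == 0:
        raise ValueError("cannot trim an empty interval")
    keep = math.floor(fraction * L)
    head = math.ceil((L - keep) / 2)
    return Interval(segment.start + head, segment.start + head + keep)


def preprocess_pip(record: SpirometryRecord,
                   cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Smoothed then min-max normalized PIP channel (the paper's order)."""
    cfg = cfg or SegmentationConfig()
    return minmax_normalize(gaussian_smooth(record.pip, cfg.sigma_s * record.fs))


def segment_record(record: SpirometryRecord,
                   cfg: SegmentationConfig | None = None,
                   trim: bool = True) -> PositionSegments:
    """Smooth, normalize and segment a record; optionally center-trim."""
    cfg = cfg or SegmentationConfig()
    segments = segment_positions(preprocess_pip(record, cfg), record.fs, cfg)
    if trim:
        segments = PositionSegments(
            supine=trim_center(segments.supine, cfg.trim_fraction),
            trendelenburg=trim_center(segments.trendelenburg, cfg.trim_fraction),
        )
    return segments
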