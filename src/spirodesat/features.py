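"""Window-based extraction of the 176-feature vector.

Each trimmed position section is divided into 20 windows of 2000 samples
(~133.3 s at 15 Hz); the window stride follows the published formula
``(section length - window size) / number of windows`` and, for sections
longer than 400,000 samples, windows are spread maximally instead.  All
per-window statistics are averaged over the 20 windows; windows in which
a statistic is undefined (e.g. fewer than 3 detected peaks) are excluded
from the average rather than zero-filled.

Families:

* signal properties — mean, median, SD, skewness, kurtosis and two
  outlier counts per channel and position, plus the two section lengths;
* correlations — Pearson/Spearman/Kendall, band-averaged coherence and
  normalized DTW, within position (AWP vs VOL) and across positions
  (Supine window i vs Trendelenburg window i, AWP and VOL);
* peak variability — HRV-style time- and frequency-domain statistics of
  the AWP/VOL peak value and peak interval series.

PIP contributes signal properties only: it is a per-breath plateau value,
not a periodic waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .dtw import dtw_distance
from .errors import FeatureUndefinedError
from .registry import (CHANNELS, CORR_METRICS, FEATURE_NAMES, INTERVAL_STATS,
                       PEAK_CHANNELS, POSITIONS, VALUE_STATS)
from .segmentation import Interval, PositionSegments
from .simulate import SpirometryRecord

__all__ = [
    "WindowingConfig",
    "PeakConfig",
    "WindowSet",
    "make_windows",
    "build_window_set",
    "signal_property_features",
    "detect_peaks",
    "variability_features",
    "correlation_features",
    "peak_variability_features",
    "coherence_mean",
    "extract_feature_vector",
]


@dataclass(frozen=True)
class WindowingConfig:
    window_samples: int = 2000
    n_windows: int = 20
    long_segment_threshold: int = 400_000

    def __post_init__(self) -> None:
        if self.window_samples <= 0 or self.n_windows <= 0:
            raise ValueError("window_samples and n_windows must be positive")


@dataclass(frozen=True)
class PeakConfig:
    """Peak detector settings for the respiratory AWP/VOL waveforms."""

    min_period_s: float = 2.0
    prominence_fraction: float = 0.1
    #: NNxx-analog thresholds: 0.5 s on intervals (the 50-ms HRV constant
    #: rescaled to breath timescales), 0.5 channel units on peak values.
    nn_interval_s: float = 0.5
    nn_value: float = 0.5
    #: Tachogram resampling rate and spectral bands (Hz).
    resample_hz: float = 4.0
    lf_band: tuple[float, float] = (0.01, 0.05)
    hf_band: tuple[float, float] = (0.05, 0.5)


@dataclass
class WindowSet:
    """20 x 2000 window arrays per (position, channel), plus section lengths."""

    windows: dict[tuple[str, str], np.ndarray]  # (position, channel) -> (n, w)
    lengths: dict[str, int]                     # position -> section length


def window_starts(length: int, cfg: WindowingConfig | None = None) -> np.ndarray:
    """Start offsets of the 20 windows within a section of ``length`` samples.

    For sections up to the long-segment threshold the stride is
    ``(L - w) / n_windows`` with fractional strides floored per start; for
    longer sections windows are spread maximally, ``(L - w) / (n_windows-1)``,
    so the last window ends exactly at the section end.
    """
    cfg = cfg or WindowingConfig()
    w, n = cfg.window_samples, cfg.n_windows
    if length < w:
        raise FeatureUndefinedError(
            f"section of {length} samples is shorter than the "
            f"{w}-sample window")
    denom = (n - 1) if (length > cfg.long_segment_threshold and n > 1) else n
    return np.array([(i * (length - w)) // denom for i in range(n)], dtype=int)


def make_windows(segment: Interval, series: np.ndarray,
                 cfg: WindowingConfig | None = None) -> np.ndarray:
    """Slice one channel of one (already trimmed) section into windows."""
    cfg = cfg or WindowingConfig()
    starts = window_starts(len(segment), cfg) + segment.start
    w = cfg.window_samples
    return np.stack([np.asarray(series[s: s + w], dtype=float)
                     for s in starts])


def build_window_set(record: SpirometryRecord, segments: PositionSegments,
                     cfg: WindowingConfig | None = None) -> WindowSet:
    cfg = cfg or WindowingConfig()
    segs = {"supine": segments.supine, "trendelenburg": segments.trendelenburg}
    windows = {}
    for pos, seg in segs.items():
        for ch in CHANNELS:
            windows[(pos, ch)] = make_windows(seg, record.channel(ch), cfg)
    return WindowSet(windows=windows,
                     lengths={pos: len(seg) for pos, seg in segs.items()})


# ---------------------------------------------------------------------------
# signal properties

def _window_property_stats(wins: np.ndarray) -> dict[str, float]:
    """Seven per-window statistics averaged over the window axis."""
    mean = wins.mean(axis=1)
    median = np.median(wins, axis=1)
    sd = wins.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = spstats.skew(wins, axis=1)
        kurt = spstats.kurtosis(wins, axis=1)  # Fisher (excess)
    zero_var = sd == 0
    skew = np.where(zero_var, 0.0, skew)
    kurt = np.where(zero_var, 0.0, kurt)

    sd0 = wins.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (wins - mean[:, None]) / sd0
    z = np.where(sd0 == 0, 0.0, z)
    z_out = (np.abs(z) > 3).sum(axis=1).astype(float)

    q1 = np.quantile(wins, 0.25, axis=1, keepdims=True)
    q3 = np.quantile(wins, 0.75, axis=1, keepdims=True)
    iqr = q3 - q1
    iqr_out = ((wins < q1 - 1.5 * iqr) | (wins > q3 + 1.5 * iqr)).sum(
        axis=1).astype(float)

    return {
        "mean": float(mean.mean()),
        "median": float(median.mean()),
        "std": float(sd.mean()),
        "skewness": float(skew.mean()),
        "kurtosis": float(kurt.mean()),
        "z_outlier": float(z_out.mean()),
        "iqr_outlier": float(iqr_out.mean()),
    }


def signal_property_features(ws: WindowSet) -> dict[str, float]:
    """The 44 signal-property features (7 stats x 6 combos + 2 lengths)."""
    out: dict[str, float] = {}
    for pos in POSITIONS:
        for ch in CHANNELS:
            stats = _window_property_stats(ws.windows[(pos, ch)])
            for stat, value in stats.items():
                out[f"{pos}.{ch}.{stat}"] = value
    for pos in POSITIONS:
        out[f"{pos}.length"] = float(ws.lengths[pos])
    return out


# ---------------------------------------------------------------------------
# peak detection and variability

def detect_peaks(window: np.ndarray, fs: float,
                 cfg: PeakConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima with a minimum separation and a prominence floor.

    The prominence threshold is a fraction of the window's amplitude
    range, which suppresses noise ripples while keeping every breath peak.
    """
    cfg = cfg or PeakConfig()
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("cannot detect peaks in an empty window")
    rng = float(window.max() - window.min())
    if rng <= 0:
        return np.array([], dtype=int), np.array([])
    distance = max(1, int(round(cfg.min_period_s * fs)))
    idx, _ = sps.find_peaks(window, distance=distance,
                            prominence=cfg.prominence_fraction * rng)
    return idx, window[idx]


def _series_stats(x: np.ndarray, prefix: str, nn_threshold: float,
                  ) -> dict[str, float]:
    """Shared time-domain block of the variability families."""
    d = np.diff(x)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    out = {
        f"{prefix}_mean": mean,
        f"{prefix}_median": float(np.median(x)),
        f"{prefix}_rmssd": float(np.sqrt(np.mean(d ** 2))),
        f"{prefix}_sdsd": float(np.std(d, ddof=1)) if d.size >= 2 else np.nan,
        f"{prefix}_cv": sd / mean if mean != 0 else 0.0,
        f"{prefix}_min": float(x.min()),
        f"{prefix}_max": float(x.max()),
        f"{prefix}_range": float(x.max() - x.min()),
        f"{prefix}_nnxx": float(np.sum(np.abs(d) > nn_threshold)),
        f"{prefix}_pnnxx": float(np.mean(np.abs(d) > nn_threshold)),
    }
    out[f"{prefix}_sdnn" if prefix == "piv" else f"{prefix}_sd"] = sd
    return out


def _interval_spectrum(intervals: np.ndarray, fs: float,
                       cfg: PeakConfig) -> dict[str, float]:
    """Welch-free periodogram of the uniformly resampled interval tachogram."""
    nan = {"piv_total_power": np.nan, "piv_lf": np.nan, "piv_hf": np.nan,
           "piv_lf_hf": np.nan, "piv_lf_norm": np.nan}
    if intervals.size < 4:
        return nan
    t = np.cumsum(intervals) / fs  # peak times in seconds
    span = t[-1] - t[0]
    if span < 10.0:
        return nan
    grid = np.arange(t[0], t[-1], 1.0 / cfg.resample_hz)
    tach = np.interp(grid, t, intervals)
    tach = tach - tach.mean()
    freqs, pxx = sps.periodogram(tach, fs=cfg.resample_hz)
    lf_mask = (freqs >= cfg.lf_band[0]) & (freqs < cfg.lf_band[1])
    hf_mask = (freqs >= cfg.hf_band[0]) & (freqs < cfg.hf_band[1])
    total = float(np.trapezoid(pxx[freqs > 0], freqs[freqs > 0]))
    lf = float(np.trapezoid(pxx[lf_mask], freqs[lf_mask])) if lf_mask.any() else 0.0
    hf = float(np.trapezoid(pxx[hf_mask], freqs[hf_mask])) if hf_mask.any() else 0.0
    return {
        "piv_total_power": total,
        "piv_lf": lf,
        "piv_hf": hf,
        "piv_lf_hf": lf / hf if hf > 0 else 0.0,
        "piv_lf_norm": lf / (lf + hf) if lf + hf > 0 else 0.0,
    }


def variability_features(peak_values: np.ndarray, peak_intervals: np.ndarray,
                         fs: float = 15.0, cfg: PeakConfig | None = None,
                         ) -> dict[str, float]:
    """The 27 variability statistics of one window's peak series.

    ``peak_intervals`` are peak-to-peak spacings in samples (16 interval
    statistics, NNxx threshold 0.5 s), ``peak_values`` the peak amplitudes
    in channel units (11 value statistics).  Requires at least 2 intervals
    and 3 values; callers treat windows below that as missing.
    """
    cfg = cfg or PeakConfig()
    values = np.asarray(peak_values, dtype=float)
    intervals = np.asarray(peak_intervals, dtype=float)
    if values.size < 3 or intervals.size < 2:
        raise FeatureUndefinedError(
            "variability features need >= 3 peaks per window")
    out = _series_stats(intervals, "piv", cfg.nn_interval_s * fs)
    out.update(_interval_spectrum(intervals, fs, cfg))
    out.update(_series_stats(values, "pvv", cfg.nn_value))
    return out


def peak_variability_features(ws: WindowSet, fs: float,
                              cfg: PeakConfig | None = None) -> dict[str, float]:
    """The 108 peak-variability features (27 x AWP/VOL x position).

    Per-window feature dictionaries are averaged with NaN exclusion; a
    combination whose every window is peak-deficient raises
    :class:`FeatureUndefinedError`.
    """
    cfg = cfg or PeakConfig()
    names = [s for s, _ in INTERVAL_STATS + VALUE_STATS]
    out: dict[str, float] = {}
    for pos in POSITIONS:
        for ch in PEAK_CHANNELS:
            rows = []
            for window in ws.windows[(pos, ch)]:
                idx, vals = detect_peaks(window, fs, cfg)
                if idx.size < 3:
                    continue
                feats = variability_features(vals, np.diff(idx).astype(float),
                                             fs, cfg)
                rows.append([feats[name] for name in names])
            if not rows:
                raise FeatureUndefinedError(
                    f"no window of {pos}/{ch} has >= 3 peaks")
            with np.errstate(invalid="ignore"):
                agg = np.nanmean(np.array(rows), axis=0)
            for name, value in zip(names, agg):
                out[f"{pos}.{ch}.{name}"] = float(value)
    return out


# ---------------------------------------------------------------------------
# correlations

def coherence_mean(a: np.ndarray, b: np.ndarray, fs: float,
                   nperseg: int = 256, band: tuple[float, float] = (0.05, 1.0),
                   ) -> float:
    """Magnitude-squared coherence averaged over the respiratory band."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("coherence_mean requires equal-length series")
    if a.size < nperseg:
        raise ValueError(f"need at least {nperseg} samples")
    freqs, cxy = sps.coherence(a, b, fs=fs, window="hann", nperseg=nperseg,
                               noverlap=nperseg // 2)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(cxy[mask].mean())


def _corr_triplet(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """PCC, SCC and Kendall tau-b; zero-variance inputs map to 0."""
    if a.std() == 0 or b.std() == 0:
        return 0.0, 0.0, 0.0
    pcc = float(np.corrcoef(a, b)[0, 1])
    scc = float(spstats.spearmanr(a, b).statistic)
    kc = float(spstats.kendalltau(a, b).statistic)
    return pcc, scc, kc


def _pair_metrics(a: np.ndarray, b: np.ndarray, fs: float) -> dict[str, float]:
    pcc, scc, kc = _corr_triplet(a, b)
    return {"pcc": pcc, "scc": scc, "kc": kc,
            "coherence": coherence_mean(a, b, fs),
            "dtw": dtw_distance(a, b)}


def correlation_features(ws: WindowSet, fs: float) -> dict[str, float]:
    """The 20 correlation features, averaged over the 20 window pairs.

    Intra-position: AWP window i vs VOL window i within each position.
    Inter-position: Supine window i vs Trendelenburg window i of the same
    channel, for AWP and VOL.
    """
    metric_names = [m for m, _ in CORR_METRICS]
    out: dict[str, float] = {}

    def averaged(pairs: list[tuple[np.ndarray, np.ndarray]]) -> dict[str, float]:
        rows = [_pair_metrics(a, b, fs) for a, b in pairs]
        return {m: float(np.mean([r[m] for r in rows])) for m in metric_names}

    for pos in POSITIONS:
        pairs = list(zip(ws.windows[(pos, "AWP")], ws.windows[(pos, "VOL")]))
        for m, v in averaged(pairs).items():
            out[f"{pos}.AWP_VOL.{m}"] = v
    for ch in PEAK_CHANNELS:
        pairs = list(zip(ws.windows[("supine", ch)],
                         ws.windows[("trendelenburg", ch)]))
        for m, v in averaged(pairs).items():
            out[f"inter.{ch}.{m}"] = v
    return out


# ---------------------------------------------------------------------------
# assembly

def extract_feature_vector(record: SpirometryRecord,
                           segments: PositionSegments,
                           windowing: WindowingConfig | None = None,
                           peaks: PeakConfig | None = None) -> pd.Series:
    """Assemble the 176-feature vector of one case in registry order.

    ``segments`` must already be center-trimmed.
    """
    ws = build_window_set(record, segments, windowing)
    values: dict[str, float] = dict(zip(
        ("sex", "age", "weight", "height"),
        (float(v) for v in record.demographics)))
    values.update(signal_property_features(ws))
    values.update(correlation_features(ws, record.fs))
    values.update(peak_variability_features(ws, record.fs, peaks))
    vector = pd.Series([values[name] for name in FEATURE_NAMES],
                       index=list(FEATURE_NAMES), name=record.case_id)
    bad = vector.index[~np.isfinite(vector.to_numpy(dtype=float))]
    if len(bad):
        raise FeatureUndefinedError(
            f"non-finite feature value(s): {', '.join(bad[:5])}")
    return vector
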