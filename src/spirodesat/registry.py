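"""Fixed registry of the 176 named features.

Order: demographics (4), signal properties (44), correlations (20), peak
variability (108).  Names encode position, channel and statistic, e.g.
``supine.PIP.mean`` or ``inter.VOL.pcc``; the clinically reported feature
indices F1-F10 resolve through :data:`TABLE_ALIASES`.

The exact composition of the 44-feature and 108-feature families is a
committed reconstruction that reproduces the published family totals and
every individually named feature: 7 per-window statistics for each of the
6 channel-by-position combinations plus the two section lengths (44), and
27 HRV-style variability statistics (16 on peak intervals, 11 on peak
values) for each of the 4 AWP/VOL-by-position combinations (108).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

__all__ = [
    "FeatureSpec",
    "REGISTRY",
    "FEATURE_NAMES",
    "FAMILY_SIZES",
    "TABLE_ALIASES",
    "registry_json",
]

CHANNELS = ("PIP", "AWP", "VOL")
POSITIONS = ("supine", "trendelenburg")
PEAK_CHANNELS = ("AWP", "VOL")  # PIP holds one value per breath: no peaks

DEMOGRAPHICS = ("sex", "age", "weight", "height")

PROPERTY_STATS = (
    ("mean", "window mean, averaged over 20 windows"),
    ("median", "window median, averaged over 20 windows"),
    ("std", "window standard deviation (ddof=1), averaged"),
    ("skewness", "window skewness (0 for zero variance), averaged"),
    ("kurtosis", "window excess kurtosis (0 for zero variance), averaged"),
    ("z_outlier", "per-window count of samples with |z| > 3, averaged"),
    ("iqr_outlier", "per-window count outside the 1.5*IQR fences, averaged"),
)

CORR_METRICS = (
    ("pcc", "Pearson correlation coefficient"),
    ("scc", "Spearman rank correlation coefficient"),
    ("kc", "Kendall rank correlation coefficient (tau-b)"),
    ("coherence", "mean magnitude-squared coherence, 0.05-1 Hz band"),
    ("dtw", "path-length-normalized dynamic time warping distance"),
)

INTERVAL_STATS = (
    ("piv_mean", "mean peak-to-peak interval (samples)"),
    ("piv_median", "median interval"),
    ("piv_sdnn", "SD of intervals (SDNN analog)"),
    ("piv_rmssd", "RMS of successive interval differences (RMSSD analog)"),
    ("piv_sdsd", "SD of successive interval differences"),
    ("piv_cv", "coefficient of variation of intervals"),
    ("piv_min", "minimum interval"),
    ("piv_max", "maximum interval"),
    ("piv_range", "interval range"),
    ("piv_nnxx", "count of successive differences > 0.5 s (NNxx analog)"),
    ("piv_pnnxx", "proportion of successive differences > 0.5 s (pNNxx analog)"),
    ("piv_total_power", "total spectral power of the interval tachogram"),
    ("piv_lf", "low-frequency power, 0.01-0.05 Hz"),
    ("piv_hf", "high-frequency power, 0.05-0.5 Hz"),
    ("piv_lf_hf", "LF/HF power ratio"),
    ("piv_lf_norm", "normalized LF power, LF/(LF+HF)"),
)

VALUE_STATS = (
    ("pvv_mean", "mean peak value"),
    ("pvv_median", "median peak value"),
    ("pvv_sd", "SD of peak values (peak value variability)"),
    ("pvv_rmssd", "RMS of successive peak-value differences"),
    ("pvv_sdsd", "SD of successive peak-value differences"),
    ("pvv_cv", "coefficient of variation of peak values"),
    ("pvv_min", "minimum peak value"),
    ("pvv_max", "maximum peak value"),
    ("pvv_range", "peak value range"),
    ("pvv_nnxx", "count of successive value differences > 0.5 units"),
    ("pvv_pnnxx", "proportion of successive value differences > 0.5 units"),
)


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    family: str  # demographics | signal_property | correlation | variability
    position: str  # supine | trendelenburg | inter | ""
    channel: str   # PIP | AWP | VOL | AWP_VOL | ""
    definition: str


def _build() -> tuple[FeatureSpec, ...]:
    specs: list[FeatureSpec] = []
    for name in DEMOGRAPHICS:
        specs.append(FeatureSpec(name, "demographics", "", "",
                                 f"patient {name}"))
    for pos in POSITIONS:
        for ch in CHANNELS:
            for stat, desc in PROPERTY_STATS:
                specs.append(FeatureSpec(f"{pos}.{ch}.{stat}",
                                         "signal_property", pos, ch, desc))
    for pos in POSITIONS:
        specs.append(FeatureSpec(f"{pos}.length", "signal_property", pos, "",
                                 "analyzed section length in samples"))
    for pos in POSITIONS:
        for metric, desc in CORR_METRICS:
            specs.append(FeatureSpec(
                f"{pos}.AWP_VOL.{metric}", "correlation", pos, "AWP_VOL",
                f"intra-position AWP vs VOL: {desc}"))
    for ch in PEAK_CHANNELS:
        for metric, desc in CORR_METRICS:
            specs.append(FeatureSpec(
                f"inter.{ch}.{metric}", "correlation", "inter", ch,
                f"Supine vs Trendelenburg windows of {ch}: {desc}"))
    for pos in POSITIONS:
        for ch in PEAK_CHANNELS:
            for stat, desc in INTERVAL_STATS + VALUE_STATS:
                specs.append(FeatureSpec(f"{pos}.{ch}.{stat}", "variability",
                                         pos, ch, desc))
    return tuple(specs)


REGISTRY: tuple[FeatureSpec, ...] = _build()
FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in REGISTRY)
FAMILY_SIZES = {
    "demographics": 4,
    "signal_property": 44,
    "correlation": 20,
    "variability": 108,
}

assert len(REGISTRY) == 176
assert len(set(FEATURE_NAMES)) == 176
for _fam, _n in FAMILY_SIZES.items():
    assert sum(s.family == _fam for s in REGISTRY) == _n

#: Clinically reported feature indices mapped to registry names.
TABLE_ALIASES = {
    "F1": "supine.PIP.z_outlier",
    "F2": "supine.PIP.mean",
    "F3": "supine.VOL.median",
    "F4": "supine.VOL.pvv_sd",
    "F5": "supine.VOL.piv_rmssd",
    "F6": "supine.AWP_VOL.kc",
    "F7": "supine.AWP.pvv_sd",
    "F8": "trendelenburg.PIP.std",
    "F9": "trendelenburg.AWP.mean",
    "F10": "inter.VOL.pcc",
}
assert set(TABLE_ALIASES.values()) <= set(FEATURE_NAMES)


def registry_json(indent: int = 2) -> str:
    """The registry as a JSON array of (name, family, channel, position,
    definition) objects."""
    return json.dumps([asdict(s) for s in REGISTRY], indent=indent)
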