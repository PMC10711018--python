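"""Synthetic intraoperative-spirometry cohort generator.

Emulates the signal structure the downstream pipeline assumes for
laparoscopic surgery in the steep Trendelenburg position: a pre-incision
noise phase, a Supine phase of mechanical ventilation at a normal peak
inspiratory pressure (PIP), a short transition ramp, a pneumoperitoneum /
Trendelenburg phase at an elevated PIP, and a post-phase after the
pressure is released.  Three channels are produced at a fixed sampling
rate: PIP (one plateau value held per breath), airway pressure (AWP) and
lung volume (VOL), with periodic breath cycles on AWP/VOL.

Group-level effects are planted through a single latent severity score
``s`` (standard normal across a cohort): the Supine PIP level, the tidal
volume, the Trendelenburg pressure multiplier and the breath-period
jitter all increase with ``s``, and the postoperative-desaturation label
is drawn from a logistic model on ``s``.  The effect directions mirror
the clinical pattern: desaturation cases have a higher Supine mean PIP,
a higher Supine median VOL and a higher Trendelenburg mean AWP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CaseProfile",
    "SpirometryRecord",
    "Cohort",
    "generate_breath_train",
    "generate_case",
    "generate_cohort",
    "DATASET_A_SIZES",
    "DATASET_B_SIZES",
]

# Cohort size conventions: (n_normal, n_desaturation).
DATASET_A_SIZES = (133, 74)
DATASET_B_SIZES = (20, 4)

# Test fraction used for the stratified split (42 of 207 cases).
TEST_FRACTION = 42 / 207

#: Latent-effect parameterization.  At severity s = -1 the profile matches the
#: normal-group defaults, at s = +1 the desaturation-group defaults.
PIP_SUPINE_BASE = 15.2      # cmH2O; 14.7 / 15.7 at s = -/+1
PIP_SUPINE_SLOPE = 0.5
TREND_MULT_BASE = 1.955     # Trendelenburg PIP = supine PIP x multiplier
TREND_MULT_SLOPE = 0.155
TIDAL_VOLUME_BASE = 666.0   # mL; calibrated so the Supine windowed VOL median
TIDAL_VOLUME_SLOPE = 44.5   # lands near 119 (normal) / 136 (desaturation)
PERIOD_JITTER_BASE = 1.75   # s; per-breath SD of the breath period
PERIOD_JITTER_SLOPE = 0.35

#: Logistic label model: P(desaturation) = sigmoid(b0 + b1 * severity).
#: b0 is set so the population prevalence is ~= 74/207 (36%).
LOGIT_SLOPE = 1.5
LOGIT_INTERCEPT = -0.83

_PHASES = ("pre", "supine", "transition", "trendelenburg", "post")


@dataclass(frozen=True)
class CaseProfile:
    """Ground-truth parameters of one synthetic case.

    ``severity`` is the standardized latent effect that couples the
    physiological parameters to the desaturation label.
    """

    group: str = "normal"
    severity: float = -1.0
    respiratory_rate_bpm: float = 12.0
    respiratory_period_sd_s: float = PERIOD_JITTER_BASE - PERIOD_JITTER_SLOPE
    pip_supine_cmH2O: float = PIP_SUPINE_BASE - PIP_SUPINE_SLOPE
    pip_trend_multiplier: float = TREND_MULT_BASE - TREND_MULT_SLOPE
    tidal_volume_mL: float = TIDAL_VOLUME_BASE - TIDAL_VOLUME_SLOPE
    peep_cmH2O: float = 5.0
    phase_durations_s: tuple[float, float, float, float, float] = (
        120.0, 900.0, 60.0, 1200.0, 120.0)
    demographics: tuple[float, float, float, float] = (0.0, 63.0, 64.7, 163.0)
    pip_baseline_cmH2O: float = 2.0
    pip_breath_cv: float = 0.06
    vol_breath_cv: float = 0.08
    noise_sd: tuple[float, float, float] = (0.3, 0.3, 5.0)  # PIP, AWP, VOL
    fs: float = 15.0

    @classmethod
    def from_severity(cls, severity: float, **overrides) -> "CaseProfile":
        """Build a profile whose planted effects follow the latent severity."""
        s = float(np.clip(severity, -3.0, 3.0))
        params = dict(
            group="desaturation" if severity > 0 else "normal",
            severity=float(severity),
            respiratory_period_sd_s=PERIOD_JITTER_BASE + PERIOD_JITTER_SLOPE * s,
            pip_supine_cmH2O=PIP_SUPINE_BASE + PIP_SUPINE_SLOPE * s,
            pip_trend_multiplier=TREND_MULT_BASE + TREND_MULT_SLOPE * s,
            tidal_volume_mL=TIDAL_VOLUME_BASE + TIDAL_VOLUME_SLOPE * s,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def default(cls, group: str, **overrides) -> "CaseProfile":
        """Group-typical profile: severity +1 (desaturation) or -1 (normal)."""
        if group not in ("normal", "desaturation"):
            raise ValueError(f"unknown group {group!r}")
        return cls.from_severity(1.0 if group == "desaturation" else -1.0,
                                 **overrides)

    def __post_init__(self) -> None:
        if len(self.phase_durations_s) != 5:
            raise ValueError("phase_durations_s must have 5 entries "
                             "(pre, supine, transition, trendelenburg, post)")
        if any(d <= 0 for d in self.phase_durations_s):
            raise ValueError("all phase durations must be positive")
        if self.phase_durations_s[1] < 600 or self.phase_durations_s[3] < 600:
            raise ValueError("supine and trendelenburg phases must last >= 600 s")
        if self.pip_trend_multiplier <= 1:
            raise ValueError("pip_trend_multiplier must exceed 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        # The normalized Supine plateau must sit in [0.3, 0.7) and the
        # Trendelenburg plateau at/above 0.7 for the rule base to apply.
        lo = self.pip_baseline_cmH2O
        hi = self.pip_supine_cmH2O * self.pip_trend_multiplier
        supine_norm = (self.pip_supine_cmH2O - lo) / (hi - lo)
        if not (0.3 <= supine_norm < 0.7):
            raise ValueError(
                f"normalized Supine PIP plateau {supine_norm:.3f} outside [0.3, 0.7)")

    @property
    def trend_pip_cmH2O(self) -> float:
        return self.pip_supine_cmH2O * self.pip_trend_multiplier

    @property
    def desaturation_probability(self) -> float:
        """Logistic label model evaluated at this profile's severity."""
        return 1.0 / (1.0 + math.exp(-(LOGIT_INTERCEPT
                                       + LOGIT_SLOPE * self.severity)))


@dataclass
class SpirometryRecord:
    """One case: three channels at a fixed sampling rate, demographics, label."""

    case_id: str
    fs: float
    pip: np.ndarray
    awp: np.ndarray
    vol: np.ndarray
    demographics: tuple[float, float, float, float]
    label: int
    truth: CaseProfile | None = None

    def __post_init__(self) -> None:
        if not (len(self.pip) == len(self.awp) == len(self.vol)):
            raise ValueError("all three channels must have the same length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.pip)

    def channel(self, name: str) -> np.ndarray:
        try:
            return {"PIP": self.pip, "AWP": self.awp, "VOL": self.vol}[name]
        except KeyError:
            raise KeyError(f"unknown channel {name!r}") from None


@dataclass
class Cohort:
    records: list[SpirometryRecord]
    split: np.ndarray  # "train"/"test" per record
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)


def _breath_waveforms(n: int, peep: float, pip_value: float,
                      tidal: float) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free AWP and VOL waveforms for one breath of ``n`` samples.

    AWP rises raised-cosine from PEEP to the breath's PIP, holds a short
    plateau and decays exponentially back to PEEP.  VOL inflates
    raised-cosine to the tidal volume (hit exactly at the end-inspiration
    sample, giving the peak detector an unambiguous maximum) and then
    decays exponentially toward zero.
    """
    k = np.arange(n, dtype=float)
    ti = max(2, int(round(0.30 * n)))          # end of inspiration
    ra = max(1, int(round(0.85 * ti)))         # end of the AWP rise
    awp = np.empty(n)
    awp[: ra + 1] = peep + (pip_value - peep) * 0.5 * (
        1.0 - np.cos(np.pi * k[: ra + 1] / ra))
    awp[ra + 1: ti + 1] = pip_value
    tau_a = 0.10 * n
    awp[ti + 1:] = peep + (pip_value - peep) * np.exp(-(k[ti + 1:] - ti) / tau_a)

    vol = np.empty(n)
    vol[: ti + 1] = tidal * 0.5 * (1.0 - np.cos(np.pi * k[: ti + 1] / ti))
    tau_v = 0.25 * max(n - ti, 1)
    vol[ti + 1:] = tidal * np.exp(-(k[ti + 1:] - ti) / tau_v)
    return awp, vol


def generate_breath_train(profile: CaseProfile, phase: str, duration_s: float,
                          rng: np.random.Generator,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate the (PIP, AWP, VOL) series of one phase.

    Breathing phases (``supine``, ``transition``, ``trendelenburg``) are
    built breath by breath: each breath draws its period from the
    profile's rate distribution and its PIP/tidal amplitudes with small
    breath-to-breath variation; the PIP channel holds the breath's peak
    value constant across the breath.  ``pre``/``post`` phases contain
    only baseline noise.  Additive Gaussian noise is applied to all
    channels; AWP and VOL are clipped at zero.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if phase not in _PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    fs = profile.fs
    n = int(round(duration_s * fs))
    sd_pip, sd_awp, sd_vol = profile.noise_sd

    if phase in ("pre", "post"):
        pip = np.full(n, profile.pip_baseline_cmH2O)
        awp = np.full(n, profile.peep_cmH2O)
        vol = np.zeros(n)
    else:
        pip = np.empty(n)
        awp = np.empty(n)
        vol = np.empty(n)
        level_start = profile.pip_supine_cmH2O
        level_end = profile.trend_pip_cmH2O
        mean_period = 60.0 / profile.respiratory_rate_bpm
        t = 0
        while t < n:
            period = mean_period
            if profile.respiratory_period_sd_s > 0:
                period = float(np.clip(
                    rng.normal(mean_period, profile.respiratory_period_sd_s),
                    2.0, 10.0))
            nb = max(4, int(round(period * fs)))
            if phase == "supine":
                level = level_start
            elif phase == "trendelenburg":
                level = level_end
            else:  # linear ramp across the transition
                level = level_start + (level_end - level_start) * (t / n)
            pip_b = level
            tidal_b = profile.tidal_volume_mL
            if profile.pip_breath_cv > 0:
                pip_b *= 1.0 + profile.pip_breath_cv * rng.standard_normal()
            if profile.vol_breath_cv > 0:
                tidal_b *= 1.0 + profile.vol_breath_cv * rng.standard_normal()
            awp_b, vol_b = _breath_waveforms(nb, profile.peep_cmH2O, pip_b,
                                             tidal_b)
            m = min(nb, n - t)
            pip[t: t + m] = pip_b
            awp[t: t + m] = awp_b[:m]
            vol[t: t + m] = vol_b[:m]
            t += m

    if sd_pip > 0:
        pip = pip + rng.normal(0.0, sd_pip, n)
    if sd_awp > 0:
        awp = awp + rng.normal(0.0, sd_awp, n)
    if sd_vol > 0:
        vol = vol + rng.normal(0.0, sd_vol, n)
    return pip, np.clip(awp, 0.0, None), np.clip(vol, 0.0, None)


def generate_case(profile: CaseProfile, rng: np.random.Generator,
                  case_id: str = "case", label: int | None = None,
                  ) -> SpirometryRecord:
    """Generate a full case by concatenating the five phases.

    The desaturation label is drawn from the logistic model on the
    profile's latent severity unless forced via ``label``.
    """
    parts = [generate_breath_train(profile, ph, dur, rng)
             for ph, dur in zip(_PHASES, profile.phase_durations_s)]
    pip = np.concatenate([p[0] for p in parts])
    awp = np.concatenate([p[1] for p in parts])
    vol = np.concatenate([p[2] for p in parts])
    if label is None:
        label = int(rng.random() < profile.desaturation_probability)
    return SpirometryRecord(case_id=case_id, fs=profile.fs, pip=pip, awp=awp,
                            vol=vol, demographics=profile.demographics,
                            label=int(label), truth=profile)


def _draw_demographics(rng: np.random.Generator) -> tuple[float, float, float, float]:
    """Sex (1 = female, 44.4%), age 20-84 yr, weight kg, height cm."""
    sex = float(rng.random() < 0.444)
    age = float(np.clip(np.round(rng.normal(63.0, 12.0)), 20, 84))
    weight = float(np.round(np.clip(rng.normal(64.7, 10.2), 35, 120), 1))
    height = float(np.round(np.clip(rng.normal(163.0, 7.1), 140, 195), 1))
    return sex, age, weight, height


def _stratified_split(labels: np.ndarray, rng: np.random.Generator,
                      test_fraction: float = TEST_FRACTION) -> np.ndarray:
    split = np.full(len(labels), "train", dtype=object)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        n_test = int(round(test_fraction * len(idx)))
        test_idx = rng.permutation(idx)[:n_test]
        split[test_idx] = "test"
    return split.astype(str)


def generate_cohort(n_normal: int = DATASET_A_SIZES[0],
                    n_desat: int = DATASET_A_SIZES[1],
                    seed: int = 0,
                    profile_overrides: dict | None = None) -> Cohort:
    """Generate a seeded cohort with a stratified train/test assignment.

    Cases are screened cheaply first: latent severities, demographics and
    labels are drawn until each label bucket is filled, and signals are
    synthesized only for accepted cases.  Default sizes mirror the primary
    dataset (133 normal / 74 desaturation; test split 27/15).
    """
    if n_normal < 0 or n_desat < 0:
        raise ValueError("cohort counts must be non-negative")
    overrides = profile_overrides or {}
    master = np.random.SeedSequence(seed)
    screen_ss, split_ss, case_root = master.spawn(3)
    rng_screen = np.random.default_rng(screen_ss)

    wanted = {0: n_normal, 1: n_desat}
    accepted: list[tuple[CaseProfile, int]] = []
    max_draws = 200 * max(1, n_normal + n_desat)
    draws = 0
    while (wanted[0] > 0 or wanted[1] > 0) and draws < max_draws:
        draws += 1
        severity = rng_screen.standard_normal()
        demo = _draw_demographics(rng_screen)
        profile = CaseProfile.from_severity(severity, demographics=demo,
                                            **overrides)
        label = int(rng_screen.random() < profile.desaturation_probability)
        if wanted[label] > 0:
            wanted[label] -= 1
            accepted.append((profile, label))
    if wanted[0] > 0 or wanted[1] > 0:
        raise RuntimeError("cohort screening did not converge")

    records = []
    for i, ((profile, label), ss) in enumerate(
            zip(accepted, case_root.spawn(max(1, len(accepted))))):
        rng = np.random.default_rng(ss)
        records.append(generate_case(profile, rng, case_id=f"case_{i:03d}",
                                     label=label))
    labels = np.array([r.label for r in records], dtype=int)
    split = (_stratified_split(labels, np.random.default_rng(split_ss))
             if len(records) else np.array([], dtype=str))
    return Cohort(records=records, split=split, seed=seed)
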