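"""Synthetic two-group cohorts of epoched virtual-sensor waveforms.

The generator emulates the statistical structure of a visual-stimulation
experiment recorded at a single virtual sensor in primary visual cortex:
each trial is the sum of

* phase-locked evoked deflections (Gaussian temporal envelopes placed in the
  canonical component windows M100/M150/M250/M500 or N1/P1/N2/P3),
* non-phase-locked induced bursts (amplitude-modulated sinusoids whose
  carrier phase is drawn uniformly at random per trial), and
* 1/f background noise synthesized by spectral shaping of white noise.

Group differences are expressed as multiplicative amplitude ratios and
additive latency shifts applied to the patient group, and every applied
effect is recorded in a ground-truth table so that downstream analyses can
be checked against what was actually planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EvokedComponentSpec",
    "InducedBurstSpec",
    "GroupEffect",
    "CohortConfig",
    "EpochedRecording",
    "COMPONENT_WINDOWS",
    "BAND_BOUNDS",
    "generate_noise",
    "generate_subject",
    "generate_cohort",
]

#: Canonical component latency windows (ms after stimulus onset).  The
#: MEG-like components and EEG-like peaks share the same time ranges.
COMPONENT_WINDOWS = {
    "M100": (40.0, 100.0),
    "M150": (100.0, 150.0),
    "M250": (150.0, 250.0),
    "M500": (250.0, 500.0),
    "N1": (40.0, 100.0),
    "P1": (100.0, 150.0),
    "N2": (150.0, 250.0),
    "P3": (250.0, 500.0),
}

#: Frequency bounds (Hz) of the oscillatory bands used throughout.
BAND_BOUNDS = {"beta": (15.0, 29.0), "NBG": (30.0, 100.0), "BBG": (100.0, 250.0)}


@dataclass(frozen=True)
class EvokedComponentSpec:
    """A phase-locked deflection with a Gaussian temporal envelope.

    Parameters
    ----------
    name
        Component label; if it matches a canonical window
        (:data:`COMPONENT_WINDOWS`) the centre latency must lie inside it.
    center_latency
        Envelope centre in ms after stimulus onset.
    width
        Gaussian envelope standard deviation in ms.
    amplitude
        Peak amplitude (arbitrary units).
    polarity
        +1 or -1; the sign of the deflection.
    trial_jitter_sd
        SD (ms) of the per-trial latency jitter.  Small by default so the
        component remains phase-locked across trials.
    """

    name: str
    center_latency: float
    width: float
    amplitude: float
    polarity: int = 1
    trial_jitter_sd: float = 5.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("component width must be > 0")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if self.trial_jitter_sd < 0:
            raise ValueError("trial_jitter_sd must be >= 0")
        win = COMPONENT_WINDOWS.get(self.name)
        if win is not None and not (win[0] <= self.center_latency <= win[1]):
            raise ValueError(
                f"component {self.name!r}: center latency {self.center_latency} ms "
                f"outside its window {win}"
            )


@dataclass(frozen=True)
class InducedBurstSpec:
    """A non-phase-locked oscillatory burst.

    The burst is ``amplitude * exp(-(t - t0)^2 / (2 * sigma^2)) *
    cos(2 pi f (t - t0) + phi)`` with ``phi`` drawn uniformly at random per
    trial, so it vanishes from the trial average (up to ~1/sqrt(n)) but
    survives per-trial spectral analysis.  ``sigma = duration / 4`` so the
    stated duration spans roughly +-2 envelope SDs.  ``phase_locked=True``
    fixes ``phi = 0`` on every trial, turning the burst into stimulus-locked
    oscillatory content that survives averaging.
    """

    band: str
    center_frequency: float
    center_latency: float
    duration: float
    amplitude: float
    bandwidth: float | None = None
    latency_jitter_sd: float = 0.0
    phase_locked: bool = False

    def __post_init__(self):
        if self.band not in BAND_BOUNDS:
            raise ValueError(f"unknown band {self.band!r}")
        lo, hi = BAND_BOUNDS[self.band]
        if not (lo <= self.center_frequency <= hi):
            raise ValueError(
                f"{self.band} burst frequency {self.center_frequency} Hz outside "
                f"band bounds {lo}-{hi} Hz"
            )
        if self.duration <= 0:
            raise ValueError("burst duration must be > 0")
        if self.latency_jitter_sd < 0:
            raise ValueError("latency_jitter_sd must be >= 0")

    @property
    def envelope_sd(self) -> float:
        return self.duration / 4.0


@dataclass(frozen=True)
class GroupEffect:
    """A ground-truth difference applied to the patient group.

    ``target`` names a component or burst (burst targets use the band name).
    ``amplitude_ratio`` multiplies the amplitude; ``latency_shift`` (ms) is
    added to the centre latency.
    """

    target: str
    amplitude_ratio: float = 1.0
    latency_shift: float = 0.0

    def __post_init__(self):
        if self.amplitude_ratio < 0:
            raise ValueError("amplitude ratio must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    n_control: int = 20
    n_patient: int = 20
    n_trials: int = 85
    fs: float = 1000.0
    t_start: float = -200.0
    t_end: float = 500.0
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    components: tuple[EvokedComponentSpec, ...] = ()
    bursts: tuple[InducedBurstSpec, ...] = ()
    group_effects: tuple[GroupEffect, ...] = ()
    modality: str = "MEG-like"
    seed: int = 0

    def __post_init__(self):
        if min(self.n_control, self.n_patient, self.n_trials) <= 0:
            raise ValueError("cohort counts must be positive")
        if not (self.t_start < 0.0 < self.t_end):
            raise ValueError("epoch must bracket stimulus onset: t_start < 0 < t_end")
        if self.noise_exponent < 0:
            raise ValueError("noise exponent must be >= 0")
        for b in self.bursts:
            if self.fs <= 2.0 * b.center_frequency:
                raise ValueError(
                    f"fs={self.fs} Hz too low for a {b.center_frequency} Hz burst"
                )
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "bursts", tuple(self.bursts))
        object.__setattr__(self, "group_effects", tuple(self.group_effects))

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in ms, inclusive of both endpoints."""
        n = int(round((self.t_end - self.t_start) * self.fs / 1000.0)) + 1
        return self.t_start + np.arange(n) * 1000.0 / self.fs


@dataclass
class EpochedRecording:
    """One subject's epoched single-channel data (trials x samples)."""

    subject_id: str
    group: str
    modality: str
    fs: float
    times: np.ndarray
    data: np.ndarray
    truth: dict | None = None
    interp_mask: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != self.times.size:
            raise ValueError("data and times have mismatched sample counts")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def generate_noise(
    n_samples: int,
    exponent: float = 1.0,
    scale: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Zero-mean noise whose power spectrum follows ``f ** -exponent``.

    White Gaussian noise is shaped in the frequency domain by multiplying
    each positive-frequency bin by ``f ** (-exponent / 2)`` (the DC bin is
    zeroed), then scaled to RMS ``scale``.
    """
    if n_samples <= 1:
        raise ValueError("n_samples must be > 1")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    if scale == 0:
        return np.zeros(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples)
    spec[0] = 0.0
    spec[1:] = spec[1:] * f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n_samples)
    x -= x.mean()
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x *= scale / rms
    return x


def _noise_trials(config: CohortConfig, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Independent 1/f noise for each trial, shaped in one vectorized pass."""
    if config.noise_scale == 0:
        return np.zeros((config.n_trials, n_samples))
    white = rng.standard_normal((config.n_trials, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    spec[:, 0] = 0.0
    spec[:, 1:] *= f[1:] ** (-config.noise_exponent / 2.0)
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x * (config.noise_scale / rms)


def _effect_for(config: CohortConfig, target: str) -> GroupEffect:
    for eff in config.group_effects:
        if eff.target == target:
            return eff
    return GroupEffect(target=target)


def generate_subject(
    config: CohortConfig,
    group: str,
    subject_seed: int | np.random.SeedSequence,
    subject_id: str | None = None,
) -> EpochedRecording:
    """Generate one subject's trials x samples matrix.

    Patient-group subjects have the config's :class:`GroupEffect` entries
    applied to the matching component/burst specs before synthesis; the
    effective specs are retained in ``recording.truth``.
    """
    if group not in ("control", "patient"):
        raise ValueError("group must be 'control' or 'patient'")
    ss = (
        subject_seed
        if isinstance(subject_seed, np.random.SeedSequence)
        else np.random.SeedSequence(subject_seed)
    )
    rng = np.random.default_rng(ss)
    times = config.times
    t = times / 1000.0  # seconds
    n_samples = times.size

    components = list(config.components)
    bursts = list(config.bursts)
    if group == "patient":
        components = [
            replace(
                c,
                amplitude=c.amplitude * _effect_for(config, c.name).amplitude_ratio,
                center_latency=c.center_latency + _effect_for(config, c.name).latency_shift,
            )
            for c in components
        ]
        bursts = [
            replace(
                b,
                amplitude=b.amplitude * _effect_for(config, b.band).amplitude_ratio,
                center_latency=b.center_latency + _effect_for(config, b.band).latency_shift,
            )
            for b in bursts
        ]

    data = _noise_trials(config, n_samples, rng)

    for c in components:
        jitter = (
            rng.normal(0.0, c.trial_jitter_sd, size=config.n_trials)
            if c.trial_jitter_sd > 0
            else np.zeros(config.n_trials)
        )
        centers = (c.center_latency + jitter)[:, None] / 1000.0
        env = np.exp(-((t[None, :] - centers) ** 2) / (2.0 * (c.width / 1000.0) ** 2))
        data += c.polarity * c.amplitude * env

    for b in bursts:
        phases = (
            np.zeros(config.n_trials)
            if b.phase_locked
            else rng.uniform(0.0, 2.0 * np.pi, size=config.n_trials)
        )
        jitter = (
            rng.normal(0.0, b.latency_jitter_sd, size=config.n_trials)
            if b.latency_jitter_sd > 0
            else np.zeros(config.n_trials)
        )
        centers = (b.center_latency + jitter)[:, None] / 1000.0
        dt = t[None, :] - centers
        env = np.exp(-(dt**2) / (2.0 * (b.envelope_sd / 1000.0) ** 2))
        data += b.amplitude * env * np.cos(
            2.0 * np.pi * b.center_frequency * dt + phases[:, None]
        )

    truth = {
        "components": tuple(components),
        "bursts": tuple(bursts),
        "group": group,
    }
    return EpochedRecording(
        subject_id=subject_id or f"{group}-?",
        group=group,
        modality=config.modality,
        fs=config.fs,
        times=times,
        data=data,
        truth=truth,
    )


def generate_cohort(config: CohortConfig) -> tuple[list[EpochedRecording], pd.DataFrame]:
    """Generate ``n_control + n_patient`` recordings plus a truth table.

    Per-subject random streams are spawned deterministically from
    ``config.seed`` via :class:`numpy.random.SeedSequence`, so the same
    config reproduces the cohort bitwise and subjects are independent.
    """
    root = np.random.SeedSequence(config.seed)
    n_total = config.n_control + config.n_patient
    children = root.spawn(n_total)
    recordings: list[EpochedRecording] = []
    rows = []
    for i in range(n_total):
        group = "control" if i < config.n_control else "patient"
        idx = i if group == "control" else i - config.n_control
        sid = f"{group}{idx:03d}"
        rec = generate_subject(config, group, children[i], subject_id=sid)
        recordings.append(rec)
        for c in rec.truth["components"]:
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "kind": "component",
                    "target": c.name,
                    "amplitude": c.amplitude,
                    "center_latency_ms": c.center_latency,
                    "frequency_hz": np.nan,
                }
            )
        for b in rec.truth["bursts"]:
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "kind": "burst",
                    "target": b.band,
                    "amplitude": b.amplitude,
                    "center_latency_ms": b.center_latency,
                    "frequency_hz": b.center_frequency,
                }
            )
    truth_table = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "group",
            "kind",
            "target",
            "amplitude",
            "center_latency_ms",
            "frequency_hz",
        ],
    )
    return recordings, truth_table
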