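"""Waveform-level preprocessing: filtering, epoching, artifact interpolation,
and stimulus-outlier run exclusion.

Filtering follows the recording pipeline's conventions: DC removal, a
fourth-order Butterworth band-pass (1-100 Hz or 100-250 Hz), and a 60 Hz
notch with harmonics (120, 180, 240 Hz).  Zero-phase (forward-backward)
application is the default so filtering never biases component-peak
latencies; a single-pass mode is available for fidelity experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import signal

from .cohort import EpochedRecording

__all__ = [
    "FilterSpec",
    "bandpass_notch",
    "epoch",
    "interpolate_stimulus_artifact",
    "reject_outlier_runs",
]

#: Named band presets (Hz).
FILTER_BANDS = {"low": (1.0, 100.0), "high": (100.0, 250.0)}


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + notch filter specification.

    ``band`` is ``(lo, hi)`` in Hz or one of the presets ``"low"``
    (1-100 Hz) / ``"high"`` (100-250 Hz).  ``notch`` lists notch centre
    frequencies; those at or above the band's upper edge or Nyquist are
    skipped.  ``zero_phase`` selects forward-backward application.
    """

    band: tuple[float, float] | str = "low"
    order: int = 4
    notch: tuple[float, ...] = (60.0, 120.0, 180.0, 240.0)
    notch_q: float = 30.0
    zero_phase: bool = True

    def edges(self) -> tuple[float, float]:
        band = FILTER_BANDS[self.band] if isinstance(self.band, str) else self.band
        lo, hi = float(band[0]), float(band[1])
        if not (0 < lo < hi):
            raise ValueError("band edges must satisfy 0 < lo < hi")
        return lo, hi


def _apply_sos(sos: np.ndarray, data: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        padlen = min(data.shape[-1] - 1, 3 * (sos.shape[0] * 2 + 1) * 10)
        return signal.sosfiltfilt(sos, data, axis=-1, padtype="even", padlen=padlen)
    return signal.sosfilt(sos, data, axis=-1)


def bandpass_notch(recording: EpochedRecording, spec: FilterSpec = FilterSpec()) -> EpochedRecording:
    """DC removal, Butterworth band-pass, and notch filtering, per trial.

    Trials are filtered independently with reflection padding (handled by
    the zero-phase filter); output shape equals input shape.
    """
    lo, hi = spec.edges()
    nyq = recording.fs / 2.0
    if hi >= nyq:
        raise ValueError(f"upper band edge {hi} Hz must be below Nyquist ({nyq} Hz)")
    data = recording.data - recording.data.mean(axis=1, keepdims=True)
    sos = signal.butter(spec.order, [lo, hi], btype="bandpass", fs=recording.fs, output="sos")
    data = _apply_sos(sos, data, spec.zero_phase)
    for f0 in spec.notch:
        if f0 >= min(hi, nyq):
            continue
        b, a = signal.iirnotch(f0, spec.notch_q, fs=recording.fs)
        nsos = signal.tf2sos(b, a)
        data = _apply_sos(nsos, data, spec.zero_phase)
    return EpochedRecording(
        subject_id=recording.subject_id,
        group=recording.group,
        modality=recording.modality,
        fs=recording.fs,
        times=recording.times,
        data=data,
        truth=recording.truth,
        interp_mask=recording.interp_mask,
    )


def epoch(
    continuous: np.ndarray,
    fs: float,
    event_times_ms: np.ndarray,
    t_start: float = -200.0,
    t_end: float = 500.0,
    subject_id: str = "subject",
    group: str = "control",
    modality: str = "MEG-like",
) -> EpochedRecording:
    """Cut trials from a continuous record around event times.

    The epoch window is inclusive of both endpoints at the sampling
    spacing, so [-200, 500] ms at 1 kHz yields 701 samples.  Events whose
    window exceeds the record bounds are dropped with a warning.
    """
    continuous = np.asarray(continuous, dtype=float)
    if continuous.ndim != 1:
        raise ValueError("continuous record must be 1-D")
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    n_rel = int(round((t_end - t_start) * fs / 1000.0)) + 1
    i_start = int(round(t_start * fs / 1000.0))
    trials = []
    for ev in np.atleast_1d(event_times_ms):
        i0 = int(round(ev * fs / 1000.0)) + i_start
        i1 = i0 + n_rel
        if i0 < 0 or i1 > continuous.size:
            warnings.warn(
                f"event at {ev} ms: epoch window exceeds record bounds; trial dropped",
                stacklevel=2,
            )
            continue
        trials.append(continuous[i0:i1])
    if not trials:
        raise ValueError("no events yielded a complete epoch")
    times = t_start + np.arange(n_rel) * 1000.0 / fs
    return EpochedRecording(
        subject_id=subject_id,
        group=group,
        modality=modality,
        fs=fs,
        times=times,
        data=np.stack(trials),
    )


def interpolate_stimulus_artifact(
    recording: EpochedRecording, t_lo: float = -10.0, t_hi: float = 10.0
) -> EpochedRecording:
    """Replace the stimulus-artifact segment by a per-trial linear bridge.

    Samples strictly inside ``(t_lo, t_hi)`` are replaced by the line
    joining the sample values at ``t_lo`` and ``t_hi``; the endpoint
    samples are unchanged.  A boolean mask of interpolated samples is
    attached so downstream statistics can exclude them.
    """
    if t_lo >= t_hi:
        raise ValueError("t_lo must be < t_hi")
    times = recording.times
    if t_lo < times[0] or t_hi > times[-1]:
        raise ValueError("interpolation window must lie inside the epoch")
    i_lo = int(np.argmin(np.abs(times - t_lo)))
    i_hi = int(np.argmin(np.abs(times - t_hi)))
    data = recording.data.copy()
    inner = np.arange(i_lo + 1, i_hi)
    if inner.size:
        frac = (times[inner] - times[i_lo]) / (times[i_hi] - times[i_lo])
        data[:, inner] = (
            recording.data[:, [i_lo]] * (1.0 - frac)[None, :]
            + recording.data[:, [i_hi]] * frac[None, :]
        )
    mask = np.zeros(times.size, dtype=bool)
    mask[inner] = True
    if recording.interp_mask is not None:
        mask |= recording.interp_mask
    return EpochedRecording(
        subject_id=recording.subject_id,
        group=recording.group,
        modality=recording.modality,
        fs=recording.fs,
        times=times,
        data=data,
        truth=recording.truth,
        interp_mask=mask,
    )


def reject_outlier_runs(
    run_features: pd.DataFrame,
    reference_trials: pd.DataFrame,
    k: float = 3.0,
) -> tuple[list, dict]:
    """Exclude runs whose features deviate more than ``k`` SD from reference.

    ``reference_trials`` holds trial-level feature vectors from the
    reference (checkerboard-only) condition; its per-feature mean and SD
    define the acceptance band.  A run is excluded iff any feature deviates
    strictly more than ``k`` standard deviations ("more than" -> strict
    inequality, so a run at exactly ``k`` SD is kept).  Zero-spread features
    are skipped with a warning.

    Returns the kept run index labels and an exclusion log mapping excluded
    run labels to their offending features.
    """
    if len(reference_trials) < 2:
        raise ValueError("need at least 2 reference trials to estimate spread")
    common = [c for c in run_features.columns if c in reference_trials.columns]
    if not common:
        raise ValueError("run and reference features share no columns")
    mean = reference_trials[common].mean()
    sd = reference_trials[common].std(ddof=1)
    usable = []
    for c in common:
        if sd[c] == 0:
            warnings.warn(f"feature {c!r} has zero spread in reference; skipped", stacklevel=2)
        else:
            usable.append(c)
    kept, log = [], {}
    for idx, row in run_features.iterrows():
        offending = [c for c in usable if abs(row[c] - mean[c]) > k * sd[c]]
        if offending:
            log[idx] = offending
        else:
            kept.append(idx)
    return kept, log
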