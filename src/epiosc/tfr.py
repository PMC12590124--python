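"""Morlet-wavelet time-frequency decomposition with evoked/induced modes.

The engine mirrors a standard virtual-sensor workflow: complex Morlet
wavelets (five cycles by default) on a 1 Hz frequency grid, squared
magnitude as power, "spectral flattening" (multiplying each frequency bin by
its frequency) to counteract 1/f power decay for ranges up to 100 Hz, and
baseline correction expressed as relative percentage change (RPC) against
the prestimulus window.

Two response modes are provided:

* evoked  — wavelet transform of the trial-averaged waveform; phase-locked
  activity survives the averaging, non-phase-locked activity attenuates.
* induced — per-trial wavelet transforms, each flattened and
  baseline-corrected, then averaged; non-phase-locked activity is retained.

Edge handling: the signal is reflection-padded before convolution and a
validity mask flags, per frequency, the samples within half the (truncated)
wavelet support of either epoch edge.  Statistics downstream consume only
valid pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import next_fast_len, rfft, irfft

from .cohort import EpochedRecording

__all__ = [
    "TFRMap",
    "BAND_RANGES",
    "morlet_power",
    "spectral_flatten",
    "baseline_rpc",
    "evoked_tfr",
    "induced_tfr",
    "oscillation_mask",
]

#: Named frequency ranges (Hz, inclusive, 1 Hz steps).  ``low``/``mid`` are
#: the induced-analysis ranges; ``full`` is the evoked 1-100 Hz grid and
#: ``high`` the 100-250 Hz grid that is never flattened.
BAND_RANGES = {
    "low": (1, 30),
    "mid": (30, 100),
    "high": (100, 250),
    "full": (1, 100),
}

#: Above this frequency, flattening overcompensates and is refused.
_FLATTEN_MAX_HZ = 100.0


@dataclass
class TFRMap:
    """Frequencies x times power map with provenance flags.

    ``values`` holds raw power, flattened power, or RPC (%) depending on the
    flags.  ``valid`` marks pixels outside the wavelet edge-effect zone.
    ``power`` optionally retains the uncorrected (possibly flattened) power
    counterpart of an RPC map, needed by :func:`oscillation_mask`.
    """

    frequencies: np.ndarray
    times: np.ndarray
    values: np.ndarray
    mode: str = "raw"
    band_range: tuple[float, float] = (1.0, 100.0)
    flattened: bool = False
    baseline_corrected: bool = False
    n_trials_in: int = 1
    valid: np.ndarray | None = None
    power: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.frequencies.size, self.times.size):
            raise ValueError("values must be (n_frequencies, n_times)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TFR values must be finite")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)

    def copy_with(self, **kw) -> "TFRMap":
        base = dict(
            frequencies=self.frequencies,
            times=self.times,
            values=self.values,
            mode=self.mode,
            band_range=self.band_range,
            flattened=self.flattened,
            baseline_corrected=self.baseline_corrected,
            n_trials_in=self.n_trials_in,
            valid=self.valid,
            power=self.power,
            meta=dict(self.meta),
        )
        base.update(kw)
        return TFRMap(**base)


def _morlet_bank(frequencies: np.ndarray, fs: float, n_cycles: float, n_samples: int):
    """Unit-energy complex Morlet wavelets, zero-padded to a common centred
    length, plus the per-frequency half-support (samples) for edge masking.

    Wavelets are truncated at +-3 temporal SDs (99.7% of the Gaussian
    envelope) and capped at the signal length.
    """
    sigmas = n_cycles / (2.0 * np.pi * frequencies)  # seconds
    halves = np.minimum(np.ceil(3.0 * sigmas * fs).astype(int), n_samples - 1)
    half_max = int(halves.max())
    length = 2 * half_max + 1
    bank = np.zeros((frequencies.size, length), dtype=complex)
    for i, (f, sig, h) in enumerate(zip(frequencies, sigmas, halves)):
        t = np.arange(-h, h + 1) / fs
        w = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2.0 * sig**2))
        w /= np.sqrt(np.sum(np.abs(w) ** 2))
        bank[i, half_max - h : half_max + h + 1] = w
    return bank, halves, half_max


def _wavelet_power(
    data: np.ndarray, fs: float, frequencies: np.ndarray, n_cycles: float
) -> tuple[np.ndarray, np.ndarray]:
    """Power (trials x freqs x times) and per-frequency edge half-support."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_trials, n = data.shape
    bank, halves, half_max = _morlet_bank(frequencies, fs, n_cycles, n)

    pad = min(half_max, n - 1)
    padded = np.concatenate(
        [data[:, pad:0:-1], data, data[:, -2 : -pad - 2 : -1]], axis=1
    )
    n_pad = padded.shape[1]
    nfft = next_fast_len(n_pad + bank.shape[1] - 1)
    f_sig = np.fft.fft(padded, n=nfft, axis=1)

    power = np.empty((n_trials, frequencies.size, n), dtype=float)
    # chunk over frequencies to bound the (trials x freqs x nfft) workspace
    chunk = max(1, int(4e7 // (n_trials * nfft)))
    offset = pad + half_max  # full-conv index of signal sample 0
    for lo in range(0, frequencies.size, chunk):
        hi = min(lo + chunk, frequencies.size)
        f_w = np.fft.fft(bank[lo:hi], n=nfft, axis=1)
        conv = np.fft.ifft(f_sig[:, None, :] * f_w[None, :, :], axis=2)
        power[:, lo:hi, :] = np.abs(conv[:, :, offset : offset + n]) ** 2
    return power, halves


def morlet_power(
    waveform: np.ndarray,
    fs: float,
    frequencies: np.ndarray,
    times: np.ndarray | None = None,
    n_cycles: float = 5.0,
) -> TFRMap:
    """Raw wavelet power of a single waveform.

    Power is the squared magnitude of the complex wavelet transform using
    unit-energy wavelets, so raw power is comparable across frequencies
    before flattening.  Samples within half the wavelet support of either
    edge are flagged invalid in ``map.valid``.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise ValueError("morlet_power expects a 1-D waveform")
    frequencies = np.asarray(frequencies, dtype=float)
    if np.any(frequencies <= 0):
        raise ValueError("frequencies must be positive")
    if np.any(frequencies >= fs / 2.0):
        raise ValueError("frequencies must lie below the Nyquist frequency")
    n = waveform.size
    if times is None:
        times = np.arange(n, dtype=float) * 1000.0 / fs
    power, halves = _wavelet_power(waveform, fs, frequencies, n_cycles)
    valid = np.ones((frequencies.size, n), dtype=bool)
    for i, h in enumerate(halves):
        h = int(h)
        if h > 0:
            valid[i, :h] = False
            valid[i, n - h :] = False
    return TFRMap(
        frequencies=frequencies,
        times=np.asarray(times, dtype=float),
        values=power[0],
        mode="raw",
        band_range=(float(frequencies.min()), float(frequencies.max())),
        valid=valid,
        meta={"n_cycles": n_cycles, "fs": fs},
    )


def spectral_flatten(tfr: TFRMap) -> TFRMap:
    """Multiply each frequency bin's power by its frequency value.

    Counteracts 1/f power decay so low-frequency power does not swamp the
    gamma range.  Refused above 100 Hz, where the correction overcompensates,
    and on maps that are already flattened or baseline-corrected.
    """
    if tfr.flattened:
        raise ValueError("map is already spectrally flattened")
    if tfr.baseline_corrected:
        raise ValueError("cannot flatten a baseline-corrected (RPC) map")
    if tfr.band_range[1] > _FLATTEN_MAX_HZ:
        raise ValueError(
            "spectral flattening is only applied up to 100 Hz; the "
            f"{tfr.band_range} Hz range is left unadjusted"
        )
    values = tfr.values * tfr.frequencies[:, None]
    return tfr.copy_with(values=values, flattened=True)


def _baseline_means(tfr: TFRMap, baseline: tuple[float, float]):
    lo, hi = baseline
    sel = (tfr.times >= lo) & (tfr.times <= hi)
    if sel.sum() < 10:
        raise ValueError("baseline window must contain at least 10 samples")
    fallback = []
    b = np.empty(tfr.frequencies.size)
    for i in range(tfr.frequencies.size):
        ok = sel & tfr.valid[i]
        if ok.sum() >= 10:
            b[i] = tfr.values[i, ok].mean()
        else:
            # wavelet support exceeds the baseline at this frequency; fall
            # back to the full baseline window and record the degradation
            b[i] = tfr.values[i, sel].mean()
            fallback.append(float(tfr.frequencies[i]))
    return b, fallback


def baseline_rpc(tfr: TFRMap, baseline: tuple[float, float] = (-200.0, 0.0)) -> TFRMap:
    """Relative percentage change against the prestimulus baseline.

    ``values[f, t] <- 100 * (values[f, t] - B_f) / B_f`` with ``B_f`` the
    mean baseline power at frequency ``f`` (valid samples; frequencies whose
    edge mask swallows the baseline fall back to all baseline samples and
    are listed in ``meta['baseline_fallback_hz']``).
    """
    if tfr.baseline_corrected:
        raise ValueError("map is already baseline-corrected")
    b, fallback = _baseline_means(tfr, baseline)
    if np.any(b == 0):
        raise ValueError("zero baseline power; cannot form relative change")
    values = 100.0 * (tfr.values - b[:, None]) / b[:, None]
    meta = dict(tfr.meta)
    meta["baseline_window_ms"] = tuple(baseline)
    if fallback:
        meta["baseline_fallback_hz"] = fallback
    return tfr.copy_with(
        values=values, baseline_corrected=True, power=tfr.values, meta=meta
    )


def _resolve_range(band_range) -> tuple[int, int]:
    if isinstance(band_range, str):
        band_range = BAND_RANGES[band_range]
    lo, hi = int(band_range[0]), int(band_range[1])
    if lo <= 0 or hi <= lo:
        raise ValueError("band range must satisfy 0 < lo < hi")
    return lo, hi


def evoked_tfr(
    recording: EpochedRecording,
    band_range="full",
    n_cycles: float = 5.0,
    baseline: tuple[float, float] = (-200.0, 0.0),
) -> TFRMap:
    """Evoked-response TFR: average trials, then transform.

    Pipeline: trial average -> Morlet power on the 1 Hz grid -> spectral
    flattening (ranges up to 100 Hz only) -> baseline RPC.
    """
    if recording.n_trials < 1:
        raise ValueError("recording has no trials")
    lo, hi = _resolve_range(band_range)
    freqs = np.arange(lo, hi + 1, dtype=float)
    avg = recording.data.mean(axis=0)
    tfr = morlet_power(avg, recording.fs, freqs, times=recording.times, n_cycles=n_cycles)
    tfr.band_range = (float(lo), float(hi))
    if hi <= _FLATTEN_MAX_HZ:
        tfr = spectral_flatten(tfr)
    tfr = baseline_rpc(tfr, baseline)
    return tfr.copy_with(mode="evoked", n_trials_in=recording.n_trials)


def induced_tfr(
    recording: EpochedRecording,
    band_range="mid",
    n_cycles: float = 5.0,
    baseline: tuple[float, float] = (-200.0, 0.0),
) -> TFRMap:
    """Induced-response TFR: transform each trial, correct, then average.

    Per trial: Morlet power -> spectral flattening (low/mid ranges only) ->
    baseline RPC; the per-trial corrected maps are averaged.  The trial-mean
    uncorrected power is retained in ``map.power``.
    """
    if recording.n_trials < 2:
        raise ValueError("induced TFR requires at least 2 trials")
    lo, hi = _resolve_range(band_range)
    freqs = np.arange(lo, hi + 1, dtype=float)
    if np.any(freqs >= recording.fs / 2.0):
        raise ValueError("frequencies must lie below the Nyquist frequency")
    power, halves = _wavelet_power(recording.data, recording.fs, freqs, n_cycles)
    n = recording.times.size
    valid = np.ones((freqs.size, n), dtype=bool)
    for i, h in enumerate(halves):
        h = int(h)
        if h > 0:
            valid[i, :h] = False
            valid[i, n - h :] = False
    flattened = hi <= _FLATTEN_MAX_HZ
    if flattened:
        power = power * freqs[None, :, None]

    # per-trial baseline means, per frequency (valid samples, with fallback)
    bl_lo, bl_hi = baseline
    sel = (recording.times >= bl_lo) & (recording.times <= bl_hi)
    if sel.sum() < 10:
        raise ValueError("baseline window must contain at least 10 samples")
    fallback = []
    b = np.empty((recording.n_trials, freqs.size))
    for i in range(freqs.size):
        ok = sel & valid[i]
        if ok.sum() >= 10:
            b[:, i] = power[:, i, ok].mean(axis=1)
        else:
            b[:, i] = power[:, i, sel].mean(axis=1)
            fallback.append(float(freqs[i]))
    if np.any(b == 0):
        raise ValueError("zero baseline power in at least one trial")
    rpc = 100.0 * (power - b[:, :, None]) / b[:, :, None]
    values = rpc.mean(axis=0)
    meta = {
        "n_cycles": n_cycles,
        "fs": recording.fs,
        "baseline_window_ms": tuple(baseline),
    }
    if fallback:
        meta["baseline_fallback_hz"] = fallback
    return TFRMap(
        frequencies=freqs,
        times=recording.times,
        values=values,
        mode="induced",
        band_range=(float(lo), float(hi)),
        flattened=flattened,
        baseline_corrected=True,
        n_trials_in=recording.n_trials,
        valid=valid,
        power=power.mean(axis=0),
        meta=meta,
    )


def oscillation_mask(
    tfr: TFRMap, factor: float = 2.0, baseline: tuple[float, float] = (-200.0, 0.0)
) -> np.ndarray:
    """Pixels whose amplitude is at least ``factor`` x the background.

    Amplitude is ``sqrt(power)`` of the uncorrected power counterpart
    (``map.power`` for corrected maps, ``map.values`` for raw ones); the
    background at each frequency is the mean baseline-window amplitude.
    "At least" is read inclusively (>=).
    """
    power = tfr.power if tfr.baseline_corrected else tfr.values
    if power is None:
        raise ValueError("no uncorrected power counterpart available")
    amp = np.sqrt(np.maximum(power, 0.0))
    ref = tfr.copy_with(
        values=amp, baseline_corrected=False, flattened=tfr.flattened, power=None
    )
    bg, _ = _baseline_means(ref, baseline)
    return amp >= factor * bg[:, None]
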