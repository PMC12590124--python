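"""Per-band TFR feature extraction and min-max normalization.

For each oscillatory band (beta 15-29 Hz, narrowband gamma 30-100 Hz,
broadband gamma 100-250 Hz) and analysis window, four features are taken
from a baseline-corrected TFR map: the peak frequency (frequency of the
largest post-stimulus power change), peak latency, peak amplitude (the RPC
value at that pixel), and the average relative power change over the
window.  The 100 Hz bin, which appears on both the 30-100 and 100-250 Hz
grids, is assigned to narrowband gamma only.

Features can alternatively be reported on an amplitude scale,
``sqrt(max(RPC, 0) / 100)`` — the oscillatory amplitude in units of the
baseline amplitude — which makes a planted waveform-amplitude ratio between
groups directly recoverable (power scales with the square of amplitude).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tfr import TFRMap

__all__ = [
    "BandWindow",
    "BandFeatures",
    "BAND_PRESETS",
    "extract_band_features",
    "minmax_normalize",
    "normalize_feature_table",
]


@dataclass(frozen=True)
class BandWindow:
    """Frequency band x analysis-window rectangle.

    ``f_lo_inclusive`` is False for broadband gamma so the shared 100 Hz
    bin belongs to narrowband gamma only.  ``t_lo`` defaults to 10 ms: the
    interpolated stimulus-onset segment is excluded from statistics.
    """

    band: str
    f_lo: float
    f_hi: float
    t_lo: float = 10.0
    t_hi: float = 500.0
    f_lo_inclusive: bool = True

    def __post_init__(self):
        if self.f_lo >= self.f_hi:
            raise ValueError("f_lo must be < f_hi")
        if self.t_lo >= self.t_hi:
            raise ValueError("t_lo must be < t_hi")


#: Default analysis windows per band (10-500 ms post-stimulus).
BAND_PRESETS = {
    "beta": BandWindow("beta", 15.0, 29.0),
    "NBG": BandWindow("NBG", 30.0, 100.0),
    "BBG": BandWindow("BBG", 100.0, 250.0, f_lo_inclusive=False),
}


@dataclass
class BandFeatures:
    band: str
    peak_frequency: float
    peak_latency: float
    peak_amplitude: float
    avg_power: float
    missing: bool = False


def extract_band_features(
    tfr: TFRMap, window: BandWindow | str, scale: str = "power"
) -> BandFeatures:
    """Extract the four band features from a baseline-corrected map.

    The peak is the maximum pixel inside the band x window rectangle
    (valid pixels only); ties break to the earliest latency, then lowest
    frequency.  ``avg_power`` is the mean value over the rectangle's valid
    pixels.  ``scale="amplitude"`` converts RPC to ``sqrt(max(RPC,0)/100)``
    before reporting amplitude-like quantities.
    """
    if isinstance(window, str):
        window = BAND_PRESETS[window]
    if scale not in ("power", "amplitude"):
        raise ValueError("scale must be 'power' or 'amplitude'")
    if not tfr.baseline_corrected:
        raise ValueError("band features are defined on baseline-corrected maps")
    f = tfr.frequencies
    t = tfr.times
    fsel = (f >= window.f_lo if window.f_lo_inclusive else f > window.f_lo) & (f <= window.f_hi)
    tsel = (t >= window.t_lo) & (t <= window.t_hi)
    if not fsel.any() or not tsel.any():
        raise ValueError("band window lies outside the map domain")
    sub = tfr.values[np.ix_(fsel, tsel)]
    ok = tfr.valid[np.ix_(fsel, tsel)]
    if not ok.any():
        return BandFeatures(window.band, np.nan, np.nan, np.nan, np.nan, missing=True)
    vals = sub if scale == "power" else np.sqrt(np.maximum(sub, 0.0) / 100.0)
    masked = np.where(ok, vals, -np.inf)
    # time-major flattening makes the first argmax the earliest latency,
    # then the lowest frequency, matching the tie-break rule
    flat = masked.T.reshape(-1)
    k = int(np.argmax(flat))
    ti, fi = divmod(k, masked.shape[0])
    return BandFeatures(
        band=window.band,
        peak_frequency=float(f[fsel][fi]),
        peak_latency=float(t[tsel][ti]),
        peak_amplitude=float(vals[fi, ti]),
        avg_power=float(vals[ok].mean()),
    )


def minmax_normalize(values) -> np.ndarray:
    """Min-max normalization across participants: (x - min) / (max - min)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = np.min(x), np.max(x)
    if lo == hi:
        raise ValueError("all values equal; min-max normalization undefined")
    return (x - lo) / (hi - lo)


def normalize_feature_table(
    table: pd.DataFrame, columns: list[str] | None = None, suffix: str = "_norm"
) -> pd.DataFrame:
    """Append min-max-normalized columns; constant columns are skipped."""
    out = table.copy()
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    for c in columns:
        x = table[c].to_numpy(dtype=float)
        if np.nanmin(x) == np.nanmax(x):
            continue
        out[c + suffix] = (x - np.nanmin(x)) / (np.nanmax(x) - np.nanmin(x))
    return out
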