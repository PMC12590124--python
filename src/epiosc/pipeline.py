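"""End-to-end convenience: cohort -> preprocessing -> TFR features table ->
group statistics -> classification.

These helpers wire the individual modules together the way the study
design intends: stimulus-artifact interpolation, evoked and induced TFRs
per subject, the four band features per response mode, min-max-normalized
feature columns, and an RBF-SVM on ANOVA-screened features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortConfig, EpochedRecording, generate_cohort
from .features import BAND_PRESETS, extract_band_features
from .preprocess import interpolate_stimulus_artifact
from .tfr import evoked_tfr, induced_tfr

__all__ = ["subject_feature_row", "cohort_feature_table", "feature_matrix"]

# which TFR band range feeds each band's features, per response mode
_INDUCED_RANGE = {"beta": "low", "NBG": "mid", "BBG": "high"}
_EVOKED_RANGE = {"beta": "full", "NBG": "full", "BBG": "high"}


def subject_feature_row(
    recording: EpochedRecording,
    bands: tuple[str, ...] = ("beta", "NBG", "BBG"),
    modes: tuple[str, ...] = ("evoked", "induced"),
    scale: str = "power",
    interpolate_artifact: bool = True,
) -> dict:
    """All band features of one subject as a flat ``{column: value}`` row."""
    rec = interpolate_stimulus_artifact(recording) if interpolate_artifact else recording
    row: dict = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "modality": rec.modality,
    }
    cache: dict = {}
    for mode in modes:
        ranges = _EVOKED_RANGE if mode == "evoked" else _INDUCED_RANGE
        for band in bands:
            rng_name = ranges[band]
            key = (mode, rng_name)
            if key not in cache:
                cache[key] = (
                    evoked_tfr(rec, rng_name)
                    if mode == "evoked"
                    else induced_tfr(rec, rng_name)
                )
            feats = extract_band_features(cache[key], BAND_PRESETS[band], scale=scale)
            prefix = f"{mode}_{band}"
            row[f"{prefix}_peak_frequency"] = feats.peak_frequency
            row[f"{prefix}_peak_latency"] = feats.peak_latency
            row[f"{prefix}_peak_amplitude"] = feats.peak_amplitude
            row[f"{prefix}_avg_power"] = feats.avg_power
    return row


def cohort_feature_table(
    recordings: list[EpochedRecording] | CohortConfig,
    bands: tuple[str, ...] = ("beta", "NBG", "BBG"),
    modes: tuple[str, ...] = ("evoked", "induced"),
    scale: str = "power",
) -> pd.DataFrame:
    """Feature table (one row per subject) for a cohort or cohort config."""
    if isinstance(recordings, CohortConfig):
        recordings, _ = generate_cohort(recordings)
    rows = [subject_feature_row(r, bands=bands, modes=modes, scale=scale) for r in recordings]
    return pd.DataFrame(rows)


def feature_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a feature table into (numeric features, binary labels).

    Labels are 1 for the patient group, 0 for controls.
    """
    y = (table["group"].to_numpy() == "patient").astype(int)
    X = table.drop(columns=[c for c in ("subject_id", "group", "modality") if c in table])
    return X, y
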