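"""Cohort containers on disk: one HDF5 file per cohort, or a directory of
per-subject CSV matrices with a JSON metadata sidecar.

Both dialects round-trip float64 data bit-exactly (the CSV dialect writes
17 significant digits, which uniquely represents every double).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .cohort import EpochedRecording

__all__ = [
    "save_cohort_hdf5",
    "load_cohort_hdf5",
    "save_cohort_csv",
    "load_cohort_csv",
]


def save_cohort_hdf5(recordings: list[EpochedRecording], path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("subjects")
        for rec in recordings:
            g = grp.create_group(rec.subject_id)
            g.create_dataset("data", data=rec.data, dtype="float64")
            g.attrs["fs"] = rec.fs
            g.attrs["group"] = rec.group
            g.attrs["modality"] = rec.modality
            g.attrs["times_ms"] = rec.times
            if rec.interp_mask is not None:
                g.create_dataset("interp_mask", data=rec.interp_mask.astype(np.uint8))


def load_cohort_hdf5(path) -> list[EpochedRecording]:
    out = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subjects"]):
            g = f["subjects"][sid]
            mask = g["interp_mask"][()].astype(bool) if "interp_mask" in g else None
            out.append(
                EpochedRecording(
                    subject_id=sid,
                    group=g.attrs["group"],
                    modality=g.attrs["modality"],
                    fs=float(g.attrs["fs"]),
                    times=np.asarray(g.attrs["times_ms"], dtype=float),
                    data=g["data"][()],
                    interp_mask=mask,
                )
            )
    return out


def save_cohort_csv(recordings: list[EpochedRecording], directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {}
    for rec in recordings:
        np.savetxt(d / f"{rec.subject_id}.csv", rec.data, fmt="%.17g", delimiter=",")
        meta[rec.subject_id] = {
            "fs": rec.fs,
            "group": rec.group,
            "modality": rec.modality,
            "times_ms": [float(t) for t in rec.times],
            "interp_mask": (
                rec.interp_mask.astype(int).tolist() if rec.interp_mask is not None else None
            ),
        }
    (d / "metadata.json").write_text(json.dumps(meta, indent=1))


def load_cohort_csv(directory) -> list[EpochedRecording]:
    d = Path(directory)
    meta = json.loads((d / "metadata.json").read_text())
    out = []
    for sid in sorted(meta):
        m = meta[sid]
        mask = np.asarray(m["interp_mask"], dtype=bool) if m["interp_mask"] is not None else None
        out.append(
            EpochedRecording(
                subject_id=sid,
                group=m["group"],
                modality=m["modality"],
                fs=float(m["fs"]),
                times=np.asarray(m["times_ms"], dtype=float),
                data=np.loadtxt(d / f"{sid}.csv", delimiter=",", ndmin=2),
                interp_mask=mask,
            )
        )
    return out
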