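"""Readers and writers for the toolkit's on-disk formats.

CSV dialects (UTF-8, LF, decimal point, floats at >= 9 significant digits):

* ``intensity`` — header ``time_s, ch01_w690..ch12_w690, ch01_w830..ch12_w830``
* ``hemo``      — header ``time_s, ch01_HbO..ch12_HbO, ch01_HbR..ch12_HbR``

plus TSV tables for schedules (kind, onset_s, duration_s, trial_index, label),
labels (trial_index, label, onset_s) and fold reports, and a minimal SNIRF
(HDF5) reader/writer covering the format's required fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .hemodynamics import DataError, HemoSeries, N_CHANNELS, OpticalRecording
from .paradigm import Event

__all__ = [
    "SchemaError",
    "write_intensity_csv", "read_intensity_csv",
    "write_hemo_csv", "read_hemo_csv",
    "write_schedule_tsv", "read_schedule_tsv",
    "write_labels_tsv", "read_labels_tsv",
    "write_snirf", "read_snirf",
    "read_recording", "write_recording",
    "SNIRF_CHANNEL_PAIRS",
]

_FLOAT_FMT = "%.10g"

#: (source, detector) pair per channel for the 8-emitter / 3-detector montage.
SNIRF_CHANNEL_PAIRS = [
    (1, 1), (2, 1), (3, 1), (4, 1),
    (3, 2), (4, 2), (5, 2), (6, 2),
    (5, 3), (6, 3), (7, 3), (8, 3),
]


class SchemaError(ValueError):
    """A file does not match the expected dialect."""


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _intensity_columns(n_channels: int) -> list[str]:
    return ([f"ch{c:02d}_w690" for c in range(1, n_channels + 1)]
            + [f"ch{c:02d}_w830" for c in range(1, n_channels + 1)])


def _hemo_columns(n_channels: int) -> list[str]:
    return ([f"ch{c:02d}_HbO" for c in range(1, n_channels + 1)]
            + [f"ch{c:02d}_HbR" for c in range(1, n_channels + 1)])


def write_intensity_csv(rec: OpticalRecording, path) -> None:
    n = len(rec.channel_ids)
    t = np.arange(rec.n_samples) / rec.fs
    data = {"time_s": t}
    for w, name in ((0, "w690"), (1, "w830")):
        for i, ch in enumerate(rec.channel_ids):
            data[f"ch{ch:02d}_{name}"] = rec.intensity[:, i, w]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT,
                              lineterminator="\n")


def read_intensity_csv(path, n_channels: int = N_CHANNELS) -> OpticalRecording:
    df = pd.read_csv(path)
    _check_columns(df, ["time_s"] + _intensity_columns(n_channels), path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if t.size > 1 else 1.0
    intensity = np.stack([
        df[[f"ch{c:02d}_w690" for c in range(1, n_channels + 1)]].to_numpy(),
        df[[f"ch{c:02d}_w830" for c in range(1, n_channels + 1)]].to_numpy(),
    ], axis=2)
    return OpticalRecording(intensity, fs=float(fs),
                            channel_ids=tuple(range(1, n_channels + 1)))


def write_hemo_csv(hemo: HemoSeries, path) -> None:
    t = np.arange(hemo.n_samples) / hemo.fs
    data = {"time_s": t}
    for i, ch in enumerate(hemo.channel_ids):
        data[f"ch{ch:02d}_HbO"] = hemo.dhbo[:, i]
    for i, ch in enumerate(hemo.channel_ids):
        data[f"ch{ch:02d}_HbR"] = hemo.dhbr[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT,
                              lineterminator="\n")


def read_hemo_csv(path, n_channels: int = N_CHANNELS) -> HemoSeries:
    df = pd.read_csv(path)
    _check_columns(df, ["time_s"] + _hemo_columns(n_channels), path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if t.size > 1 else 1.0
    dhbo = df[[f"ch{c:02d}_HbO" for c in range(1, n_channels + 1)]].to_numpy()
    dhbr = df[[f"ch{c:02d}_HbR" for c in range(1, n_channels + 1)]].to_numpy()
    return HemoSeries(dhbo, dhbr, fs=float(fs),
                      channel_ids=tuple(range(1, n_channels + 1)))


def write_schedule_tsv(events: list[Event], path) -> None:
    pd.DataFrame([{
        "kind": ev.kind, "onset_s": ev.onset_s, "duration_s": ev.duration_s,
        "trial_index": "" if ev.trial_index is None else ev.trial_index,
        "label": "" if ev.label is None else ev.label,
    } for ev in events]).to_csv(path, sep="\t", index=False,
                                float_format=_FLOAT_FMT, lineterminator="\n")


def read_schedule_tsv(path) -> list[Event]:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["kind", "onset_s", "duration_s", "trial_index", "label"], path)
    events = []
    for row in df.itertuples(index=False):
        idx = None if pd.isna(row.trial_index) or row.trial_index == "" \
            else int(row.trial_index)
        lab = None if pd.isna(row.label) or row.label == "" else str(row.label)
        events.append(Event(str(row.kind), float(row.onset_s),
                            float(row.duration_s), idx, lab))
    return events


def write_labels_tsv(table: pd.DataFrame, path) -> None:
    table[["trial_index", "label", "onset_s"]].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_labels_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["trial_index", "label", "onset_s"], path)
    return df


# ---------------------------------------------------------------------------
# SNIRF (HDF5)
# ---------------------------------------------------------------------------

def _snirf_meta(group, fs: float) -> None:
    tags = group.create_group("metaDataTags")
    tags.create_dataset("SubjectID", data="synthetic")
    tags.create_dataset("MeasurementDate", data="unknown")
    tags.create_dataset("MeasurementTime", data="unknown")
    tags.create_dataset("LengthUnit", data="cm")
    tags.create_dataset("TimeUnit", data="s")
    tags.create_dataset("FrequencyUnit", data="Hz")


def _snirf_probe(group, wavelengths) -> None:
    probe = group.create_group("probe")
    probe.create_dataset("wavelengths", data=np.asarray(wavelengths, dtype=float))
    # nominal positions on a forehead arc; geometry is presentational here
    src = np.array([[np.cos(a), np.sin(a), 0.0]
                    for a in np.linspace(0.2, np.pi - 0.2, 8)])
    det = np.array([[np.cos(a), np.sin(a), 0.0]
                    for a in np.linspace(0.6, np.pi - 0.6, 3)])
    probe.create_dataset("sourcePos3D", data=src)
    probe.create_dataset("detectorPos3D", data=det)


def write_snirf(obj: "OpticalRecording | HemoSeries", path) -> None:
    """Write a recording or concentration series as a SNIRF v1.0 file.

    Intensities use measurement dataType 1 (CW amplitude); concentration
    series use dataType 99999 with dataTypeLabel HbO / HbR.
    """
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        if isinstance(obj, OpticalRecording):
            fs, n = obj.fs, obj.n_samples
            ts = np.hstack([obj.intensity[:, :, 0], obj.intensity[:, :, 1]])
            cols = []
            for wi in range(2):
                for ci, ch in enumerate(obj.channel_ids):
                    cols.append(("intensity", ch, wi))
            _snirf_probe(nirs, obj.wavelengths_nm)
        else:
            fs, n = obj.fs, obj.n_samples
            ts = np.hstack([obj.dhbo, obj.dhbr])
            cols = [("HbO", ch, 0) for ch in obj.channel_ids] \
                + [("HbR", ch, 1) for ch in obj.channel_ids]
            _snirf_probe(nirs, (690, 830))
        data.create_dataset("dataTimeSeries", data=ts)
        data.create_dataset("time", data=np.arange(n) / fs)
        for mi, (kind, ch, wi) in enumerate(cols, start=1):
            ml = data.create_group(f"measurementList{mi}")
            s, d = SNIRF_CHANNEL_PAIRS[(ch - 1) % len(SNIRF_CHANNEL_PAIRS)]
            ml.create_dataset("sourceIndex", data=s)
            ml.create_dataset("detectorIndex", data=d)
            ml.create_dataset("wavelengthIndex", data=wi + 1)
            ml.create_dataset("dataTypeIndex", data=1)
            if kind == "intensity":
                ml.create_dataset("dataType", data=1)
            else:
                ml.create_dataset("dataType", data=99999)
                ml.create_dataset("dataTypeLabel", data=kind)
        _snirf_meta(nirs, fs)


def _h5_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def read_snirf(path) -> "OpticalRecording | HemoSeries":
    """Read back a file written by :func:`write_snirf`."""
    import h5py

    with h5py.File(path, "r") as f:
        data = f["nirs"]["data1"]
        ts = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        fs = 1.0 / np.median(np.diff(time)) if time.size > 1 else 1.0
        ml_names = sorted((k for k in data.keys() if k.startswith("measurementList")),
                          key=lambda k: int(k[len("measurementList"):]))
        dtypes = [int(data[k]["dataType"][()]) for k in ml_names]
        n_meas = len(ml_names)
        if n_meas % 2:
            raise SchemaError(f"{path}: odd measurement count {n_meas}")
        half = n_meas // 2
        if all(dt == 1 for dt in dtypes):
            intensity = np.stack([ts[:, :half], ts[:, half:]], axis=2)
            return OpticalRecording(intensity, fs=float(fs),
                                    channel_ids=tuple(range(1, half + 1)))
        labels = [_h5_str(data[k]["dataTypeLabel"]) for k in ml_names]
        hbo = ts[:, [i for i, lab in enumerate(labels) if lab == "HbO"]]
        hbr = ts[:, [i for i, lab in enumerate(labels) if lab == "HbR"]]
        if hbo.shape[1] != hbr.shape[1] or hbo.shape[1] == 0:
            raise SchemaError(f"{path}: unbalanced HbO/HbR measurement lists")
        return HemoSeries(hbo, hbr, fs=float(fs),
                          channel_ids=tuple(range(1, hbo.shape[1] + 1)))


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_recording(path, format: str):
    """Read by dialect name: ``csv-intensity``, ``csv-hemo`` or ``snirf``."""
    if format == "csv-intensity":
        return read_intensity_csv(path)
    if format == "csv-hemo":
        return read_hemo_csv(path)
    if format == "snirf":
        return read_snirf(path)
    raise SchemaError(f"unknown format {format!r}")


def write_recording(obj, path, format: str) -> None:
    if format == "csv-intensity":
        if not isinstance(obj, OpticalRecording):
            raise DataError("csv-intensity expects an OpticalRecording")
        write_intensity_csv(obj, path)
    elif format == "csv-hemo":
        if not isinstance(obj, HemoSeries):
            raise DataError("csv-hemo expects a HemoSeries")
        write_hemo_csv(obj, path)
    elif format == "snirf":
        write_snirf(obj, path)
    else:
        raise SchemaError(f"unknown format {format!r}")
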