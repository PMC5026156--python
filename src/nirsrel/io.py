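"""Plain-text I/O for recordings and haemoglobin series, plus optional
SNIRF (HDF5) export for interoperability.

A recording is stored as a tidy long-format CSV of optical density
(columns: time, channel, wavelength, od), a JSON sidecar with the design
and scalar ground truth, and an optional long-format CSV of the
ground-truth component series (time, channel, functional, systemic).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignSpec
from .errors import InputError
from .preprocess import HaemoSeries
from .simulate import GroundTruth, MotionEvent, RawRecording

OD_COLUMNS = ("time", "channel", "wavelength", "od")


def recording_basename(rec: RawRecording) -> str:
    return f"{rec.subject}_ses-{rec.session}"


def write_recording(rec: RawRecording, directory, include_truth_series: bool = True) -> Path:
    """Write one recording as CSV + JSON sidecar; returns the base path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / recording_basename(rec)

    n_channels, n_wavelengths, n = rec.od.shape
    frame = pd.DataFrame({
        "time": np.tile(rec.time, n_channels * n_wavelengths),
        "channel": np.repeat(np.arange(1, n_channels + 1), n_wavelengths * n),
        "wavelength": np.tile(np.repeat(np.asarray(rec.wavelengths, float), n), n_channels),
        "od": rec.od.reshape(-1),
    })
    frame.to_csv(f"{base}_od.csv", index=False, float_format="%.10g")

    gt = rec.ground_truth
    sidecar = {
        "subject": rec.subject,
        "session": rec.session,
        "fs": rec.fs,
        "wavelengths": list(rec.wavelengths),
        "dpf": rec.dpf,
        "source_detector_separation_mm": rec.source_detector_separation_mm,
        "conditions": list(rec.conditions),
        "design": {
            "onsets": {c: list(v) for c, v in rec.design.onsets.items()},
            "block_duration_s": rec.design.block_duration_s,
            "control_onsets": list(rec.design.control_onsets),
            "total_duration_s": rec.design.total_duration_s,
        },
        "ground_truth": {
            "amplitudes": gt.amplitudes.tolist(),
            "k_f": gt.k_f,
            "k_s": gt.k_s,
            "true_icc": gt.true_icc,
            "motion_log": [dataclasses.asdict(e) for e in gt.motion_log],
        },
    }
    Path(f"{base}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    if include_truth_series:
        truth = pd.DataFrame({
            "time": np.tile(rec.time, n_channels),
            "channel": np.repeat(np.arange(1, n_channels + 1), n),
            "functional": gt.functional.reshape(-1),
            "systemic": gt.systemic.reshape(-1),
        })
        truth.to_csv(f"{base}_truth.csv", index=False, float_format="%.10g")
    return base


def read_recording(base) -> RawRecording:
    """Read a recording written by :func:`write_recording`."""
    base = Path(base)
    od_path = Path(f"{base}_od.csv")
    sidecar_path = Path(f"{base}.json")
    if not od_path.exists() or not sidecar_path.exists():
        raise InputError(f"missing recording files for base path {base}")
    frame = pd.read_csv(od_path)
    missing = set(OD_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"{od_path}: missing required column(s) {sorted(missing)}")
    meta = json.loads(sidecar_path.read_text())

    wavelengths = tuple(float(w) for w in meta["wavelengths"])
    channels = np.sort(frame["channel"].unique())
    time = np.sort(frame["time"].unique())
    n_channels, n = len(channels), len(time)
    od = np.empty((n_channels, len(wavelengths), n))
    sub = frame.sort_values(["channel", "wavelength", "time"])
    try:
        od[:] = sub["od"].to_numpy().reshape(n_channels, len(wavelengths), n)
    except ValueError as exc:
        raise InputError(f"{od_path}: irregular channel/wavelength/time grid ({exc})")

    design = DesignSpec(
        onsets={c: tuple(v) for c, v in meta["design"]["onsets"].items()},
        block_duration_s=meta["design"]["block_duration_s"],
        control_onsets=tuple(meta["design"]["control_onsets"]),
        total_duration_s=meta["design"]["total_duration_s"],
    )
    gt_meta = meta["ground_truth"]
    truth_path = Path(f"{base}_truth.csv")
    functional = systemic = np.zeros((n_channels, 0))
    if truth_path.exists():
        truth = pd.read_csv(truth_path).sort_values(["channel", "time"])
        functional = truth["functional"].to_numpy().reshape(n_channels, n)
        systemic = truth["systemic"].to_numpy().reshape(n_channels, n)
    ground_truth = GroundTruth(
        amplitudes=np.asarray(gt_meta["amplitudes"], float),
        functional=functional,
        systemic=systemic,
        k_f=gt_meta["k_f"],
        k_s=gt_meta["k_s"],
        true_icc=gt_meta["true_icc"],
        motion_log=[MotionEvent(**e) for e in gt_meta["motion_log"]],
    )
    return RawRecording(
        subject=meta["subject"],
        session=meta["session"],
        time=time,
        od=od,
        design=design,
        fs=meta["fs"],
        wavelengths=wavelengths,
        dpf=meta["dpf"],
        source_detector_separation_mm=meta["source_detector_separation_mm"],
        conditions=tuple(meta["conditions"]),
        ground_truth=ground_truth,
    )


def write_haemo(haemo: HaemoSeries, path) -> Path:
    """Write a HaemoSeries as long CSV (time, channel, component, value)."""
    path = Path(path)
    components = {"hbo": haemo.hbo, "hbr": haemo.hbr}
    if haemo.functional is not None:
        components["functional"] = haemo.functional
        components["systemic"] = haemo.systemic
    n_channels, n = haemo.hbo.shape
    frames = []
    for name, data in components.items():
        frames.append(pd.DataFrame({
            "time": np.tile(haemo.time, n_channels),
            "channel": np.repeat(np.arange(1, n_channels + 1), n),
            "component": name,
            "value": data.reshape(-1),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
    return path


def read_haemo(path, fs: float) -> HaemoSeries:
    frame = pd.read_csv(path)
    required = {"time", "channel", "component", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise InputError(f"{path}: missing required column(s) {sorted(missing)}")
    time = np.sort(frame["time"].unique())
    channels = np.sort(frame["channel"].unique())
    n_channels, n = len(channels), len(time)

    def grab(name):
        sub = frame[frame["component"] == name]
        if sub.empty:
            return None
        return sub.sort_values(["channel", "time"])["value"].to_numpy().reshape(n_channels, n)

    hbo, hbr = grab("hbo"), grab("hbr")
    if hbo is None or hbr is None:
        raise InputError(f"{path}: hbo/hbr components are required")
    return HaemoSeries(time=time, fs=fs, hbo=hbo, hbr=hbr,
                       functional=grab("functional"), systemic=grab("systemic"))


# ---------------------------------------------------------------------------
# SNIRF container (HDF5) export/import


def write_snirf(rec: RawRecording, path) -> Path:
    """Minimal SNIRF export: dataTimeSeries/time/measurementList/probe.

    The design and scalar ground truth travel in metaDataTags as a JSON
    string so a SNIRF round trip is lossless for analysis purposes.
    """
    import h5py

    path = Path(path)
    n_channels, n_wavelengths, n = rec.od.shape
    data = rec.od.reshape(n_channels * n_wavelengths, n).T  # time x measurement
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        sidecar = {
            "subject": rec.subject,
            "session": rec.session,
            "conditions": list(rec.conditions),
            "dpf": rec.dpf,
            "source_detector_separation_mm": rec.source_detector_separation_mm,
            "design": {
                "onsets": {c: list(v) for c, v in rec.design.onsets.items()},
                "block_duration_s": rec.design.block_duration_s,
                "control_onsets": list(rec.design.control_onsets),
                "total_duration_s": rec.design.total_duration_s,
            },
            "ground_truth": {
                "amplitudes": rec.ground_truth.amplitudes.tolist(),
                "k_f": rec.ground_truth.k_f,
                "k_s": rec.ground_truth.k_s,
                "true_icc": rec.ground_truth.true_icc,
            },
        }
        meta.create_dataset("SubjectID", data=rec.subject)
        meta.create_dataset("nirsrelSidecar", data=json.dumps(sidecar, sort_keys=True))
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=rec.time)
        for i in range(n_channels * n_wavelengths):
            ch, w = divmod(i, n_wavelengths)
            ml = d1.create_group(f"measurementList{i + 1}")
            ml.create_dataset("sourceIndex", data=ch + 1)
            ml.create_dataset("detectorIndex", data=ch + 1)
            ml.create_dataset("wavelengthIndex", data=w + 1)
            ml.create_dataset("dataType", data=1)
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths, float))
    return path


def read_snirf(path) -> RawRecording:
    """Read a SNIRF file written by :func:`write_snirf`."""
    import h5py

    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        wavelengths = tuple(float(w) for w in nirs["probe/wavelengths"][()])
        time = np.asarray(nirs["data1/time"][()], float)
        data = np.asarray(nirs["data1/dataTimeSeries"][()], float)
        sidecar = json.loads(nirs["metaDataTags/nirsrelSidecar"][()])
    n = len(time)
    n_wavelengths = len(wavelengths)
    n_channels = data.shape[1] // n_wavelengths
    od = data.T.reshape(n_channels, n_wavelengths, n)
    fs = 1.0 / float(np.median(np.diff(time)))
    design = DesignSpec(
        onsets={c: tuple(v) for c, v in sidecar["design"]["onsets"].items()},
        block_duration_s=sidecar["design"]["block_duration_s"],
        control_onsets=tuple(sidecar["design"]["control_onsets"]),
        total_duration_s=sidecar["design"]["total_duration_s"],
    )
    gt = sidecar["ground_truth"]
    return RawRecording(
        subject=sidecar["subject"],
        session=sidecar["session"],
        time=time,
        od=od,
        design=design,
        fs=fs,
        wavelengths=wavelengths,
        dpf=sidecar["dpf"],
        source_detector_separation_mm=sidecar["source_detector_separation_mm"],
        conditions=tuple(sidecar["conditions"]),
        ground_truth=GroundTruth(
            amplitudes=np.asarray(gt["amplitudes"], float),
            functional=np.zeros((n_channels, 0)),
            systemic=np.zeros((n_channels, 0)),
            k_f=gt["k_f"],
            k_s=gt["k_s"],
            true_icc=gt["true_icc"],
        ),
    )
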