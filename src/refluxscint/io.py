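"""Readers and writers for on-disk study formats.

The fixture format for one patient study is a directory with a
``metadata.json`` file plus one little-endian uint32 binary per image
segment (``upright.u32le``, ``supine.u32le``, ``delayed.u32le``),
row-major, frames contiguous.  It round-trips bit-exactly.  DICOM
nuclear-medicine multi-frame export/import is supported through pydicom
for the dynamic segments.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .kinetics import KineticsParams
from .protocol import AcquisitionProtocol
from .render import DelayedImage, DynamicStudy
from .tac import ROISet, TimeActivityCurve


class ParseError(ValueError):
    pass


class ConsistencyError(ValueError):
    pass


@dataclass
class StudyBundle:
    """One patient's full imaging study plus provenance."""

    patient_id: str
    upright: DynamicStudy
    supine: DynamicStudy
    delayed: DelayedImage
    rois: ROISet
    provenance: dict

    def __post_init__(self) -> None:
        m = self.upright.frames.shape[1]
        if self.supine.frames.shape[1] != m:
            raise ConsistencyError("upright and supine matrix sizes differ")
        if self.rois.matrix != m:
            raise ConsistencyError("ROI matrix does not match the dynamic matrix")


def _write_counts(path: Path, array: np.ndarray) -> None:
    if array.min() < 0:
        raise ValueError("counts must be non-negative")
    path.write_bytes(array.astype("<u4").tobytes())


def _read_counts(path: Path, shape: tuple) -> np.ndarray:
    expected = int(np.prod(shape)) * 4
    raw = path.read_bytes()
    if len(raw) != expected:
        n_frame = int(np.prod(shape[1:])) * 4 if len(shape) == 3 else expected
        frame = len(raw) // max(n_frame, 1)
        raise ParseError(
            f"{path.name}: expected {expected} bytes, got {len(raw)} "
            f"(truncated at frame {frame})"
        )
    return np.frombuffer(raw, dtype="<u4").reshape(shape).astype(np.int64)


def write_study(bundle: StudyBundle, directory: "str | Path") -> Path:
    """Write a study bundle in the fixture format; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    protocol = bundle.upright.protocol
    meta = {
        "patient_id": bundle.patient_id,
        "protocol": dataclasses.asdict(protocol),
        "segments": {},
        "rois": {
            name: pix.tolist() for name, pix in bundle.rois.regions.items()
        },
        "roi_matrix": bundle.rois.matrix,
        "provenance": bundle.provenance,
    }
    for name, study in (("upright", bundle.upright), ("supine", bundle.supine)):
        meta["segments"][name] = {
            "shape": list(study.frames.shape),
            "frame_times": study.frame_times.tolist(),
            "posture": study.posture,
            "file": f"{name}.u32le",
        }
        _write_counts(directory / f"{name}.u32le", study.frames)
    meta["segments"]["delayed"] = {
        "shape": list(bundle.delayed.pixels.shape),
        "acquisition_time_minutes": bundle.delayed.acquisition_time_minutes,
        "file": "delayed.u32le",
    }
    _write_counts(directory / "delayed.u32le", bundle.delayed.pixels)
    (directory / "metadata.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_study(directory: "str | Path") -> StudyBundle:
    """Read a fixture-format study bundle."""
    directory = Path(directory)
    meta_path = directory / "metadata.json"
    if not meta_path.exists():
        raise ParseError(f"{meta_path}: missing metadata.json")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"{meta_path}: malformed JSON ({e})") from e
    protocol = AcquisitionProtocol(**meta["protocol"])
    studies = {}
    for name in ("upright", "supine"):
        seg = meta["segments"][name]
        frames = _read_counts(directory / seg["file"], tuple(seg["shape"]))
        studies[name] = DynamicStudy(
            posture=seg["posture"],
            frames=frames,
            frame_times=np.asarray(seg["frame_times"], dtype=float),
            protocol=protocol,
        )
    seg = meta["segments"]["delayed"]
    delayed = DelayedImage(
        pixels=_read_counts(directory / seg["file"], tuple(seg["shape"])),
        acquisition_time_minutes=seg["acquisition_time_minutes"],
        protocol=protocol,
    )
    rois = ROISet(
        regions={k: np.asarray(v, dtype=int) for k, v in meta["rois"].items()},
        matrix=meta["roi_matrix"],
    )
    return StudyBundle(
        patient_id=meta["patient_id"],
        upright=studies["upright"],
        supine=studies["supine"],
        delayed=delayed,
        rois=rois,
        provenance=meta.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# DICOM nuclear-medicine multi-frame export (optional path)
# ---------------------------------------------------------------------------

_NM_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.20"


def write_dicom(study: DynamicStudy, path: "str | Path", patient_id: str = "") -> Path:
    """Export one dynamic segment as a DICOM NM multi-frame file."""
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    if study.frames.max() >= 2**16:
        raise ValueError("frame counts exceed 16-bit DICOM pixel depth")
    path = Path(path)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _NM_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _NM_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "NM"
    ds.PatientID = patient_id
    ds.SeriesDescription = f"reflux study {study.posture} dynamic"
    n, rows, cols = study.frames.shape
    ds.NumberOfFrames = n
    ds.Rows = rows
    ds.Columns = cols
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.ActualFrameDuration = int(study.frame_seconds * 1000)
    ds.PixelData = study.frames.astype("<u2").tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def read_dicom(path: "str | Path", protocol: AcquisitionProtocol | None = None) -> DynamicStudy:
    """Re-import a DICOM NM multi-frame dynamic segment."""
    import pydicom

    ds = pydicom.dcmread(path)
    frames = ds.pixel_array.astype(np.int64)
    if frames.ndim == 2:
        frames = frames[None]
    desc = getattr(ds, "SeriesDescription", "")
    posture = "supine" if "supine" in desc else "upright"
    dt = float(ds.ActualFrameDuration) / 1000.0
    return DynamicStudy(
        posture=posture,
        frames=frames,
        frame_times=np.arange(len(frames)) * dt,
        protocol=protocol or AcquisitionProtocol(),
    )


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def cohort_to_frame(cohort) -> pd.DataFrame:
    """Ground-truth table: one row per patient (record + kinetics)."""
    rows = []
    for record, kinetics in cohort:
        row = dataclasses.asdict(record)
        row.update({f"k_{k}": v for k, v in dataclasses.asdict(kinetics).items()})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(df: pd.DataFrame):
    """Inverse of :func:`cohort_to_frame`."""
    cohort = []
    record_fields = [f.name for f in dataclasses.fields(PatientRecord)]
    kin_fields = [f.name for f in dataclasses.fields(KineticsParams)]
    for _, row in df.iterrows():
        record = PatientRecord(**{k: row[k] for k in record_fields})
        kinetics = KineticsParams(**{k: row[f"k_{k}"] for k in kin_fields})
        cohort.append((record, kinetics))
    return cohort


def tacs_to_frame(tacs: "list[TimeActivityCurve]") -> pd.DataFrame:
    rows = []
    for tac in tacs:
        for t, v in zip(tac.times, tac.values):
            rows.append(
                {"roi": tac.roi_name, "posture": tac.posture, "t_seconds": t, "value": v}
            )
    return pd.DataFrame(rows)
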