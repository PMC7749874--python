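"""Voxel-volume I/O: flat raster (.raw + JSON header) and DICOM CT series.

The flat format keeps tests and pipelines dependency-light: a little-endian
binary block per volume plus a JSON header recording shape, voxel size,
dtype and HU scaling, with the organ-label map and its name table stored
alongside.  DICOM in/out covers the clinical exchange path (CT Image
Storage slices, HU via RescaleSlope/Intercept).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .errors import InvalidInputError
from .phantoms import VoxelPhantom


def save_raw(phantom: VoxelPhantom, basepath) -> Path:
    """Write ``<base>.raw`` (int16 HU), ``<base>.labels.raw`` and ``<base>.json``."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    hu = np.round(phantom.ct_numbers).astype("<i2")
    hu.tofile(base.with_suffix(".raw"))
    phantom.organ_labels.astype("<u2").tofile(base.with_suffix(".labels.raw"))
    header = {
        "shape": list(phantom.shape),
        "voxel_size_mm": phantom.voxel_size_mm,
        "dtype": "int16-le",
        "hu_scaling": {"slope": 1.0, "intercept": 0.0},
        "organ_names": {str(k): v for k, v in phantom.organ_names.items()},
        "name": phantom.name,
    }
    base.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return base.with_suffix(".json")


def load_raw(basepath) -> VoxelPhantom:
    base = Path(basepath)
    header = json.loads(base.with_suffix(".json").read_text())
    shape = tuple(header["shape"])
    hu = np.fromfile(base.with_suffix(".raw"), dtype="<i2").reshape(shape).astype(np.float32)
    scale = header.get("hu_scaling", {"slope": 1.0, "intercept": 0.0})
    hu = hu * scale["slope"] + scale["intercept"]
    labels_path = base.with_suffix(".labels.raw")
    labels = None
    if labels_path.exists():
        labels = np.fromfile(labels_path, dtype="<u2").reshape(shape)
    return VoxelPhantom(
        hu,
        header["voxel_size_mm"],
        organ_labels=labels,
        organ_names={int(k): v for k, v in header.get("organ_names", {}).items()},
        name=header.get("name", base.stem),
    )


def save_dicom_series(phantom: VoxelPhantom, directory) -> Path:
    """Write one CT Image Storage file per axial (z) slice."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    nx, ny, nz = phantom.shape
    dz = phantom.voxel_size_mm
    x0 = phantom.centers_mm(0)[0]
    y0 = phantom.centers_mm(1)[0]
    for k in range(nz):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientName = phantom.name
        ds.PatientID = phantom.name
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [x0, y0, float(phantom.centers_mm(2)[k])]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dz, dz]
        ds.SliceThickness = dz
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        # pixel rows are y, columns are x
        pixels = np.round(phantom.ct_numbers[:, :, k].T + 1024.0)
        ds.PixelData = np.clip(pixels, 0, 65535).astype("<u2").tobytes()
        pydicom.dcmwrite(directory / f"ct_{k:04d}.dcm", ds, enforce_file_format=True)
    return directory


def load_dicom_series(directory, voxel_size_mm: float | None = None) -> VoxelPhantom:
    """Read a directory of CT slices back into a phantom (no labels)."""
    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise InvalidInputError(f"no DICOM files in {directory}")
    slices = [pydicom.dcmread(f) for f in files]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    first = slices[0]
    hu = np.stack(
        [
            s.pixel_array.astype(np.float32) * float(s.RescaleSlope) + float(s.RescaleIntercept)
            for s in slices
        ],
        axis=-1,
    ).transpose(1, 0, 2)  # (rows=y, cols=x, z) -> (x, y, z)
    size = voxel_size_mm if voxel_size_mm is not None else float(first.PixelSpacing[0])
    return VoxelPhantom(hu, size, name=str(getattr(first, "PatientID", "dicom")))
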