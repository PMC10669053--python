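"""Volumes, label maps, and NIfTI / DICOM-series I/O.

Conventions fixed package-wide:

* array axis order is ``(slice, row, column)``, 0-based;
* ``spacing`` is ``(dz, dy, dx)`` in millimetres, matching the axis
  order, so all surface distances come out in mm;
* CT intensities are Hounsfield units (``intensity_kind="HU"``) until
  :func:`cardioseg.preprocess.normalize_hu` maps them to ``[0, 1]``
  (``intensity_kind="normalized"``).

NIfTI is the working format (read and write).  DICOM series are
read-only: slices are sorted by position along the scan axis and
rescaled to HU with the stored slope/intercept.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LabelMap",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "read_dicom_series",
]

MAX_LABEL = 10


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing in mm.

    ``data`` has axis order (slice, row, column); ``spacing`` is
    (dz, dy, dx) mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    intensity_kind: str = "HU"  # "HU" | "normalized"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.intensity_kind not in ("HU", "normalized"):
            raise ValueError(f"unknown intensity_kind {self.intensity_kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, intensity_kind: str | None = None) -> "Volume":
        return replace(
            self, data=data, intensity_kind=intensity_kind or self.intensity_kind
        )


@dataclass
class LabelMap:
    """A 3D integer label map paired with a Volume (same grid)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label map must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label map must be integer, got dtype {self.data.dtype}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.data.size:
            lo, hi = int(self.data.min()), int(self.data.max())
            if lo < 0 or hi > MAX_LABEL:
                raise ValueError(
                    f"label values must lie in 0..{MAX_LABEL}, found range [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _spacing_from_header(img) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(
            f"NIfTI header has invalid voxel sizes {zooms}; "
            "set pixdim (e.g. with nibabel) before loading"
        )
    return tuple(float(z) for z in zooms)


def write_volume(vol: Volume, path: str | os.PathLike) -> None:
    """Write a Volume as NIfTI; spacing goes into the header zooms."""
    img = nib.Nifti1Image(
        np.asarray(vol.data, dtype=np.float32), _affine_from_spacing(vol.spacing)
    )
    img.header.set_zooms(vol.spacing)
    nib.save(img, os.fspath(path))


def _is_dicom_dir(path: str) -> bool:
    return os.path.isdir(path)


def read_volume(path: str | os.PathLike, intensity_kind: str = "HU") -> Volume:
    """Read a NIfTI file or a directory of DICOM slices as a Volume."""
    path = os.fspath(path)
    if _is_dicom_dir(path):
        return read_dicom_series(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    return Volume(data, _spacing_from_header(img), intensity_kind=intensity_kind)


def write_labelmap(labels: LabelMap, path: str | os.PathLike) -> None:
    """Write a LabelMap as NIfTI (int16, lossless for codes 0..10)."""
    img = nib.Nifti1Image(
        np.asarray(labels.data, dtype=np.int16), _affine_from_spacing(labels.spacing)
    )
    img.header.set_zooms(labels.spacing)
    nib.save(img, os.fspath(path))


def read_labelmap(path: str | os.PathLike) -> LabelMap:
    img = nib.load(os.fspath(path))
    raw = np.asarray(img.dataobj)
    data = np.rint(raw).astype(np.int16)
    if not np.allclose(raw, data, atol=1e-6):
        raise ValueError(f"{path}: voxel values are not integers; not a label map")
    return LabelMap(data, _spacing_from_header(img))


def read_dicom_series(directory: str | os.PathLike) -> Volume:
    """Stack a directory of single-frame DICOM slices into a Volume.

    Slices are sorted by position along the normal axis
    (ImagePositionPatient z, falling back to InstanceNumber) and
    rescaled to HU via RescaleSlope/RescaleIntercept.
    """
    import pydicom

    directory = os.fspath(directory)
    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    if not files:
        raise ValueError(f"{directory}: no DICOM files found")
    slices = [pydicom.dcmread(f) for f in files]

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) > 1:
        raise ValueError(
            f"{directory}: directory mixes {len(uids)} DICOM series; "
            "split it into one directory per series"
        )

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)

    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    data = np.stack(planes, axis=0)

    first = slices[0]
    ps = getattr(first, "PixelSpacing", None)
    if ps is None:
        raise ValueError(
            f"{directory}: DICOM slices lack PixelSpacing; "
            "cannot establish in-plane geometry (add (0028,0030) or "
            "convert to NIfTI with explicit zooms)"
        )
    dy, dx = float(ps[0]), float(ps[1])
    if len(slices) > 1 and all(
        hasattr(s, "ImagePositionPatient") for s in slices[:2]
    ):
        dz = abs(
            float(slices[1].ImagePositionPatient[2])
            - float(slices[0].ImagePositionPatient[2])
        )
        if dz <= 0:
            dz = float(getattr(first, "SliceThickness", 0) or 0)
    else:
        dz = float(getattr(first, "SliceThickness", 0) or 0)
    if dz <= 0:
        raise ValueError(
            f"{directory}: cannot determine slice spacing; "
            "set SliceThickness (0018,0050) or ImagePositionPatient"
        )
    return Volume(data, (dz, dy, dx), intensity_kind="HU")
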