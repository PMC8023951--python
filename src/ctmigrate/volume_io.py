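"""CT volume input/output and the coordinate conventions of the package.

A :class:`CTVolume` is a 3-D grid of Hounsfield units together with the
affine index->world map ``world = origin + direction @ (spacing * index)``.
The world frame is DICOM LPS in millimetres throughout the package; NIfTI
files (RAS by convention) are converted to LPS on read by the underlying
SimpleITK readers, so every transform and every reported migration value
lives in one frame — the CT DICOM coordinate system.

Conventions:

* voxel arrays are indexed ``(i, j, k)`` with ``i`` along the world x-ish
  axis (the first column of ``direction``);
* ``origin`` is the world position of the *center* of voxel ``(0, 0, 0)``;
* supported formats: NIfTI (.nii/.nii.gz) and MetaImage (.mha/.mhd) read
  and write, DICOM series directories read-only.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import AmbiguityError, FormatError
from .transform import RigidTransform

_EXTENSIONS = {
    "nifti": (".nii", ".nii.gz"),
    "metaimage": (".mha", ".mhd"),
}


@dataclass
class CTVolume:
    """3-D Hounsfield-unit grid with a rigid index->world map."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        err = np.abs(self.direction.T @ self.direction - np.eye(3)).max()
        if err > 1e-6 or np.linalg.det(self.direction) < 0:
            raise FormatError(
                "direction must be orthonormal with determinant +1 "
                f"(|D'D-I| = {err:.2e}, det = {np.linalg.det(self.direction):.4f})"
            )

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel, mm^3."""
        return float(np.prod(self.spacing))

    # ------------------------------------------------------------------ #
    # geometry
    # ------------------------------------------------------------------ #
    def index_to_world(self, index) -> np.ndarray:
        """Map (continuous) voxel indices (..., 3) to world mm."""
        idx = np.asarray(index, dtype=float)
        return (idx * self.spacing) @ self.direction.T + self.origin

    def world_to_index(self, points) -> np.ndarray:
        """Map world points (..., 3) to continuous voxel indices."""
        p = np.asarray(points, dtype=float) - self.origin
        return (p @ self.direction) / self.spacing

    def world_bounds(self) -> np.ndarray:
        """(2, 3) min/max world coordinates of the voxel-center grid."""
        n = np.array(self.shape, dtype=float) - 1.0
        corners = np.array(
            [[i, j, k] for i in (0, n[0]) for j in (0, n[1]) for k in (0, n[2])]
        )
        w = self.index_to_world(corners)
        return np.vstack([w.min(axis=0), w.max(axis=0)])

    # ------------------------------------------------------------------ #
    # SimpleITK bridge (array axis order is reversed: sitk uses z,y,x)
    # ------------------------------------------------------------------ #
    def to_sitk(self, dtype=None) -> sitk.Image:
        arr = self.voxels if dtype is None else self.voxels.astype(dtype)
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.ravel()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, meta: dict | None = None) -> "CTVolume":
        arr = sitk.GetArrayFromImage(img).T
        return cls(
            voxels=arr,
            spacing=np.array(img.GetSpacing()),
            origin=np.array(img.GetOrigin()),
            direction=np.array(img.GetDirection()).reshape(3, 3),
            meta=dict(meta or {}),
        )


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    for fmt, exts in _EXTENSIONS.items():
        if any(name.endswith(e) for e in exts):
            return fmt
    raise ValueError(
        f"cannot infer volume format from {path.name!r}; "
        "expected .nii/.nii.gz/.mha/.mhd"
    )


def read_volume(path, format: str | None = None) -> CTVolume:
    """Read a CT volume from NIfTI, MetaImage, or a DICOM series directory.

    DICOM rescale slope/intercept is applied so voxel values are Hounsfield
    units.  A directory containing more than one CT series is rejected with
    an :class:`AmbiguityError` rather than guessed at.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if format == "dicom_dir" or (format is None and path.is_dir()):
        return _read_dicom_dir(path)
    if format is None:
        format = _infer_format(path)
    if format not in _EXTENSIONS:
        raise ValueError(f"unsupported read format {format!r}")
    try:
        img = sitk.ReadImage(os.fspath(path))
    except RuntimeError as exc:  # pragma: no cover - ITK message passthrough
        raise FormatError(f"could not read {path}: {exc}") from exc
    vol = CTVolume.from_sitk(img, meta={"source": str(path), "format": format})
    return vol


def _read_dicom_dir(path: Path) -> CTVolume:
    reader = sitk.ImageSeriesReader()
    series = reader.GetGDCMSeriesIDs(os.fspath(path))
    if len(series) == 0:
        raise FormatError(f"no DICOM series found in {path}")
    if len(series) > 1:
        raise AmbiguityError(
            f"{path} contains {len(series)} DICOM series; expected exactly one"
        )
    files = reader.GetGDCMSeriesFileNames(os.fspath(path), series[0])
    reader.SetFileNames(files)
    img = reader.Execute()
    # GDCM applies RescaleSlope/Intercept, so values are already HU
    return CTVolume.from_sitk(
        img, meta={"source": str(path), "format": "dicom_dir", "series": series[0]}
    )


def write_volume(volume: CTVolume, path, format: str | None = None) -> None:
    """Write a volume as NIfTI or MetaImage (DICOM write is unsupported:
    results of this package are measurements, not images)."""
    path = Path(path)
    if format is None:
        format = _infer_format(path)
    if format not in _EXTENSIONS:
        raise ValueError(f"unsupported write format {format!r}")
    if not any(path.name.lower().endswith(e) for e in _EXTENSIONS[format]):
        raise ValueError(
            f"extension of {path.name!r} does not match format {format!r}"
        )
    sitk.WriteImage(volume.to_sitk(), os.fspath(path))


@dataclass
class GroundTruth:
    """Exact phantom truth accompanying a synthetic examination pair.

    ``bead_positions_*`` are world coordinates (mm) in the exam-1 frame;
    ``implant_pose`` is the true motion of the implant relative to its
    exam-1 placement *in the exam-1 pelvis frame* (the quantity the
    measurement pipeline estimates); ``repositioning`` is the whole-body
    motion applied between the examinations.
    """

    bead_positions_bone: np.ndarray
    bead_positions_implant: np.ndarray
    implant_pose: RigidTransform
    repositioning: RigidTransform

    def __post_init__(self):
        self.bead_positions_bone = np.asarray(
            self.bead_positions_bone, dtype=float
        ).reshape(-1, 3)
        self.bead_positions_implant = np.asarray(
            self.bead_positions_implant, dtype=float
        ).reshape(-1, 3)

    def to_dict(self) -> dict:
        return {
            "bead_positions_bone": self.bead_positions_bone.tolist(),
            "bead_positions_implant": self.bead_positions_implant.tolist(),
            "implant_pose": self.implant_pose.to_dict(),
            "repositioning": self.repositioning.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            bead_positions_bone=np.array(d["bead_positions_bone"]).reshape(-1, 3),
            bead_positions_implant=np.array(d["bead_positions_implant"]).reshape(-1, 3),
            implant_pose=RigidTransform.from_dict(d["implant_pose"]),
            repositioning=RigidTransform.from_dict(d["repositioning"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))
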