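"""Implant migration: cup motion relative to the pelvis in 6 DOF.

The method registers the same pair of examinations twice — once on the
reference body (pelvic bone, by surface anatomy or by beads) and once on
the implant body (cup surface or implant beads) — and reports the relative
transform ``t_reference^-1 ∘ t_implant``, the implant's motion expressed in
the exam-1 pelvis frame.  Translations are reported as the displacement of
the implant's exam-1 centroid (a raw matrix translation would depend on
where the scanner put the world origin); rotations as intrinsic x->y->z
Euler angles in degrees, DICOM LPS axes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np

from .errors import QualityError
from .registration import (
    RegistrationQuality,
    RegistrationSettings,
    common_region_mask,
    match_beads,
    register_masked,
    register_points,
    verify_registration,
)
from .segmentation import detect_beads, largest_components, select_near, threshold_mask
from .transform import RigidTransform
from .volume_io import CTVolume

EULER_CONVENTION = "intrinsic-xyz-deg-LPS"

_GIMBAL_TOL_DEG = 1e-6


@dataclass
class MigrationResult:
    """6-DOF cup-vs-pelvis motion plus total translation.

    ``total_translation`` (TT) is the Euclidean norm of (tx, ty, tz); all
    rotations lie in (-180, 180].  ``quality`` carries the verification
    records of both registrations.
    """

    tx: float
    ty: float
    tz: float
    rx: float
    ry: float
    rz: float
    total_translation: float
    rotation_center: tuple
    euler_convention: str = EULER_CONVENTION
    gimbal_lock: bool = False
    quality: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def translations(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])

    @property
    def rotations(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MigrationResult":
        d = dict(d)
        d["rotation_center"] = tuple(d.get("rotation_center", (0.0, 0.0, 0.0)))
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "MigrationResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def relative_motion(t_reference: RigidTransform,
                    t_implant: RigidTransform) -> RigidTransform:
    """Implant motion in the exam-1 pelvis frame: ``t_reference^-1 ∘
    t_implant``.  Identity when implant and pelvis moved identically
    (pure patient repositioning)."""
    return t_reference.inverse().compose(t_implant)


def _wrap_deg(a: float) -> float:
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def decompose(motion: RigidTransform, center=(0.0, 0.0, 0.0),
              convention: str = EULER_CONVENTION,
              quality: dict | None = None,
              config: dict | None = None) -> MigrationResult:
    """Express a rigid motion as 6 DOF about a reporting center.

    Translation is the displacement of ``center`` under the motion,
    ``t + (R - I) @ center``.  Euler angles follow R = Rx @ Ry @ Rz
    (intrinsic x->y->z).  At gimbal lock (|ry| within 1e-6° of 90°) the
    x/z split is undefined; the documented tie rule sets rz = 0 and the
    result is flagged.
    """
    if convention != EULER_CONVENTION:
        raise ValueError(f"unsupported Euler convention {convention!r}")
    c = np.asarray(center, dtype=float)
    R = motion.rotation
    disp = motion.translation + (R - np.eye(3)) @ c

    sy = float(np.clip(R[0, 2], -1.0, 1.0))
    ry = np.rad2deg(np.arcsin(sy))
    gimbal = abs(90.0 - abs(ry)) < _GIMBAL_TOL_DEG
    if not gimbal:
        rx = np.rad2deg(np.arctan2(-R[1, 2], R[2, 2]))
        rz = np.rad2deg(np.arctan2(-R[0, 1], R[0, 0]))
    else:
        # R = Rx @ Ry(±90): R[1,0] = sin(rx)*sy, R[1,1] = cos(rx)
        rz = 0.0
        rx = np.rad2deg(np.arctan2(R[1, 0] / sy, R[1, 1]))

    t = [float(v) for v in disp]
    return MigrationResult(
        tx=t[0], ty=t[1], tz=t[2],
        rx=_wrap_deg(float(rx)), ry=_wrap_deg(float(ry)), rz=_wrap_deg(float(rz)),
        total_translation=float(np.linalg.norm(disp)),
        rotation_center=tuple(float(v) for v in c),
        euler_convention=convention,
        gimbal_lock=bool(gimbal),
        quality=dict(quality or {}),
        config=dict(config or {}),
    )


@dataclass(frozen=True)
class MeasureConfig:
    """Resolved configuration of one pair measurement.

    HU thresholds default to the package's cohort defaults (bone >= 250,
    metal >= 2000, bead detection >= 1000 — beads blur down well below the
    solid-metal plateau at clinical voxel sizes); all of them are meant to
    be set once per cohort, as the clinical workflow prescribes.
    """

    reference_mode: str = "surface"   # "surface" | "beads"
    implant_mode: str = "surface"     # "surface" | "beads"
    bone_lower_hu: float = 250.0
    metal_lower_hu: float = 2000.0
    bead_detect_hu: float = 1000.0
    implant_bead_detect_hu: float = 500.0
    bead_min_volume: float = 0.1
    bead_max_volume: float = 4.0
    bead_merge_distance: float = 1.0
    bead_match_coarse_mm: float = 8.0
    bead_match_mm: float = 2.0
    metal_dilation_vox: int = 3
    min_component_voxels: int = 50
    common_region_residual_hu: float = 150.0
    common_region_min_fraction: float = 0.5
    point_tolerance_mm: float = 0.5
    implant_verify_tol_hu: float = 300.0  # metal edges: ~5000 HU/mm gradients
    strict: bool = False
    registration: RegistrationSettings = field(default_factory=RegistrationSettings)

    def to_dict(self) -> dict:
        return asdict(self)


def _bone_reference_mask(volume: CTVolume, cfg: MeasureConfig):
    """Bone body for the reference registration: bone-window voxels with
    everything bright (implant, beads, their partial-volume rims) dilated
    away so nothing that moves with the implant leaks into the reference."""
    bone = threshold_mask(volume, cfg.bone_lower_hu, cfg.metal_lower_hu)
    bright = threshold_mask(volume, cfg.bead_detect_hu)
    bone.mask &= ~bright.dilated(cfg.metal_dilation_vox).mask
    return largest_components(bone, k=1, min_voxels=cfg.min_component_voxels)


def _implant_mask(volume: CTVolume, cfg: MeasureConfig):
    metal = threshold_mask(volume, cfg.metal_lower_hu)
    return largest_components(metal, k=1, min_voxels=cfg.min_component_voxels)


def _cup_bounding_sphere(mask) -> tuple:
    idx = np.argwhere(mask.mask)
    w = mask.index_to_world(idx)
    c = w.mean(axis=0)
    r = float(np.linalg.norm(w - c, axis=1).max())
    return c, r


def _bead_transform(volume_a, volume_b, cfg, implant: bool):
    """Bead-based registration of either body: detect beads in both exams,
    split implant vs bone beads by the cup's bounding sphere, coarse-match,
    solve, re-match tightly, re-solve.

    Implant beads sit in low-HU cement/liner space and blur down far more
    than beads embedded in bone, so the implant pass uses its own lower
    threshold; at that threshold the bone body itself is suprathreshold but
    rejects itself through the bead size window.
    """
    threshold = cfg.implant_bead_detect_hu if implant else cfg.bead_detect_hu
    beads = []
    for vol in (volume_a, volume_b):
        imp_mask = _implant_mask(vol, cfg)
        excl = imp_mask.dilated(cfg.metal_dilation_vox)
        found = detect_beads(
            vol, threshold, cfg.bead_min_volume, cfg.bead_max_volume,
            exclusion_mask=excl, merge_distance=cfg.bead_merge_distance,
        )
        center, radius = _cup_bounding_sphere(imp_mask)
        beads.append(select_near(found, center, 1.1 * radius, inside=implant))
    a, b = beads
    init = RigidTransform(np.eye(3),
                          b.centroids.mean(axis=0) - a.centroids.mean(axis=0))
    pairs = match_beads(a, b, init, cfg.bead_match_coarse_mm)
    T0, _ = register_points(a, b, pairs, tolerance=cfg.point_tolerance_mm)
    pairs = match_beads(a, b, T0, cfg.bead_match_mm)
    return register_points(a, b, pairs, tolerance=cfg.point_tolerance_mm)


def measure_pair(exam_a: CTVolume, exam_b: CTVolume,
                 config: MeasureConfig | None = None) -> MigrationResult:
    """Full pipeline on one examination pair.

    Segmentation -> reference registration (surface mode runs one
    common-region refinement pass; bead mode matches and superimposes
    bone beads) -> implant registration -> relative motion -> 6-DOF
    decomposition about the implant's exam-1 centroid.  In strict mode a
    red verification aborts with a :class:`QualityError` instead of
    returning a result.
    """
    cfg = config or MeasureConfig()
    quality: dict = {}

    implant_mask_a = _implant_mask(exam_a, cfg)
    center = implant_mask_a.world_centroid()

    # --- reference body -------------------------------------------------
    if cfg.reference_mode == "surface":
        ref_a = _bone_reference_mask(exam_a, cfg)
        ref_b = _bone_reference_mask(exam_b, cfg)
        init = RigidTransform(np.eye(3),
                              ref_b.world_centroid() - ref_a.world_centroid())
        # first pass runs coarse: it only has to feed common-region masking
        coarse = dataclasses.replace(cfg.registration, strides=(4, 2),
                                     smoothing_sigmas=(2.0, 1.0),
                                     max_points=4000)
        t0, _ = register_masked(exam_a, exam_b, ref_a, init, coarse)
        common = common_region_mask(
            exam_a, exam_b, t0, ref_a,
            cfg.common_region_residual_hu, cfg.common_region_min_fraction,
        )
        t_ref, q_ref = register_masked(exam_a, exam_b, common, t0,
                                       cfg.registration)
    elif cfg.reference_mode == "beads":
        t_ref, q_ref = _bead_transform(exam_a, exam_b, cfg, implant=False)
    else:
        raise ValueError(f"unknown reference mode {cfg.reference_mode!r}")
    quality["reference"] = q_ref.to_dict()

    # --- implant body ---------------------------------------------------
    if cfg.implant_mode == "surface":
        imp_settings = dataclasses.replace(
            cfg.registration, verify_tol_hu=cfg.implant_verify_tol_hu)
        t_imp, q_imp = register_masked(exam_a, exam_b, implant_mask_a,
                                       t_ref, imp_settings)
    elif cfg.implant_mode == "beads":
        t_imp, q_imp = _bead_transform(exam_a, exam_b, cfg, implant=True)
    else:
        raise ValueError(f"unknown implant mode {cfg.implant_mode!r}")
    quality["implant"] = q_imp.to_dict()

    if cfg.strict:
        for name, q in (("reference", q_ref), ("implant", q_imp)):
            if q.status != "green":
                raise QualityError(
                    f"{name} registration verified red "
                    f"(fraction within tolerance {q.fraction_within_tol:.3f})"
                )

    motion = relative_motion(t_ref, t_imp)
    return decompose(motion, center=center, quality=quality,
                     config=cfg.to_dict())
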