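"""Rigid-body definition by HU thresholding and sub-voxel bead detection.

The measurement method defines two rigid bodies per examination — the
pelvic bone and the cup — by manual HU thresholds held constant within a
cohort.  This module provides the threshold masking, connected-component
cleanup, and tantalum-bead detection those definitions need.  Bead
centroids are computed to sub-voxel accuracy by weighting each voxel with
its HU excess above the detection threshold, which discounts
partial-volume voxels at the bead boundary without modeling the scanner
point-spread function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .errors import AmbiguityError, EmptyResultError
from .volume_io import CTVolume

_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)  # 26-neighbour


@dataclass
class BinaryMask:
    """Boolean voxel mask sharing the grid geometry of a parent volume."""

    mask: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)

    @classmethod
    def like(cls, volume: CTVolume, mask: np.ndarray, **meta) -> "BinaryMask":
        if mask.shape != volume.shape:
            raise ValueError("mask shape does not match parent volume")
        return cls(mask, volume.spacing, volume.origin, volume.direction,
                   meta={k: str(v) for k, v in meta.items()})

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def index_to_world(self, index) -> np.ndarray:
        idx = np.asarray(index, dtype=float)
        return (idx * self.spacing) @ self.direction.T + self.origin

    def world_centroid(self) -> np.ndarray:
        idx = np.argwhere(self.mask)
        if idx.size == 0:
            raise EmptyResultError("cannot take the centroid of an empty mask")
        return self.index_to_world(idx.mean(axis=0))

    def to_volume(self) -> CTVolume:
        """8-bit label volume (for saving masks as NIfTI/MetaImage)."""
        return CTVolume(self.mask.astype(np.uint8), self.spacing,
                        self.origin, self.direction, dict(self.meta))

    def dilated(self, iterations: int = 1) -> "BinaryMask":
        m = ndimage.binary_dilation(self.mask, structure=_CONNECTIVITY,
                                    iterations=iterations)
        return BinaryMask(m, self.spacing, self.origin, self.direction,
                          dict(self.meta))


@dataclass
class BeadSet:
    """Sub-voxel world-coordinate bead centroids with per-bead audit data,
    sorted by descending peak HU then lexicographic position."""

    centroids: np.ndarray
    voxel_counts: np.ndarray
    peak_hu: np.ndarray
    threshold: float

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 3)
        self.voxel_counts = np.asarray(self.voxel_counts, dtype=int).reshape(-1)
        self.peak_hu = np.asarray(self.peak_hu, dtype=float).reshape(-1)

    def __len__(self) -> int:
        return self.centroids.shape[0]

    def subset(self, keep) -> "BeadSet":
        keep = np.asarray(keep)
        return BeadSet(self.centroids[keep], self.voxel_counts[keep],
                       self.peak_hu[keep], self.threshold)

    def to_json(self, path) -> None:
        rows = [
            {"id": i, "x": float(c[0]), "y": float(c[1]), "z": float(c[2]),
             "voxels": int(n), "peak_hu": float(p)}
            for i, (c, n, p) in enumerate(
                zip(self.centroids, self.voxel_counts, self.peak_hu))
        ]
        Path(path).write_text(
            json.dumps({"threshold": self.threshold, "beads": rows}, indent=1))


def threshold_mask(volume: CTVolume, lower: float,
                   upper: float = np.inf) -> BinaryMask:
    """Mask of voxels with ``lower <= HU <= upper``.

    The thresholds are recorded in the mask metadata for audit, mirroring
    the per-cohort constancy of the manually chosen clinical thresholds.
    An empty mask is a legal result.
    """
    if not lower < upper:
        raise ValueError(f"lower threshold {lower} must be < upper {upper}")
    m = (volume.voxels >= lower) & (volume.voxels <= upper)
    return BinaryMask.like(volume, m, lower=lower, upper=upper)


def largest_components(mask: BinaryMask, k: int = 1,
                       min_voxels: int = 1) -> BinaryMask:
    """Union of the ``k`` largest 26-connected components of at least
    ``min_voxels`` voxels.

    Equal-sized components are ordered by the lowest linear (C-order)
    index at which each component first occurs — a deterministic,
    documented tie-break.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels, n = ndimage.label(mask.mask, structure=_CONNECTIVITY)
    if n == 0:
        raise EmptyResultError("mask has no connected component")
    flat = labels.ravel()
    counts = np.bincount(flat)[1:]  # component sizes, label 1..n
    first = np.full(n, flat.size, dtype=np.int64)
    uniq, uniq_first = np.unique(flat, return_index=True)
    for lab, fi in zip(uniq, uniq_first):
        if lab > 0:
            first[lab - 1] = fi
    order = sorted(range(n), key=lambda i: (-counts[i], first[i]))
    chosen = [i + 1 for i in order if counts[i] >= min_voxels][:k]
    if not chosen:
        raise EmptyResultError(
            f"no connected component has >= {min_voxels} voxels"
        )
    out = np.isin(labels, chosen)
    return BinaryMask(out, mask.spacing, mask.origin, mask.direction,
                      dict(mask.meta))


def detect_beads(volume: CTVolume, threshold: float,
                 min_volume: float = 0.1, max_volume: float = 2.0,
                 exclusion_mask: BinaryMask | None = None,
                 merge_distance: float = 1.0) -> BeadSet:
    """Detect tantalum beads as bead-sized suprathreshold components.

    Components of physical volume within ``[min_volume, max_volume]`` mm³
    (the bead size window that separates ~1 mm beads from the implant body)
    become beads.  The centroid of each bead is the intensity-weighted mean
    of its voxel positions with weights ``HU - threshold``, mapped to world
    millimetres.  Two accepted beads closer than ``merge_distance`` raise
    an :class:`AmbiguityError` rather than being silently merged.
    """
    if not min_volume < max_volume:
        raise ValueError("min_volume must be < max_volume")
    supra = volume.voxels >= threshold
    if exclusion_mask is not None:
        supra &= ~exclusion_mask.mask
    labels, n = ndimage.label(supra, structure=_CONNECTIVITY)
    if n == 0:
        return BeadSet(np.zeros((0, 3)), np.zeros(0, int), np.zeros(0), threshold)

    vvol = volume.voxel_volume
    counts = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(
        (counts * vvol >= min_volume) & (counts * vvol <= max_volume)) + 1
    objects = ndimage.find_objects(labels)
    cents, nvox, peaks = [], [], []
    for lab in keep:
        sl = tuple(
            slice(max(s.start - 2, 0), min(s.stop + 2, n))
            for s, n in zip(objects[lab - 1], volume.shape)
        )
        comp = labels[sl] == lab
        hu = volume.voxels[sl].astype(float)
        # the bead's partial-volume shoulder extends below the detection
        # threshold: estimate the local background from a one-voxel shell
        # around the component and weight every voxel by its HU excess
        # above that background, which makes the centroid the center of
        # mass of the bead rather than of its suprathreshold core
        grown = ndimage.binary_dilation(comp, structure=_CONNECTIVITY)
        free = labels[sl] == 0
        if exclusion_mask is not None:
            free &= ~exclusion_mask.mask[sl]
        shell = grown & ~comp & free
        bg = float(np.median(hu[shell])) if shell.any() else threshold
        region = comp | (grown & free)
        w = np.clip(hu - bg, 0.0, None) * region
        total = w.sum()
        if total <= 0:  # pathological flat region; fall back to core
            w = (hu - threshold).clip(0.0, None) * comp
            total = w.sum()
        offsets = np.array([s.start for s in sl], dtype=float)
        grids = np.indices(comp.shape, dtype=float)
        cidx = np.array([(g * w).sum() for g in grids]) / total + offsets
        cents.append(volume.index_to_world(cidx))
        nvox.append(int(comp.sum()))
        peaks.append(float(hu[comp].max()))
    if not cents:
        return BeadSet(np.zeros((0, 3)), np.zeros(0, int), np.zeros(0), threshold)

    cents = np.array(cents)
    nvox = np.array(nvox)
    peaks = np.array(peaks)
    order = np.lexsort((cents[:, 2], cents[:, 1], cents[:, 0], -peaks))
    cents, nvox, peaks = cents[order], nvox[order], peaks[order]
    if len(cents) > 1 and pdist(cents).min() <= merge_distance:
        raise AmbiguityError(
            "two detected beads closer than the merge distance "
            f"({merge_distance} mm); refusing to merge them silently"
        )
    return BeadSet(cents, nvox, peaks, threshold)


def select_near(beads: BeadSet, center, radius: float,
                inside: bool = True) -> BeadSet:
    """Split a bead set by distance from a point — used to separate implant
    beads (inside the cup's bounding sphere) from bone beads."""
    d = np.linalg.norm(beads.centroids - np.asarray(center, float), axis=1)
    keep = d <= radius if inside else d > radius
    return beads.subset(keep)


def mutual_nearest(a: np.ndarray, b: np.ndarray, max_distance: float):
    """Mutual nearest-neighbour index pairs between two point sets."""
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, j_ab = tb.query(a)
    d_ba, i_ba = ta.query(b)
    pairs = []
    for i, (d, j) in enumerate(zip(d_ab, j_ab)):
        if d <= max_distance and i_ba[j] == i:
            pairs.append((i, int(j)))
    return pairs
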