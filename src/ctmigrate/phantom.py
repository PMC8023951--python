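"""Synthetic CT phantom: pelvis-like bone, acetabular cup, tantalum beads.

The generator emulates the double-examination study design used to estimate
method precision: two consecutive CT scans of the same hip with the patient
repositioned in between and, by assumption, zero true motion between cup and
pelvis.  Geometry is deliberately simple but carries the features the
measurement method relies on:

* a thick-walled half-ellipsoid bone shell with a hemispherical acetabular
  socket carved at its apex (the "pelvis");
* a hemispherical metal cup shell seated in the socket, with a few
  asymmetric screw holes so that all six degrees of freedom of the implant
  are observable from its surface;
* ~1 mm tantalum beads embedded in the bone wall and in the cup interior
  (standing in for beads in cement/polyethylene), placed by seeded
  rejection sampling;
* anti-aliased rasterization (supersampling), Gaussian partial-volume
  blur, and additive Gaussian HU noise.

All geometry parameters are world millimetres; every random choice flows
from explicit integer seeds, so volumes are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GenerationError
from .transform import RigidTransform
from .volume_io import CTVolume, GroundTruth

_REFERENCE_EXTENT_MM = 96.0  # extent of the default 160^3 x 0.6 mm grid


@dataclass(frozen=True)
class BoneGeometry:
    """Half-ellipsoid shell (z >= center_z) with a spherical socket carved
    around its apex."""

    center: tuple = (0.0, 0.0, -14.0)
    outer_radii: tuple = (36.0, 32.0, 28.0)
    wall_thickness: float = 7.0
    socket_radius: float = 17.0

    @property
    def inner_radii(self) -> np.ndarray:
        return np.asarray(self.outer_radii) - self.wall_thickness

    @property
    def apex(self) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        return c + np.array([0.0, 0.0, self.outer_radii[2]])

    def scaled(self, f: float) -> "BoneGeometry":
        return BoneGeometry(
            center=tuple(f * np.asarray(self.center)),
            outer_radii=tuple(f * np.asarray(self.outer_radii)),
            wall_thickness=f * self.wall_thickness,
            socket_radius=f * self.socket_radius,
        )


@dataclass(frozen=True)
class CupGeometry:
    """Hemispherical shell (dome pointing down, z <= center_z) seated in the
    socket.  ``holes`` are (azimuth°, polar°, radius mm) spherical cutouts
    through the shell — the screw holes of a real acetabular cup, and the
    feature that breaks the hemisphere's rotational symmetry."""

    center: tuple = (0.0, 0.0, 14.0)
    outer_radius: float = 16.5
    thickness: float = 4.0
    holes: tuple = ((0.0, 45.0, 2.5), (100.0, 55.0, 2.5), (210.0, 40.0, 2.5))

    @property
    def inner_radius(self) -> float:
        return self.outer_radius - self.thickness

    def hole_centers(self) -> np.ndarray:
        """World-frame (unposed) centers of the screw-hole cutout spheres."""
        c = np.asarray(self.center, dtype=float)
        mid = 0.5 * (self.outer_radius + self.inner_radius)
        out = []
        for az, pol, _r in self.holes:
            az, pol = np.deg2rad(az), np.deg2rad(pol)
            d = np.array(
                [np.sin(pol) * np.cos(az), np.sin(pol) * np.sin(az), -np.cos(pol)]
            )
            out.append(c + mid * d)
        return np.array(out).reshape(-1, 3)

    def scaled(self, f: float) -> "CupGeometry":
        return CupGeometry(
            center=tuple(f * np.asarray(self.center)),
            outer_radius=f * self.outer_radius,
            thickness=f * self.thickness,
            holes=tuple((az, pol, f * r) for az, pol, r in self.holes),
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic examination.

    HU defaults are plausible clinical values: soft-tissue background
    -50 HU, cortical-ish bone 700 HU, metal and tantalum 3000 HU.  The
    0.6 mm isotropic default spacing matches thin-slice hip protocols.
    ``blur_sigma`` models the scanner point-spread function of a sharp bone
    reconstruction kernel (sigma 0.4 mm ~ FWHM 0.9 mm); noise is additive
    Gaussian in HU.
    """

    grid_shape: tuple = (160, 160, 160)
    spacing: tuple = (0.6, 0.6, 0.6)
    bone: BoneGeometry = field(default_factory=BoneGeometry)
    cup: CupGeometry = field(default_factory=CupGeometry)
    n_bone_beads: int = 8
    n_implant_beads: int = 4
    bead_radius: float = 0.5
    hu_background: float = -50.0
    hu_bone: float = 700.0
    hu_metal: float = 3000.0
    hu_bead: float = 4000.0
    blur_sigma: float = 0.4
    noise_sigma: float = 20.0
    seed: int = 0
    supersample: int = 3
    bead_min_separation: float = 3.0
    bead_clearance: float = 0.5
    implant_bead_clearance: float = 2.5  # cement gap between bead and shell
    bone_bead_points: tuple | None = None
    implant_bead_points: tuple | None = None

    @classmethod
    def scaled_default(cls, grid_shape=(96, 96, 96), spacing=(0.6, 0.6, 0.6),
                       **overrides) -> "PhantomSpec":
        """Default geometry scaled to fit a different grid extent.

        Bead radius, clearances and HU values are physical properties and
        are not scaled; only the macroscopic geometry is.
        """
        extent = np.asarray(grid_shape) * np.asarray(spacing)
        f = float(extent.min()) / _REFERENCE_EXTENT_MM
        spec = cls(
            grid_shape=tuple(int(n) for n in grid_shape),
            spacing=tuple(float(s) for s in spacing),
            bone=BoneGeometry().scaled(f),
            cup=CupGeometry().scaled(f),
        )
        return replace(spec, **overrides) if overrides else spec

    # ------------------------------------------------------------------ #
    # grid
    # ------------------------------------------------------------------ #
    @property
    def origin(self) -> np.ndarray:
        """Grid centered on the world origin, voxel-center convention."""
        n = np.asarray(self.grid_shape, dtype=float)
        return -0.5 * (n - 1.0) * np.asarray(self.spacing)

    def validate(self) -> None:
        if self.cup.outer_radius >= self.bone.socket_radius:
            raise GenerationError(
                f"cup outer radius {self.cup.outer_radius} must be smaller "
                f"than the socket radius {self.bone.socket_radius}"
            )
        if not (self.hu_background < self.hu_bone < self.hu_metal <= self.hu_bead):
            raise GenerationError(
                "HU ordering must satisfy background < bone < metal <= bead"
            )
        if self.bead_min_separation < 2.0 * self.bead_radius:
            raise GenerationError(
                "bead_min_separation must be at least one bead diameter"
            )
        if self.supersample < 1:
            raise GenerationError("supersample must be >= 1")

    # ------------------------------------------------------------------ #
    # membership predicates (structure frame, vectorized over (N, 3))
    # ------------------------------------------------------------------ #
    def bone_contains(self, pts: np.ndarray, inset: float = 0.0,
                      socket_inset: float | None = None) -> np.ndarray:
        """Points inside the bone shell; ``inset`` demands a conservative
        margin (mm) from every bounding surface.  ``socket_inset`` lets the
        socket (which abuts the metal cup) demand a larger margin than the
        free bone surfaces."""
        g = self.bone
        c = np.asarray(g.center)
        q = pts - c
        ro = np.asarray(g.outer_radii)
        ri = g.inner_radii
        rho_o = np.sum((q / ro) ** 2, axis=-1)
        rho_i = np.sum((q / ri) ** 2, axis=-1)
        d_sock = np.linalg.norm(pts - g.apex, axis=-1)
        if socket_inset is None:
            socket_inset = inset
        if inset == 0.0:
            m = (rho_o <= 1.0) & (rho_i >= 1.0)
            m &= q[..., 2] >= 0.0
        else:
            m = rho_o <= (1.0 - inset / ro.min()) ** 2
            m &= rho_i >= (1.0 + inset / ri.min()) ** 2
            m &= q[..., 2] >= inset
        m &= d_sock >= g.socket_radius + socket_inset
        return m

    def cup_contains(self, pts: np.ndarray) -> np.ndarray:
        g = self.cup
        c = np.asarray(g.center)
        d = np.linalg.norm(pts - c, axis=-1)
        m = (d <= g.outer_radius) & (d >= g.inner_radius)
        m &= pts[..., 2] <= c[2]
        for hc, (_az, _pol, hr) in zip(g.hole_centers(), g.holes):
            m &= np.linalg.norm(pts - hc, axis=-1) > hr
        return m

    def cup_interior_contains(self, pts: np.ndarray, inset: float = 0.0) -> np.ndarray:
        """The cavity inside the cup shell (cement/liner space) that hosts
        the implant beads."""
        g = self.cup
        c = np.asarray(g.center)
        d = np.linalg.norm(pts - c, axis=-1)
        return (d <= g.inner_radius - inset) & (pts[..., 2] <= c[2] - inset)

    def geometry_corner_points(self) -> np.ndarray:
        """Bounding points of all structures, used for the grid-fit check."""
        pts = []
        bc, br = np.asarray(self.bone.center), np.asarray(self.bone.outer_radii)
        for sx in (-1, 1):
            for sy in (-1, 1):
                pts.append(bc + [sx * br[0], sy * br[1], 0.0])
                pts.append(bc + [sx * br[0], sy * br[1], br[2]])
        cc, cr = np.asarray(self.cup.center), self.cup.outer_radius
        for sx in (-1, 1):
            for sy in (-1, 1):
                for sz in (-1, 0):
                    pts.append(cc + cr * np.array([sx, sy, sz]))
        return np.array(pts)


# ---------------------------------------------------------------------- #
# bead placement
# ---------------------------------------------------------------------- #
def _sample_beads(spec: PhantomSpec, rng: np.random.Generator):
    """Rejection-sample bead centers inside their host structures.

    Beads must sit at least ``bead_radius + bead_clearance`` inside every
    host surface and at least ``bead_min_separation`` from each other.
    Explicit bead points given on the PhantomSpec bypass sampling but
    still go through the containment and collision checks.
    """
    depth = spec.bead_radius + spec.bead_clearance
    placed: list[np.ndarray] = []

    def _admit(predicate, n_wanted, label, host_depth):
        ok = 0
        lo = np.asarray(spec.origin)
        hi = lo + (np.asarray(spec.grid_shape) - 1) * np.asarray(spec.spacing)
        for _ in range(400):
            if ok >= n_wanted:
                break
            batch = rng.uniform(lo, hi, size=(4096, 3))
            good = predicate(batch)
            for p in batch[good]:
                if ok >= n_wanted:
                    break
                if all(
                    np.linalg.norm(p - q) >= spec.bead_min_separation for q in placed
                ):
                    placed.append(p)
                    ok += 1
        if ok < n_wanted:
            raise GenerationError(
                f"could not place {n_wanted} {label} beads with separation "
                f"{spec.bead_min_separation} mm and depth {host_depth} mm; "
                "the host structure may be too small for that many beads"
            )

    if spec.bone_bead_points is not None:
        bone_pts = np.asarray(spec.bone_bead_points, dtype=float).reshape(-1, 3)
        if not np.all(spec.bone_contains(bone_pts, inset=spec.bead_radius)):
            raise GenerationError("explicit bone bead outside its host structure")
        placed.extend(bone_pts)
    else:
        # keep bone beads clear of the socket: the metal cup sits right
        # behind that surface and bead detection excludes a dilated metal
        # neighbourhood, which must not swallow reference beads
        socket_depth = spec.bead_radius + max(spec.bead_clearance,
                                              spec.implant_bead_clearance) + 0.5
        _admit(lambda b: spec.bone_contains(b, inset=depth,
                                            socket_inset=socket_depth),
               spec.n_bone_beads, "bone", depth)
        bone_pts = np.array(placed[:spec.n_bone_beads]).reshape(-1, 3)

    n_before = len(placed)
    if spec.implant_bead_points is not None:
        imp_pts = np.asarray(spec.implant_bead_points, dtype=float).reshape(-1, 3)
        if not np.all(spec.cup_interior_contains(imp_pts, inset=spec.bead_radius)):
            raise GenerationError("explicit implant bead outside the cup interior")
        placed.extend(imp_pts)
    else:
        imp_depth = spec.bead_radius + max(spec.bead_clearance,
                                           spec.implant_bead_clearance)
        _admit(lambda b: spec.cup_interior_contains(b, inset=imp_depth),
               spec.n_implant_beads, "implant", imp_depth)
        imp_pts = np.array(placed[n_before:])

    all_pts = np.array(placed).reshape(-1, 3)
    if len(all_pts) > 1:
        from scipy.spatial.distance import pdist

        if pdist(all_pts).min() < 2.0 * spec.bead_radius:
            raise GenerationError(
                "bead collision: two bead centers closer than one bead diameter"
            )
    return bone_pts.reshape(-1, 3), imp_pts.reshape(-1, 3)


def sample_beads(spec: PhantomSpec):
    """Public seeded bead placement (bone points, implant points)."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xBEAD]))
    return _sample_beads(spec, rng)


# ---------------------------------------------------------------------- #
# rasterization
# ---------------------------------------------------------------------- #
def _check_in_grid(spec: PhantomSpec, poses) -> None:
    lo = spec.origin - 0.5 * np.asarray(spec.spacing)
    hi = lo + np.asarray(spec.grid_shape) * np.asarray(spec.spacing)
    corners = spec.geometry_corner_points()
    for pose in poses:
        w = pose.apply(corners)
        if np.any(w < lo) or np.any(w > hi):
            raise GenerationError(
                "posed phantom geometry extends outside the voxel grid"
            )


def _bone_membership_f32(spec: PhantomSpec, q: np.ndarray) -> np.ndarray:
    """Float32 bone-shell test on structure-frame points (N, 3)."""
    g = spec.bone
    c = np.asarray(g.center, dtype=np.float32)
    p = q - c
    inv_o = (1.0 / np.asarray(g.outer_radii, dtype=np.float64) ** 2).astype(np.float32)
    inv_i = (1.0 / g.inner_radii.astype(np.float64) ** 2).astype(np.float32)
    rho_o = (p * p * inv_o).sum(axis=-1)
    m = rho_o <= np.float32(1.0)
    m &= (p * p * inv_i).sum(axis=-1) >= np.float32(1.0)
    m &= p[..., 2] >= np.float32(0.0)
    s = q - g.apex.astype(np.float32)
    m &= (s * s).sum(axis=-1) >= np.float32(g.socket_radius ** 2)
    return m


def _cup_membership_f32(spec: PhantomSpec, q: np.ndarray) -> np.ndarray:
    """Float32 cup-shell test on structure-frame points (N, 3)."""
    g = spec.cup
    c = np.asarray(g.center, dtype=np.float32)
    p = q - c
    d2 = (p * p).sum(axis=-1)
    m = (d2 <= np.float32(g.outer_radius ** 2))
    m &= d2 >= np.float32(g.inner_radius ** 2)
    m &= q[..., 2] <= np.float32(c[2])
    for hc, (_az, _pol, hr) in zip(g.hole_centers(), g.holes):
        s = q - hc.astype(np.float32)
        m &= (s * s).sum(axis=-1) > np.float32(hr ** 2)
    return m


def _structure_bbox(spec: PhantomSpec, poses, beads_world) -> tuple:
    """World-space min/max bounds of the posed geometry."""
    pts = [pose.apply(spec.geometry_corner_points()) for pose in poses]
    if len(beads_world):
        pts.append(np.asarray(beads_world) + spec.bead_radius)
        pts.append(np.asarray(beads_world) - spec.bead_radius)
    allp = np.vstack(pts)
    return allp.min(axis=0), allp.max(axis=0)


def _rasterize(spec: PhantomSpec, bone_pose: RigidTransform,
               implant_pose: RigidTransform, noise_seed,
               bone_beads: np.ndarray, implant_beads: np.ndarray) -> CTVolume:
    """Supersampled rasterization -> PSF blur -> additive noise.

    Membership is evaluated in each structure's own frame by pulling fine
    world points back through the inverse pose, so a posed phantom is the
    analytic transform of the identity phantom (not a resampling of it).
    Work is restricted to the bounding box of the posed geometry; the rest
    of the grid is uniform background.
    """
    _check_in_grid(spec, [bone_pose, implant_pose])
    nx, ny, nz = spec.grid_shape
    S = int(spec.supersample)
    sp = np.asarray(spec.spacing)
    origin = spec.origin

    inv_bone = bone_pose.inverse()
    inv_imp = implant_pose.inverse()
    bead_r2 = np.float32(spec.bead_radius ** 2)
    bead_world = [(bone_pose.apply(p)) for p in bone_beads]
    bead_world += [(implant_pose.apply(p)) for p in implant_beads]

    # coarse index window containing all posed structures (+1 voxel pad)
    lo_w, hi_w = _structure_bbox(spec, [bone_pose, implant_pose], bead_world)
    lo_i = np.maximum(np.floor((lo_w - origin) / sp).astype(int) - 1, 0)
    hi_i = np.minimum(np.ceil((hi_w - origin) / sp).astype(int) + 2,
                      np.array([nx, ny, nz]))
    wx, wy, wz = hi_i - lo_i

    Rb = inv_bone.rotation.astype(np.float32)
    tb = inv_bone.translation.astype(np.float32)
    Ri = inv_imp.rotation.astype(np.float32)
    ti = inv_imp.translation.astype(np.float32)

    def hu_at(flat: np.ndarray) -> np.ndarray:
        """HU of arbitrary world points, priority bead > metal > bone."""
        hu = np.full(flat.shape[0], spec.hu_background, dtype=np.float32)
        hu[_bone_membership_f32(spec, flat @ Rb.T + tb)] = spec.hu_bone
        hu[_cup_membership_f32(spec, flat @ Ri.T + ti)] = spec.hu_metal
        wmin = flat.min(axis=0) - spec.bead_radius
        wmax = flat.max(axis=0) + spec.bead_radius
        for wc in bead_world:
            if np.any(wc < wmin) or np.any(wc > wmax):
                continue
            s = flat - wc.astype(np.float32)
            hu[(s * s).sum(axis=-1) <= bead_r2] = spec.hu_bead
        return hu

    # pass 1: voxel-center labels over the geometry window
    ci = ((np.arange(lo_i[0], hi_i[0]) * sp[0]) + origin[0]).astype(np.float32)
    cj = ((np.arange(lo_i[1], hi_i[1]) * sp[1]) + origin[1]).astype(np.float32)
    ck = ((np.arange(lo_i[2], hi_i[2]) * sp[2]) + origin[2]).astype(np.float32)
    centers = np.empty((wx, wy, wz, 3), dtype=np.float32)
    centers[..., 0] = ci[:, None, None]
    centers[..., 1] = cj[None, :, None]
    centers[..., 2] = ck[None, None, :]
    win = hu_at(centers.reshape(-1, 3)).reshape(wx, wy, wz)

    # pass 2: supersample only voxels whose 26-neighbourhood is not
    # uniform (structure boundaries) or that a bead's bbox touches —
    # everywhere else the voxel mean equals the center value exactly
    from scipy.ndimage import maximum_filter, minimum_filter

    boundary = maximum_filter(win, size=3) != minimum_filter(win, size=3)
    for wc in bead_world:
        blo = np.floor((wc - spec.bead_radius - origin) / sp).astype(int) - 1
        bhi = np.ceil((wc + spec.bead_radius - origin) / sp).astype(int) + 2
        blo = np.maximum(blo - lo_i, 0)
        bhi = np.minimum(bhi - lo_i, [wx, wy, wz])
        boundary[blo[0]:bhi[0], blo[1]:bhi[1], blo[2]:bhi[2]] = True

    if S > 1 and boundary.any():
        bidx = np.argwhere(boundary)  # window indices
        off = (np.arange(S, dtype=np.float32) + 0.5) / S - 0.5
        oi, oj, ok = np.meshgrid(off, off, off, indexing="ij")
        offsets = np.stack([oi, oj, ok], axis=-1).reshape(-1, 3) * sp.astype(
            np.float32)
        base = ((bidx + lo_i) * sp + origin).astype(np.float32)
        chunk = max(1, 2_000_000 // offsets.shape[0])
        means = np.empty(len(bidx), dtype=np.float32)
        for s0 in range(0, len(bidx), chunk):
            s1 = min(len(bidx), s0 + chunk)
            pts = (base[s0:s1, None, :] + offsets[None, :, :]).reshape(-1, 3)
            means[s0:s1] = hu_at(pts).reshape(s1 - s0, -1).mean(axis=1)
        win[tuple(bidx.T)] = means

    out = np.full((nx, ny, nz), np.float32(spec.hu_background), dtype=np.float32)
    out[lo_i[0]:hi_i[0], lo_i[1]:hi_i[1], lo_i[2]:hi_i[2]] = win

    if spec.blur_sigma > 0:
        out = gaussian_filter(out, sigma=spec.blur_sigma / sp, mode="nearest")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(noise_seed)
        out = out + rng.normal(0.0, spec.noise_sigma, out.shape).astype(np.float32)

    return CTVolume(
        voxels=out.astype(np.float32),
        spacing=sp,
        origin=origin,
        direction=np.eye(3),
        meta={"phantom": "ctmigrate", "noise_sigma": str(spec.noise_sigma)},
    )


def generate_phantom(spec: PhantomSpec,
                     pose: RigidTransform | None = None):
    """Rasterize one examination with the whole phantom moved by ``pose``.

    Returns ``(volume, truth)`` where the ground truth records the posed
    bead positions; ``implant_pose`` is the identity because bone and
    implant move together (no cup-vs-pelvis motion within one exam).
    """
    spec.validate()
    pose = pose or RigidTransform.identity()
    bone_pts, imp_pts = sample_beads(spec)
    noise_seed = np.random.SeedSequence([int(spec.seed), 0x5EED])
    vol = _rasterize(spec, pose, pose, noise_seed, bone_pts, imp_pts)
    truth = GroundTruth(
        bead_positions_bone=pose.apply(bone_pts) if len(bone_pts) else bone_pts,
        bead_positions_implant=pose.apply(imp_pts) if len(imp_pts) else imp_pts,
        implant_pose=RigidTransform.identity(),
        repositioning=pose,
    )
    return vol, truth


def simulate_double_exam(spec: PhantomSpec, repositioning: RigidTransform,
                         migration: RigidTransform, seeds=(0, 1)):
    """Simulate a double examination.

    Exam 1 is at identity.  In exam 2 the whole anatomy is moved by
    ``repositioning``; the implant (cup and implant beads) additionally
    moves by ``migration`` expressed in the exam-1 pelvis frame, i.e. its
    exam-2 pose is ``repositioning ∘ migration``.  Noise is independent per
    exam through ``seeds``.  With ``migration = identity`` the pair
    realizes the double-examination assumption: any measured motion is
    method error.
    """
    spec.validate()
    bone_pts, imp_pts = sample_beads(spec)
    ident = RigidTransform.identity()
    implant_pose_2 = repositioning.compose(migration)
    exam1 = _rasterize(spec, ident, ident,
                       np.random.SeedSequence([int(seeds[0]), 0x5EED]),
                       bone_pts, imp_pts)
    exam2 = _rasterize(spec, repositioning, implant_pose_2,
                       np.random.SeedSequence([int(seeds[1]), 0x5EED]),
                       bone_pts, imp_pts)
    truth = GroundTruth(
        bead_positions_bone=bone_pts,
        bead_positions_implant=imp_pts,
        implant_pose=migration,
        repositioning=repositioning,
    )
    return exam1, exam2, truth


def sample_repositioning(rng: np.random.Generator,
                         rot_deg=(0.5, 2.0), trans_mm=(1.0, 5.0)) -> RigidTransform:
    """Random patient repositioning between consecutive scans.

    Models the *residual* misalignment after the radiographer recenters the
    patient in the field of view: a rotation of 0.5-2 degrees about a random
    axis and a 1-5 mm shift in a random direction.
    """
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(*rot_deg)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    shift = rng.uniform(*trans_mm) * direction
    return RigidTransform.from_axis_angle(axis, angle, shift)
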