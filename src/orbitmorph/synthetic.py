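"""Synthetic paired (T1, T2) orbital-cavity phantoms with known ground truth.

The phantom emulates the imaging situation of the study cohort: a
soft-tissue-filled orbital cavity bounded by a bone-intensity shell and
surrounded by air, imaged at two time points.  The cavity is a truncated
paraboloid of revolution (wide anterior aperture, narrow posterior
apex) — not anatomy-accurate, but topologically equivalent to an orbit
for every downstream stage: it admits the same anterior/posterior
landmark cut planes and a star-shaped surface.

Between T1 and T2 the cavity wall is displaced by Gaussian bumps placed
near the frontozygomatic and frontomaxillary regions of the rim (where
the clinical colour maps localise the post-expansion change), the whole
T2 anatomy is moved by a small rigid offset (patient repositioning), and
fresh acquisition noise is added.

Ground truth (volumes, increment, within-tolerance surface fractions)
is computed from the implicit geometry itself by star-shaped radial
quadrature with vectorised bisection — a dense-sampling oracle that is
independent of the voxel pipeline being validated.

Coordinates: world mm; the cavity axis runs along +y (posterior apex to
anterior aperture).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CalibrationFailed, DegeneratePhantom, GridTooSmall
from .image import VolumeImage, write_volume
from .registration import RigidTransform

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "OrbitGeometry",
    "generate_phantom_pair",
    "calibrate_bumps",
    "oracle_cropped_volume",
    "save_phantom_pair",
]

LANDMARK_NAMES = ("FZS", "SF", "ALC", "OC1", "OC2", "OC3")

# geometry constants: aperture/length aspect and crop-plane fractions
_ASPECT_L_OVER_R = 2.4
_POSTERIOR_PLANE_FRAC = 0.10
_ANTERIOR_PLANE_FRAC = 0.92
# azimuth (deg) / axial-fraction placement of rim landmarks and bumps
_ANTERIOR_LM_AZ = {"FZS": 40.0, "SF": 150.0, "ALC": 260.0}
_POSTERIOR_LM_AZ = {"OC1": 20.0, "OC2": 140.0, "OC3": 265.0}
_BUMP_PLACEMENT = ((45.0, 0.66), (200.0, 0.45))  # (azimuth deg, axial fraction): FZ, FM


@dataclass
class PhantomParams:
    """Generator knobs; defaults mirror the study conditions."""

    cavity_mean_volume: float = 24.0  # cm^3, cropped (between-planes) T1 volume
    cavity_volume_cv: float = 0.07  # per-subject fractional SD of cavity volume
    bump_centers: np.ndarray | None = None  # (n,3) world mm; None = FZ/FM placement
    bump_amplitudes: tuple[float, ...] = (0.0, 0.0)  # mm, signed, outward positive
    bump_sigma: float = 4.5  # mm
    rigid_rotation_deg: tuple[float, float, float] = (2.0, -1.5, 2.5)
    rigid_translation: tuple[float, float, float] = (1.2, -0.8, 1.5)  # mm
    noise_sd: float = 30.0  # intensity units
    cross_section_ellipticity: float = 1.10  # z/x axis ratio of the cavity section
    texture_amplitude: float = 2.0  # mm, max height of static wall relief (0 disables)
    texture_sigma: float = 1.8  # mm, lateral extent of relief features
    n_texture: int = 40  # relief features per subject
    voxel_spacing: float = 0.3  # mm, isotropic
    intensity_air: float = 50.0
    intensity_soft: float = 600.0
    intensity_bone: float = 1600.0
    shell_thickness: float = 4.5  # mm of bone around the cavity
    grid_shape: tuple[int, int, int] | None = None  # None = auto-size
    palatal_width: float = 30.0  # mm at T1
    palatal_expansion: float = 2.2  # mm mean T2-T1 widening
    palatal_expansion_sd: float = 0.33  # mm per-subject SD
    seed: int = 0

    def validate(self) -> None:
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be > 0")
        if self.bump_sigma <= 0:
            raise ValueError("bump_sigma must be > 0")
        levels = sorted([self.intensity_air, self.intensity_soft, self.intensity_bone])
        min_sep = min(levels[1] - levels[0], levels[2] - levels[1])
        if self.noise_sd > 0 and min_sep < 5.0 * self.noise_sd:
            raise ValueError("intensity levels must be separated by >= 5x noise_sd")
        if any(abs(a) > self.shell_thickness for a in self.bump_amplitudes):
            raise DegeneratePhantom(
                "bump displacement exceeds the bone-shell thickness"
            )

    def rigid_offset(self) -> RigidTransform:
        return RigidTransform.from_euler_deg(self.rigid_rotation_deg, self.rigid_translation)


def _sum_gaussians(x, y, z, centers, amplitudes, sigma) -> np.ndarray:
    """Sum of isotropic Gaussians, evaluating exp only within 4.5 sigma.

    The masked evaluation matters: with tens of relief features per
    subject the exponential would otherwise dominate the whole phantom
    generation time.
    """
    xb, yb, zb = np.broadcast_arrays(x, y, z)
    shape = xb.shape
    pts = np.empty((int(np.prod(shape)), 3), dtype=np.float32)
    pts[:, 0] = xb.ravel()
    pts[:, 1] = yb.ravel()
    pts[:, 2] = zb.ravel()
    centers = np.asarray(centers, dtype=np.float32)
    amplitudes = np.asarray(amplitudes, dtype=np.float32)
    live = amplitudes != 0.0
    centers, amplitudes = centers[live], amplitudes[live]
    out = np.zeros(len(pts), dtype=np.float32)
    if len(centers):
        cut2 = np.float32((4.5 * sigma) ** 2)
        inv = np.float32(1.0 / (2.0 * sigma**2))
        c2 = np.einsum("ij,ij->i", centers, centers)
        for start in range(0, len(pts), 262144):
            block = pts[start:start + 262144]
            # squared distances to every centre via one BLAS product
            d2 = (
                np.einsum("ij,ij->i", block, block)[:, None]
                + c2[None, :]
                - 2.0 * (block @ centers.T)
            )
            ex = np.zeros_like(d2)
            np.exp(-d2 * inv, where=d2 < cut2, out=ex)
            out[start:start + 262144] = ex @ amplitudes
    return out.reshape(shape)


@dataclass
class OrbitGeometry:
    """Scaled analytic geometry of one subject's cavity (internal).

    The cavity is an elliptic paraboloid: in axis-scaled coordinates
    ``x' = (x - cx)/sx, z' = (z - cz)/sz`` the wall is
    ``rho'^2 = c (y - ya0)``.  The mild ellipticity (sx sz = 1, so
    volumes are unchanged) breaks the rotational symmetry a pure surface
    of revolution would have — real orbits are not symmetric either, and
    a symmetric phantom would leave the azimuth of the rigid
    registration unconstrained.
    """

    cx: float
    cz: float
    ya0: float  # apex y
    length: float  # apex-to-aperture length L
    aperture_radius: float  # geometric-mean semi-axis R at the anterior face
    y_post: float  # posterior crop plane
    y_ant: float  # anterior crop plane
    bump_centers: np.ndarray  # (n, 3)
    bump_amplitudes: np.ndarray  # (n,)
    bump_sigma: float
    sx: float = 1.0  # x semi-axis scale (sx * sz = 1)
    sz: float = 1.0
    # static per-subject wall relief, identical at both time points
    texture_centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    texture_amplitudes: np.ndarray = field(default_factory=lambda: np.zeros(0))
    texture_sigma: float = 2.5

    @property
    def c(self) -> float:  # paraboloid coefficient, rho'^2 = c (y - ya0)
        return self.aperture_radius**2 / self.length

    @property
    def y_front(self) -> float:
        return self.ya0 + self.length

    def rho_s(self, y):
        """Scaled-coordinate wall radius at height y."""
        return np.sqrt(self.c * np.clip(y - self.ya0, 0.0, None))

    def rim_point(self, y: float, azimuth_rad: float) -> np.ndarray:
        """World point on the wall at the given height and azimuth."""
        r = float(self.rho_s(y))
        return np.array([
            self.cx + self.sx * r * np.cos(azimuth_rad),
            y,
            self.cz + self.sz * r * np.sin(azimuth_rad),
        ])

    def phi_t1(self, x, y, z):
        """Implicit function of the T1 cavity (negative inside).

        The static texture field (orbital-wall relief shared by both
        time points) is part of the baseline anatomy: it anchors the
        rigid registration the way fissures and fossae do on real
        orbital surfaces.
        """
        rho = np.hypot((x - self.cx) / self.sx, (z - self.cz) / self.sz)
        dy = y - self.ya0
        wall = np.where(dy >= 0, rho - self.rho_s(y), np.hypot(rho, dy))
        base = np.maximum(wall, y - self.y_front)
        if len(self.texture_amplitudes):
            base = base - self._near_wall_field(
                base, x, y, z, self.texture_centers, self.texture_amplitudes,
                self.texture_sigma,
            )
        return base

    def bump_field(self, x, y, z, base=None):
        if not len(self.bump_amplitudes) or not np.any(self.bump_amplitudes != 0.0):
            return 0.0
        if base is not None:
            return self._near_wall_field(
                base, x, y, z, self.bump_centers, self.bump_amplitudes, self.bump_sigma
            )
        return _sum_gaussians(
            x, y, z, self.bump_centers, self.bump_amplitudes, self.bump_sigma
        )

    @staticmethod
    def _near_wall_field(base, x, y, z, centers, amps, sigma):
        """Gaussian field restricted to the wall neighbourhood.

        Relief and deformation amplitudes are bounded well below 8 mm, so
        points farther than that from the undisturbed wall keep their
        material regardless — skipping them makes voxel-grid evaluation
        several times cheaper.
        """
        base = np.asarray(base)
        if base.size < 200_000:
            return _sum_gaussians(x, y, z, centers, amps, sigma)
        sel = np.abs(base) < 8.0
        xb, yb, zb = np.broadcast_arrays(x, y, z)
        out = np.zeros(base.shape, dtype=np.float32)
        out[sel] = _sum_gaussians(xb[sel], yb[sel], zb[sel], centers, amps, sigma)
        return out

    def phi_t2(self, x, y, z):
        """Implicit function of the deformed (T2) cavity in material frame."""
        base = self.phi_t1(x, y, z)
        return base - self.bump_field(x, y, z, base=base)

    def analytic_cropped_volume_t1(self) -> float:
        """Exact slab volume of the undeformed cavity between the planes, mm^3."""
        a = self.y_ant - self.ya0
        p = self.y_post - self.ya0
        return float(np.pi * self.c / 2.0 * (a**2 - p**2))


def _build_geometry(params: PhantomParams, jitter: float = 1.0) -> OrbitGeometry:
    """Solve paraboloid dimensions for the (jittered) target cropped volume."""
    v_mm3 = params.cavity_mean_volume * 1000.0 * jitter
    frac = _ANTERIOR_PLANE_FRAC**2 - _POSTERIOR_PLANE_FRAC**2
    # V = pi/2 * R^2 * L * frac with L = aspect * R
    r = (2.0 * v_mm3 / (np.pi * frac * _ASPECT_L_OVER_R)) ** (1.0 / 3.0)
    length = _ASPECT_L_OVER_R * r
    ya0 = params.shell_thickness + 1.0
    ell = np.sqrt(params.cross_section_ellipticity)
    geom = OrbitGeometry(
        cx=0.0,
        cz=0.0,
        ya0=ya0,
        length=length,
        aperture_radius=r,
        y_post=ya0 + _POSTERIOR_PLANE_FRAC * length,
        y_ant=ya0 + _ANTERIOR_PLANE_FRAC * length,
        bump_centers=np.zeros((0, 3)),
        bump_amplitudes=np.zeros(0),
        bump_sigma=params.bump_sigma,
        sx=1.0 / ell,
        sz=ell,
    )
    if params.bump_centers is not None:
        centers = np.atleast_2d(np.asarray(params.bump_centers, dtype=float))
    else:
        centers = np.asarray([
            geom.rim_point(ya0 + yfrac * length, np.radians(az_deg))
            for az_deg, yfrac in _BUMP_PLACEMENT
        ])
    amps = np.asarray(params.bump_amplitudes, dtype=float)
    if len(amps) != len(centers):
        raise ValueError("bump_amplitudes and bump_centers lengths differ")
    geom.bump_centers = centers
    geom.bump_amplitudes = amps
    return geom


# ---------------------------------------------------------------------------
# ground-truth quadrature (star-shaped radial representation)

def _radial_surface(geom: OrbitGeometry, timepoint: str, y: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Radius r(y, theta) of the zero level set, by vectorised bisection.

    The cavity is star-shaped around its axis and the Gaussian radial
    slopes are < 1, so the implicit function is monotone along each ray
    and the crossing is unique.  Along a fixed ray the squared distance
    to each Gaussian centre is a quadratic in r, so the per-ray
    coefficients are precomputed once and each bisection step is pure
    arithmetic (no 3D field evaluation).
    """
    yy, tt = np.meshgrid(y, theta, indexing="ij")
    shape = yy.shape
    yy = yy.ravel()
    tt = tt.ravel()
    cos_t, sin_t = np.cos(tt), np.sin(tt)
    # wall part: phi_wall(r) = r * slope(theta) - rho_s(y); face term constant
    slope = np.hypot(cos_t / geom.sx, sin_t / geom.sz)
    rho_s = geom.rho_s(yy)
    face = yy - geom.y_front

    groups = []  # (b, c, amp, inv_2sig2, cut2) per Gaussian family
    fams = [(geom.texture_centers, geom.texture_amplitudes, geom.texture_sigma)]
    if timepoint == "T2":
        fams.append((geom.bump_centers, geom.bump_amplitudes, geom.bump_sigma))
    ox, oz = geom.cx, geom.cz
    for centers, amps, sigma in fams:
        centers = np.asarray(centers, dtype=float)
        amps = np.asarray(amps, dtype=float)
        live = amps != 0.0
        if not live.any():
            continue
        centers, amps = centers[live], amps[live]
        dx = centers[:, 0][None, :] - ox
        dy = centers[:, 1][None, :] - yy[:, None]
        dz = centers[:, 2][None, :] - oz
        b2 = (-2.0 * (cos_t[:, None] * dx + sin_t[:, None] * dz)).astype(np.float32)
        c = (dx * dx + dy * dy + dz * dz).astype(np.float32)  # |ctr - o|^2
        inv = np.float32(1.0 / (2.0 * sigma**2))
        groups.append((b2, c, amps.astype(np.float32), inv,
                       np.float32(-((4.5 * sigma) ** 2) * inv),
                       np.empty_like(c), np.empty_like(c),
                       np.empty(c.shape, dtype=bool)))

    amax = float(np.abs(geom.bump_amplitudes).max()) if len(geom.bump_amplitudes) else 0.0
    if len(geom.texture_amplitudes):
        amax += float(np.abs(geom.texture_amplitudes).max())
    lo = np.zeros_like(yy)
    hi = np.full_like(yy, max(geom.sx, geom.sz) * geom.aperture_radius + amax + 2.0)
    for _ in range(34):
        mid = 0.5 * (lo + hi)
        val = np.maximum(mid * slope - rho_s, face)
        m32 = mid.astype(np.float32)[:, None]
        for b2, c, amps, inv, thresh, d2, ex, msk in groups:
            np.add(b2, m32, out=d2)
            np.multiply(d2, m32, out=d2)
            np.add(d2, c, out=d2)
            np.multiply(d2, -inv, out=d2)  # d2 now holds -d2 / (2 sigma^2)
            np.greater(d2, thresh, out=msk)
            ex.fill(0.0)
            np.exp(d2, where=msk, out=ex)
            val = val - ex @ amps
        inside = val < 0
        lo = np.where(inside, mid, lo)
        hi = np.where(inside, hi, mid)
    return (0.5 * (lo + hi)).reshape(shape)


def _quadrature_cropped_volume(geom: OrbitGeometry, timepoint: str, n_y: int = 120, n_theta: int = 160) -> float:
    """Slab volume between the crop planes: V = int int r^2/2 dtheta dy."""
    nodes, weights = np.polynomial.legendre.leggauss(n_y)
    y = 0.5 * (geom.y_post + geom.y_ant) + 0.5 * (geom.y_ant - geom.y_post) * nodes
    wy = 0.5 * (geom.y_ant - geom.y_post) * weights
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    r = _radial_surface(geom, timepoint, y, theta)
    ring = (r**2).sum(axis=1) * (2.0 * np.pi / n_theta) / 2.0
    return float((ring * wy).sum())


def _t1_cropped_reference_surface(
    geom: OrbitGeometry, n_y: int = 120, n_theta: int = 256
) -> "object":
    """Exact-distance query against a fine triangulation of the cropped
    T1 surface (wall strip plus the two planar cap discs).

    Triangulating (rather than point-sampling) keeps the distance exact
    up to the chord error, which at this resolution is sub-micron —
    far below the tolerance-band scale where the counting happens.
    """
    from .meshes import NearestSurface, make_mesh

    y = np.linspace(geom.y_post, geom.y_ant, n_y)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    r = _radial_surface(geom, "T1", y, theta)
    tt = theta[None, :]
    wall = np.stack([
        geom.cx + r * np.cos(tt),
        np.broadcast_to(y[:, None], r.shape),
        geom.cz + r * np.sin(tt),
    ], axis=-1)

    verts = [wall.reshape(-1, 3)]
    faces = []
    nv = 0
    for i in range(n_y - 1):
        cols = np.arange(n_theta)
        a = nv + i * n_theta + cols
        b = nv + i * n_theta + (cols + 1) % n_theta
        c = nv + (i + 1) * n_theta + cols
        d = nv + (i + 1) * n_theta + (cols + 1) % n_theta
        faces.append(np.column_stack([a, b, c]))
        faces.append(np.column_stack([b, d, c]))
    nv += n_y * n_theta

    for iy, y_cap in ((0, geom.y_post), (-1, geom.y_ant)):
        edge_r = r[iy]
        n_r = 16
        rows = []
        for k in range(1, n_r + 1):
            frac = k / n_r
            rows.append(np.stack([
                geom.cx + frac * edge_r * np.cos(theta),
                np.full(n_theta, y_cap),
                geom.cz + frac * edge_r * np.sin(theta),
            ], axis=-1))
        cap_verts = np.concatenate([v.reshape(-1, 3) for v in rows], axis=0)
        center = np.array([[geom.cx, y_cap, geom.cz]])
        verts.append(cap_verts)
        verts.append(center)
        cols = np.arange(n_theta)
        for k in range(n_r - 1):
            a = nv + k * n_theta + cols
            b = nv + k * n_theta + (cols + 1) % n_theta
            c = nv + (k + 1) * n_theta + cols
            d = nv + (k + 1) * n_theta + (cols + 1) % n_theta
            faces.append(np.column_stack([a, b, c]))
            faces.append(np.column_stack([b, d, c]))
        center_idx = nv + n_r * n_theta
        a = nv + cols
        b = nv + (cols + 1) % n_theta
        faces.append(np.column_stack([
            a, b, np.full(n_theta, center_idx)
        ]))
        nv += n_r * n_theta + 1

    mesh = make_mesh(np.concatenate(verts, axis=0), np.concatenate(faces, axis=0))
    return NearestSurface(mesh, k=8, signed=False)


def _truth_match_fractions(
    geom: OrbitGeometry, tolerances=(0.20, 0.40), n_y: int = 160, n_theta: int = 208,
    reference=None,
) -> dict[float, float]:
    """Area fraction of the cropped T2 surface within each tolerance of T1.

    Dense structured sampling of the T2 surface (wall r(y,theta) plus the
    two cap discs), exact point-to-triangle distance to a fine
    triangulation of the cropped T1 surface, area weights from the
    parametric surface element.
    """
    if reference is None:
        reference = _t1_cropped_reference_surface(geom)
    y = np.linspace(geom.y_post, geom.y_ant, n_y)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    r = _radial_surface(geom, "T2", y, theta)
    tt = theta[None, :]
    px = geom.cx + r * np.cos(tt)
    pz = geom.cz + r * np.sin(tt)
    py = np.broadcast_to(y[:, None], r.shape)
    pts = np.stack([px, py, pz], axis=-1)
    # parametric tangents -> area element (theta direction is periodic)
    dy_t = np.gradient(pts, y, axis=0)
    dth = 2.0 * np.pi / n_theta
    dt_t = (np.roll(pts, -1, axis=1) - np.roll(pts, 1, axis=1)) / (2.0 * dth)
    w_wall = np.linalg.norm(np.cross(dy_t, dt_t), axis=-1) * (y[1] - y[0]) * dth
    weights = [w_wall.ravel()]
    points = [pts.reshape(-1, 3)]
    # cap discs of the T2 crop (polar quadrature up to r(y_cap, theta))
    for y_cap, iy in ((geom.y_post, 0), (geom.y_ant, -1)):
        r_edge = r[iy]  # (n_theta,)
        n_r = 48
        u = (np.arange(n_r) + 0.5) / n_r
        rr = r_edge[None, :] * u[:, None]
        w_cap = r_edge[None, :] ** 2 * u[:, None] * (1.0 / n_r) * dth
        cap_pts = np.stack([
            geom.cx + rr * np.cos(tt),
            np.full_like(rr, y_cap),
            geom.cz + rr * np.sin(tt),
        ], axis=-1)
        weights.append(w_cap.ravel())
        points.append(cap_pts.reshape(-1, 3))
    w = np.concatenate(weights)
    d, _, _, _ = reference.query(np.concatenate(points, axis=0))
    total = w.sum()
    return {float(t): float(w[d <= t].sum() / total) for t in tolerances}


def oracle_cropped_volume(
    geom: OrbitGeometry, timepoint: str, spacing: float, oversample: int = 4
) -> float:
    """Independent volume oracle: marching cubes of the implicit field
    sampled at ``spacing / oversample``, volume by the divergence theorem.

    Used by validation only — a second numerical route against the
    radial-quadrature truth.
    """
    from skimage.measure import marching_cubes
    import trimesh

    phi = geom.phi_t1 if timepoint == "T1" else geom.phi_t2
    h = spacing / float(oversample)
    amax = float(np.abs(geom.bump_amplitudes).max()) if len(geom.bump_amplitudes) else 0.0
    if len(geom.texture_amplitudes):
        amax += float(np.abs(geom.texture_amplitudes).max())
    rmax = max(geom.sx, geom.sz) * geom.aperture_radius + amax + 2.0
    xs = np.arange(geom.cx - rmax, geom.cx + rmax + h, h)
    ys = np.arange(geom.y_post - 2.0, geom.y_ant + 2.0, h)
    zs = np.arange(geom.cz - rmax, geom.cz + rmax + h, h)
    x = xs[:, None, None]
    y = ys[None, :, None]
    z = zs[None, None, :]
    f = phi(x, y, z)
    f = np.maximum(f, y - geom.y_ant)
    f = np.maximum(f, geom.y_post - y)
    verts, faces, _, _ = marching_cubes(f.astype(np.float32), 0.0, spacing=(h, h, h))
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return float(abs(mesh.volume))


# ---------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Generator ground truth for one (T1, T2) phantom pair."""

    true_volume_t1: float  # cm^3, cropped slab
    true_volume_t2: float  # cm^3
    true_increment: float  # cm^3, t2 - t1
    true_match_fraction: dict[float, float]  # tolerance mm -> fraction in [0, 1]
    applied_rigid: RigidTransform  # material (T1 frame) -> T2 scanner frame
    landmarks_t1: dict[str, np.ndarray]
    landmarks_t2: dict[str, np.ndarray]
    palatal_t1: np.ndarray  # (2, 3) left/right junction points
    palatal_t2: np.ndarray
    seed_point_t1: np.ndarray
    seed_point_t2: np.ndarray
    geometry: OrbitGeometry = field(repr=False, default=None)

    def __post_init__(self) -> None:
        names = set(self.landmarks_t1)
        if names != set(LANDMARK_NAMES):
            raise ValueError(f"landmark names must be exactly {LANDMARK_NAMES}")
        tols = sorted(self.true_match_fraction)
        fracs = [self.true_match_fraction[t] for t in tols]
        if any(b < a - 1e-12 for a, b in zip(fracs, fracs[1:])):
            raise ValueError("true_match_fraction must be non-decreasing in tolerance")

    def to_json_dict(self) -> dict:
        return {
            "true_volume_t1_cm3": self.true_volume_t1,
            "true_volume_t2_cm3": self.true_volume_t2,
            "true_increment_cm3": self.true_increment,
            "true_match_fraction": {f"{k:.2f}": v for k, v in self.true_match_fraction.items()},
            "applied_rigid": self.applied_rigid.to_json_dict(),
            "landmarks_t1": [
                {"name": n, "x": p[0], "y": p[1], "z": p[2]}
                for n, p in self.landmarks_t1.items()
            ],
            "landmarks_t2": [
                {"name": n, "x": p[0], "y": p[1], "z": p[2]}
                for n, p in self.landmarks_t2.items()
            ],
            "palatal_t1": self.palatal_t1.tolist(),
            "palatal_t2": self.palatal_t2.tolist(),
            "seed_point_t1": self.seed_point_t1.tolist(),
            "seed_point_t2": self.seed_point_t2.tolist(),
        }


def _apply_texture(geom: OrbitGeometry, params: PhantomParams, rng: np.random.Generator) -> None:
    """Draw the per-subject static wall relief onto the geometry in place."""
    if params.texture_amplitude <= 0 or params.n_texture <= 0:
        return
    az = rng.uniform(0.0, 2.0 * np.pi, params.n_texture)
    yfrac = rng.uniform(0.18, 0.85, params.n_texture)
    amp = rng.uniform(0.4 * params.texture_amplitude, params.texture_amplitude,
                      params.n_texture) * rng.choice([-1.0, 1.0], params.n_texture)
    geom.texture_centers = np.asarray([
        geom.rim_point(geom.ya0 + f * geom.length, a) for a, f in zip(az, yfrac)
    ])
    geom.texture_amplitudes = amp
    geom.texture_sigma = params.texture_sigma


def _landmarks(geom: OrbitGeometry) -> dict[str, np.ndarray]:
    lms = {name: geom.rim_point(geom.y_ant, np.radians(az))
           for name, az in _ANTERIOR_LM_AZ.items()}
    lms.update({name: geom.rim_point(geom.y_post, np.radians(az))
                for name, az in _POSTERIOR_LM_AZ.items()})
    return lms


def _auto_grid(params: PhantomParams, geom_max_rho: float, y_front: float) -> tuple[int, int, int]:
    h = params.voxel_spacing
    half_xz = geom_max_rho + params.shell_thickness + 2.0
    n_xz = int(np.ceil(2.0 * half_xz / h)) + 1
    n_y = int(np.ceil((y_front + 2.0) / h)) + 1
    return (n_xz, n_y, n_xz)


def _intensity_volume(
    params: PhantomParams, phi_on_grid: np.ndarray, spacing: float
) -> np.ndarray:
    """Map an implicit-function sample to CBCT-like intensities.

    The gradient-normalised field approximates signed distance, so the
    soft/bone and bone/air transitions are one voxel wide everywhere
    (partial-volume emulation) and the bone shell has the requested
    metric thickness.
    """
    gx, gy, gz = np.gradient(phi_on_grid, spacing, spacing, spacing)
    gnorm = np.sqrt(gx * gx + gy * gy + gz * gz)
    del gx, gy, gz
    phin = phi_on_grid / np.maximum(gnorm, 0.2)
    del gnorm
    w = spacing
    ramp1 = np.clip(phin / w + 0.5, 0.0, 1.0)
    ramp2 = np.clip((phin - params.shell_thickness) / w + 0.5, 0.0, 1.0)
    return (
        params.intensity_soft
        + (params.intensity_bone - params.intensity_soft) * ramp1
        + (params.intensity_air - params.intensity_bone) * ramp2
    )


def generate_phantom_pair(
    params: PhantomParams, compute_match_truth: bool = True
) -> tuple[VolumeImage, VolumeImage, PhantomTruth]:
    """Generate the (T1, T2) volume pair and its ground truth.

    Deterministic for a given ``params.seed``: the RNG draws, in fixed
    order, the per-subject cavity-size jitter, the palatal expansion, the
    T1 noise field and the T2 noise field.  ``compute_match_truth=False``
    skips the (comparatively expensive) within-tolerance surface-fraction
    oracle for runs that only use the volumetric truth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    cv = params.cavity_volume_cv
    jitter = 1.0 + cv * float(np.clip(rng.standard_normal(), -2.5, 2.5)) if cv > 0 else 1.0
    expansion = params.palatal_expansion + params.palatal_expansion_sd * float(rng.standard_normal())

    geom = _build_geometry(params, jitter=jitter)
    _apply_texture(geom, params, rng)
    amax_pos = float(np.clip(geom.bump_amplitudes, 0, None).max()) if len(geom.bump_amplitudes) else 0.0
    amax_pos += params.texture_amplitude
    max_rho_bound = max(geom.sx, geom.sz) * geom.aperture_radius + amax_pos

    h = params.voxel_spacing
    shape = params.grid_shape or _auto_grid(params, max_rho_bound, geom.y_front)
    extent = np.array(shape) * h
    # exact lateral fit check: sample the actual deformed wall radius
    probe_y = np.linspace(geom.ya0 + 0.02 * geom.length, geom.y_front - 0.05, 48)
    max_rho = float(_radial_surface(geom, "T2", probe_y,
                                    np.linspace(0, 2 * np.pi, 64, endpoint=False)).max())
    if max_rho + 1.0 > min(extent[0], extent[2]) / 2.0:
        raise GridTooSmall("cavity (plus bumps) does not fit the grid laterally")
    if geom.y_front + 1.5 > extent[1]:
        raise GridTooSmall("cavity does not fit the grid axially")

    origin = np.array([-extent[0] / 2.0 + h / 2.0, 0.0, -extent[2] / 2.0 + h / 2.0])
    # float32 grids: keeps the (large) implicit-field evaluation fast; the
    # truth quadratures below stay in float64
    xs = (origin[0] + h * np.arange(shape[0])).astype(np.float32)
    ys = (origin[1] + h * np.arange(shape[1])).astype(np.float32)
    zs = (origin[2] + h * np.arange(shape[2])).astype(np.float32)

    # T1: implicit sampled on the grid directly (T1 carries no bumps)
    phi1 = geom.phi_t1(xs[:, None, None], ys[None, :, None], zs[None, None, :])
    vox1 = _intensity_volume(params, phi1, h)
    del phi1
    if params.noise_sd > 0:
        vox1 = vox1 + rng.normal(0.0, params.noise_sd, size=vox1.shape)
    vol1 = VolumeImage(vox1.astype(np.float32), np.full(3, h), origin)

    # T2: deformed anatomy carried through the rigid offset; the grid is
    # sampled at the inverse-mapped world coordinates (no resampling step)
    rigid = params.rigid_offset()
    if np.allclose(rigid.matrix, np.eye(4)):
        # identity offset: sample on the grid directly so a bump-free,
        # noise-free pair is bit-identical to T1
        phi2 = geom.phi_t2(xs[:, None, None], ys[None, :, None], zs[None, None, :])
        vox2 = _intensity_volume(params, phi2, h)
        del phi2
        if params.noise_sd > 0:
            vox2 = vox2 + rng.normal(0.0, params.noise_sd, size=vox2.shape)
        vol2 = VolumeImage(vox2.astype(np.float32), np.full(3, h), origin)
        return _finalise_pair(params, geom, rng, vol1, vol2, rigid, expansion,
                              compute_match_truth)
    inv = rigid.inverse()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    qx = inv.rotation[0, 0] * gx + inv.rotation[0, 1] * gy + inv.rotation[0, 2] * gz + inv.translation[0]
    qy = inv.rotation[1, 0] * gx + inv.rotation[1, 1] * gy + inv.rotation[1, 2] * gz + inv.translation[1]
    qz = inv.rotation[2, 0] * gx + inv.rotation[2, 1] * gy + inv.rotation[2, 2] * gz + inv.translation[2]
    del gx, gy, gz
    phi2 = geom.phi_t2(qx, qy, qz)
    del qx, qy, qz
    vox2 = _intensity_volume(params, phi2, h)
    del phi2
    if params.noise_sd > 0:
        vox2 = vox2 + rng.normal(0.0, params.noise_sd, size=vox2.shape)
    vol2 = VolumeImage(vox2.astype(np.float32), np.full(3, h), origin)
    return _finalise_pair(params, geom, rng, vol1, vol2, rigid, expansion,
                          compute_match_truth)


def _finalise_pair(params, geom, rng, vol1, vol2, rigid, expansion,
                   compute_match_truth) -> tuple[VolumeImage, VolumeImage, PhantomTruth]:
    """Assemble ground truth, landmarks and ancillary points for a pair."""
    # ground truth; the analytic slab volume only holds for a relief-free
    # wall, so textured subjects use the radial quadrature for T1 as well
    if len(geom.texture_amplitudes):
        v1 = _quadrature_cropped_volume(geom, "T1") / 1000.0
    else:
        v1 = geom.analytic_cropped_volume_t1() / 1000.0
    if np.any(geom.bump_amplitudes != 0.0):
        v2 = _quadrature_cropped_volume(geom, "T2") / 1000.0
        match = _truth_match_fractions(geom) if compute_match_truth else {}
    else:
        v2 = v1
        match = {0.20: 1.0, 0.40: 1.0}

    lms1 = _landmarks(geom)
    lms2 = {n: rigid.apply(p) for n, p in lms1.items()}
    half_w = (params.palatal_width + 0.0) / 2.0
    pal_y = geom.ya0 + 0.5 * geom.length
    pal_z = geom.cz - geom.aperture_radius - params.shell_thickness - 1.0
    pal1 = np.array([[geom.cx - half_w, pal_y, pal_z], [geom.cx + half_w, pal_y, pal_z]])
    pal2_material = pal1 + np.array([[-expansion / 2.0, 0, 0], [expansion / 2.0, 0, 0]])
    pal2 = rigid.apply(pal2_material)
    seed_pt = np.array([geom.cx, 0.5 * (geom.y_post + geom.y_ant), geom.cz])

    truth = PhantomTruth(
        true_volume_t1=v1,
        true_volume_t2=v2,
        true_increment=v2 - v1,
        true_match_fraction=match,
        applied_rigid=rigid,
        landmarks_t1=lms1,
        landmarks_t2=lms2,
        palatal_t1=pal1,
        palatal_t2=pal2,
        seed_point_t1=seed_pt,
        seed_point_t2=rigid.apply(seed_pt),
        geometry=geom,
    )
    return vol1, vol2, truth


# ---------------------------------------------------------------------------
# calibration

_CALIBRATION_TEXTURE_SEED0 = 900001


def _calibration_geometries(params: PhantomParams, n_draws: int) -> list[OrbitGeometry]:
    """Mean-size geometries with representative wall-relief draws.

    Calibration targets are population means, and the wall relief
    interacts with the deformation (it changes local wall area and
    curvature), so calibration truth is averaged over several fixed
    relief realisations; more draws tighten the mean at linear cost.
    """
    geoms = []
    if params.texture_amplitude > 0 and params.n_texture > 0:
        for s in range(_CALIBRATION_TEXTURE_SEED0, _CALIBRATION_TEXTURE_SEED0 + n_draws):
            geom = _build_geometry(params, jitter=1.0)
            _apply_texture(geom, params, np.random.default_rng(s))
            geoms.append(geom)
    else:
        geoms.append(_build_geometry(params, jitter=1.0))
    return geoms


def _truth_increment_for(params: PhantomParams, amplitudes: np.ndarray,
                         n_draws: int = 12) -> float:
    p = dataclasses.replace(params, bump_amplitudes=tuple(amplitudes))
    vals = []
    for geom in _calibration_geometries(p, n_draws):
        v1 = _quadrature_cropped_volume(geom, "T1")
        v2 = _quadrature_cropped_volume(geom, "T2")
        vals.append((v2 - v1) / 1000.0)
    return float(np.mean(vals))


def _truth_match_for(
    params: PhantomParams, amplitudes: np.ndarray, tol: float,
    cache: dict | None = None, n_draws: int = 8,
) -> float:
    """Calibration-time truth; the T1 reference surfaces are bump-free and
    can be cached across amplitude/extent iterations."""
    p = dataclasses.replace(params, bump_amplitudes=tuple(amplitudes))
    geoms = _calibration_geometries(p, n_draws)
    if cache is not None and "refs" not in cache:
        cache["refs"] = [_t1_cropped_reference_surface(g) for g in geoms]
    refs = cache["refs"] if cache is not None else [None] * len(geoms)
    vals = [
        _truth_match_fractions(geom, tolerances=(tol,), reference=ref)[float(tol)]
        for geom, ref in zip(geoms, refs)
    ]
    return float(np.mean(vals))


def calibrate_bumps(
    target_increment: float | None,
    target_match_fraction: dict[float, float] | None,
    params: PhantomParams,
    rel_tol: float = 0.002,
    max_iter: int = 40,
) -> PhantomParams:
    """Scale the bump amplitudes (and, if needed, their extent) so that the
    generated ground truth hits the requested targets.

    * ``target_increment`` only: the amplitude scale is solved by secant
      iteration at fixed ``bump_sigma`` (the increment is monotone and
      nearly linear in the scale).
    * ``target_match_fraction`` only (single tolerance): amplitude scale
      solved against the fraction (monotone decreasing).
    * both: outer secant on ``bump_sigma`` for the fraction with an
      inner amplitude solve for the increment.

    Deterministic: no randomness is involved; the calibration is done at
    the mean cavity geometry (per-subject jitter averages out).
    """
    if target_increment is not None and abs(target_increment) > 5.0:
        raise CalibrationFailed("target increment outside the achievable +-5 cm^3")
    if target_match_fraction:
        for tol, f in target_match_fraction.items():
            if not (0.0 < f <= 1.0):
                raise CalibrationFailed("target fractions must be in (0, 1]")

    base = np.asarray(params.bump_amplitudes, dtype=float)
    if not np.any(base != 0.0):
        base = np.array([1.0, 0.85])[: max(2, len(base))] if len(base) != 1 else np.array([1.0])
    base = base / np.abs(base).max()

    if target_increment is not None and abs(target_increment) < 1e-12 and not target_match_fraction:
        return dataclasses.replace(params, bump_amplitudes=tuple(0.0 * base))

    def solve_amp_for_increment(p: PhantomParams) -> np.ndarray:
        flat = base.sum() * 2.0 * np.pi * p.bump_sigma**2 / 1000.0  # cm^3 per mm of scale
        s = target_increment / flat
        f0 = _truth_increment_for(p, s * base)
        s_prev, f_prev = s, f0
        s = s * target_increment / f0 if f0 != 0 else s * 2
        for _ in range(max_iter):
            f = _truth_increment_for(p, s * base)
            if abs(f - target_increment) <= rel_tol * abs(target_increment):
                return s * base
            denom = f - f_prev
            if denom == 0:
                break
            s_new = s - (f - target_increment) * (s - s_prev) / denom
            s_prev, f_prev = s, f
            s = float(np.clip(s_new, 0.05 * s, 20.0 * s))
        raise CalibrationFailed("amplitude solve for the increment did not converge")

    def solve_sigma_for_fraction(p: PhantomParams, tol: float, target: float) -> float:
        """Solve the bump extent at fixed amplitude (fraction decreases in sigma).

        Calibrating the extent rather than the amplitude keeps the wall
        displacement steep where it crosses the tolerance, which makes
        the within-tolerance fraction robust to micrometre-scale
        registration residuals downstream.
        """
        amps = np.asarray(p.bump_amplitudes, dtype=float)
        if np.abs(amps).max() <= tol:
            raise CalibrationFailed("bump amplitude must exceed the tolerance")
        cache: dict = {}
        lo, hi = 0.3, 0.6
        for _ in range(60):
            if _truth_match_for(dataclasses.replace(p, bump_sigma=hi), amps, tol,
                                cache=cache) < target:
                break
            hi *= 1.5
            if hi > 40.0:
                raise CalibrationFailed("could not bracket the match-fraction target")
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            f = _truth_match_for(dataclasses.replace(p, bump_sigma=mid), amps, tol,
                                 cache=cache)
            if abs(f - target) <= 0.002:
                return mid
            if f > target:
                lo = mid
            else:
                hi = mid
        raise CalibrationFailed("extent solve for the match fraction did not converge")

    if target_match_fraction is None:
        amps = solve_amp_for_increment(params)
        out = dataclasses.replace(params, bump_amplitudes=tuple(amps))
    elif target_increment is None:
        (tol, target), = target_match_fraction.items()
        p = params
        if not np.any(np.asarray(p.bump_amplitudes) != 0.0):
            p = dataclasses.replace(p, bump_amplitudes=tuple(base))
        sigma = solve_sigma_for_fraction(p, float(tol), float(target))
        out = dataclasses.replace(p, bump_sigma=float(sigma))
    else:
        (tol, target), = list(target_match_fraction.items())[:1]
        sigma = params.bump_sigma
        p = params
        amps = solve_amp_for_increment(p)
        f = _truth_match_for(p, amps, float(tol))
        sigma_prev, f_prev = sigma, f
        sigma = sigma * (1.25 if f < target else 0.8)
        ok = abs(f - target) <= 0.005
        for _ in range(max_iter):
            if ok:
                break
            p = dataclasses.replace(params, bump_sigma=float(sigma))
            amps = solve_amp_for_increment(p)
            f = _truth_match_for(p, amps, float(tol))
            if abs(f - target) <= 0.005:
                ok = True
                break
            denom = f - f_prev
            if denom == 0:
                break
            s_new = sigma - (f - target) * (sigma - sigma_prev) / denom
            sigma_prev, f_prev = sigma, f
            sigma = float(np.clip(s_new, 0.3 * sigma, 3.0 * sigma))
        if not ok:
            raise CalibrationFailed("joint sigma/amplitude calibration did not converge")
        out = dataclasses.replace(params, bump_sigma=float(sigma), bump_amplitudes=tuple(amps))

    if any(abs(a) > out.shell_thickness for a in out.bump_amplitudes):
        raise CalibrationFailed("calibrated amplitude exceeds the shell thickness")
    return out


# ---------------------------------------------------------------------------
# run-directory output

def save_phantom_pair(
    outdir: str | Path,
    vol1: VolumeImage,
    vol2: VolumeImage,
    truth: PhantomTruth,
    params: PhantomParams,
) -> Path:
    """Write volumes (NRRD), landmarks/truth (JSON) and a manifest."""
    from .cropping import write_landmarks

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(vol1, outdir / "t1.nrrd")
    write_volume(vol2, outdir / "t2.nrrd")
    (outdir / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=2))
    write_landmarks(truth.landmarks_t1, outdir / "landmarks_t1.json")
    write_landmarks(truth.landmarks_t2, outdir / "landmarks_t2.json")
    pdict = dataclasses.asdict(params)
    pdict["bump_centers"] = (
        None if params.bump_centers is None else np.asarray(params.bump_centers).tolist()
    )
    manifest = {
        "files": ["t1.nrrd", "t2.nrrd", "truth.json",
                  "landmarks_t1.json", "landmarks_t2.json"],
        "params": pdict,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return outdir
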