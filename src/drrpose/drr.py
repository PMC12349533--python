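"""Digitally reconstructed radiograph (DRR) rendering by perspective ray casting.

Each detector pixel defines a ray from the point source through the pixel
centre.  The ray is expressed in the volume frame (via the inverse of the
pose transform), intersected with the volume's bounding box, and sampled
uniformly with trilinear interpolation.  The pixel value is the step-length
weighted Riemann sum of the samples, i.e. an approximation of the line
integral of the CT intensities along the ray.

Conventions
-----------
* Volume intensities are indexed ``[i, j, k]`` along world (x, y, z); the
  world position of voxel (i, j, k) is ``origin + spacing * (i, j, k)``.
* Points outside the volume contribute 0 (air).
* Detector pixel (0, 0) is the top-left corner; pixel (r, c) sits at
  ``center + pixel_spacing * ((c - (nc-1)/2) * u_axis + (r - (nr-1)/2) * v_axis)``.
* Grayscale conversion is a per-image linear min-max map onto [0, 255].

Two numerically identical backends are provided: a vectorised numpy path
and a fused numba kernel used automatically when numba is importable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from . import _kernels
from .pose import PoseParameters, RigidTransform, pose_to_matrix

__all__ = [
    "Volume",
    "ProjectionGeometry",
    "Image2D",
    "make_default_geometry",
    "sample_trilinear",
    "render_drr",
    "render_batch",
    "to_grayscale",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Volume:
    """A 3D scalar grid (CT numbers or attenuation-like units).

    ``data[i, j, k]`` runs along world (x, y, z); ``spacing`` is mm/voxel and
    ``origin`` the world position (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        d = np.ascontiguousarray(self.data, dtype=np.float64)
        if d.ndim != 3 or min(d.shape) < 2:
            raise ValueError(f"volume must be 3D with all dimensions >= 2, got {d.shape}")
        if not np.all(np.isfinite(d)):
            raise ValueError("volume intensities must be finite")
        sp = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(sp <= 0):
            raise ValueError(f"voxel spacing must be positive, got {sp}")
        og = np.asarray(self.origin, dtype=float).reshape(3)
        for a in (d, sp, og):
            a.setflags(write=False)
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", og)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def center(self) -> np.ndarray:
        """World coordinates of the grid centre (the default rotation pivot)."""
        return self.origin + self.spacing * (np.array(self.shape) - 1) / 2.0

    @property
    def extent_max(self) -> np.ndarray:
        """World position of the last voxel along each axis."""
        return self.origin + self.spacing * (np.array(self.shape) - 1)


@dataclass(frozen=True)
class ProjectionGeometry:
    """Point-source / flat-detector projection geometry.

    ``u_axis``/``v_axis`` are the detector column/row directions (orthonormal,
    mm); ``shape`` is (rows, cols); ``pixel_spacing`` in mm; ``step`` is the
    ray sampling interval in mm.
    """

    source: np.ndarray
    detector_center: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    shape: tuple[int, int]
    pixel_spacing: float
    step: float

    def __post_init__(self) -> None:
        src = np.asarray(self.source, dtype=float).reshape(3)
        ctr = np.asarray(self.detector_center, dtype=float).reshape(3)
        u = np.asarray(self.u_axis, dtype=float).reshape(3)
        v = np.asarray(self.v_axis, dtype=float).reshape(3)
        if not (
            np.isclose(np.linalg.norm(u), 1.0, atol=1e-9)
            and np.isclose(np.linalg.norm(v), 1.0, atol=1e-9)
            and np.isclose(u @ v, 0.0, atol=1e-9)
        ):
            raise ValueError("detector axes must be orthonormal unit vectors")
        normal = np.cross(u, v)
        if abs((src - ctr) @ normal) < 1e-9:
            raise ValueError("source must not lie on the detector plane")
        shape = (int(self.shape[0]), int(self.shape[1]))
        if min(shape) < 1:
            raise ValueError(f"detector shape must be positive, got {shape}")
        if not float(self.pixel_spacing) > 0:
            raise ValueError("pixel spacing must be positive")
        if not float(self.step) > 0:
            raise ValueError("ray sampling step must be positive")
        for a in (src, ctr, u, v):
            a.setflags(write=False)
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "detector_center", ctr)
        object.__setattr__(self, "u_axis", u)
        object.__setattr__(self, "v_axis", v)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "pixel_spacing", float(self.pixel_spacing))
        object.__setattr__(self, "step", float(self.step))

    @cached_property
    def pixel_centers(self) -> np.ndarray:
        """(rows*cols, 3) world positions of all pixel centres, row-major."""
        nr, nc = self.shape
        r = np.arange(nr) - (nr - 1) / 2.0
        c = np.arange(nc) - (nc - 1) / 2.0
        rr, cc = np.meshgrid(r, c, indexing="ij")
        pts = (
            self.detector_center
            + self.pixel_spacing * cc[..., None] * self.u_axis
            + self.pixel_spacing * rr[..., None] * self.v_axis
        )
        return pts.reshape(-1, 3)

    def transformed(self, t: RigidTransform) -> "ProjectionGeometry":
        """Geometry with source/detector moved rigidly by ``t``."""
        return ProjectionGeometry(
            source=t.apply(self.source),
            detector_center=t.apply(self.detector_center),
            u_axis=t.rotation @ self.u_axis,
            v_axis=t.rotation @ self.v_axis,
            shape=self.shape,
            pixel_spacing=self.pixel_spacing,
            step=self.step,
        )


@dataclass(frozen=True)
class Image2D:
    """A 2D scalar image with isotropic pixel spacing (mm)."""

    pixels: np.ndarray
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        p = np.ascontiguousarray(self.pixels, dtype=np.float64)
        if p.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValueError("image pixels must be finite")
        p.setflags(write=False)
        object.__setattr__(self, "pixels", p)
        object.__setattr__(self, "pixel_spacing", float(self.pixel_spacing))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def make_default_geometry(
    view: str = "frontal",
    source_to_iso: float = 1000.0,
    iso_to_detector: float = 200.0,
    shape: tuple[int, int] = (256, 256),
    pixel_spacing: float = 1.0,
    step: float = 0.5,
    view_change: RigidTransform | None = None,
) -> ProjectionGeometry:
    """Build the frontal or lateral projection geometry.

    The frontal source sits on the -Z axis at ``source_to_iso`` mm from the
    isocenter (world origin), aiming along +Z; the detector plane is at
    ``iso_to_detector`` mm on +Z with columns along +X and rows along -Y.
    The lateral geometry is the frontal one moved by the *inverse* of the
    frontal-to-lateral view change (moving the camera one way is equivalent
    to rotating the volume the other), which for the default +90 degree
    rotation about Y puts the lateral source on the +X axis.
    """
    if source_to_iso <= 0 or iso_to_detector <= 0:
        raise ValueError("source-to-isocenter and isocenter-to-detector distances must be > 0")
    geom = ProjectionGeometry(
        source=np.array([0.0, 0.0, -float(source_to_iso)]),
        detector_center=np.array([0.0, 0.0, float(iso_to_detector)]),
        u_axis=np.array([1.0, 0.0, 0.0]),
        v_axis=np.array([0.0, -1.0, 0.0]),
        shape=shape,
        pixel_spacing=pixel_spacing,
        step=step,
    )
    if view == "frontal":
        return geom
    if view == "lateral":
        from .pose import default_view_change

        vc = view_change if view_change is not None else default_view_change()
        return geom.transformed(vc.inverse())
    raise ValueError(f"view must be 'frontal' or 'lateral', got {view!r}")


def sample_trilinear(volume: Volume, world_points) -> np.ndarray:
    """Trilinear interpolation of the volume at world points (mm).

    Accepts a single point (3,) or an array (..., 3).  Points outside the
    grid (beyond the outermost voxel centres) return 0.
    """
    pts = np.asarray(world_points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    c = (pts - volume.origin) / volume.spacing
    dims = np.array(volume.shape)
    inside = np.all((c >= 0.0) & (c <= dims - 1), axis=-1)
    i0 = np.clip(np.floor(c).astype(np.int64), 0, dims - 2)
    f = c - i0
    i0 = np.where(inside[..., None], i0, 0)
    f = np.where(inside[..., None], f, 0.0)
    x0, y0, z0 = i0[..., 0], i0[..., 1], i0[..., 2]
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    d = volume.data
    c00 = d[x0, y0, z0] * (1 - fx) + d[x0 + 1, y0, z0] * fx
    c10 = d[x0, y0 + 1, z0] * (1 - fx) + d[x0 + 1, y0 + 1, z0] * fx
    c01 = d[x0, y0, z0 + 1] * (1 - fx) + d[x0 + 1, y0, z0 + 1] * fx
    c11 = d[x0, y0 + 1, z0 + 1] * (1 - fx) + d[x0 + 1, y0 + 1, z0 + 1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    vals = (c0 * (1 - fz) + c1 * fz) * inside
    return vals[0] if single else vals


def _ray_volume_spans(volume: Volume, src: np.ndarray, dirs: np.ndarray, tmax: np.ndarray):
    """Entry/exit ray parameters against the volume bounding box (slab test)."""
    lo = volume.origin
    hi = volume.extent_max
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = (lo - src) / dirs
        t1 = (hi - src) / dirs
    near = np.where(dirs != 0, np.minimum(t0, t1), -np.inf)
    far = np.where(dirs != 0, np.maximum(t0, t1), np.inf)
    # parallel rays outside the slab never hit
    outside = (dirs == 0) & ((src < lo) | (src > hi))
    near = np.where(outside, np.inf, near)
    tn = np.maximum(near.max(axis=-1), 0.0)
    tf = np.minimum(far.min(axis=-1), tmax)
    return tn, tf


def _accumulate_numpy(volume: Volume, src: np.ndarray, dirs: np.ndarray, tmax: np.ndarray, step: float) -> np.ndarray:
    tn, tf = _ray_volume_spans(volume, src, dirs, tmax)
    npix = dirs.shape[0]
    counts = np.zeros(npix, dtype=np.int64)
    hit = tf > tn
    counts[hit] = ((tf[hit] - tn[hit]) / step).astype(np.int64)
    accum = np.zeros(npix)
    nmax = int(counts.max()) if npix else 0
    if nmax == 0:
        return accum
    # chunk over pixels to bound the (pixels x samples) coordinate array
    chunk = max(1, int(2_000_000 // max(nmax, 1)))
    ks = np.arange(nmax)
    for a in range(0, npix, chunk):
        b = min(a + chunk, npix)
        t = tn[a:b, None] + (ks[None, :] + 0.5) * step
        valid = ks[None, :] < counts[a:b, None]
        pts = src + t[..., None] * dirs[a:b, None, :]
        vals = sample_trilinear(volume, pts.reshape(-1, 3)).reshape(b - a, nmax)
        accum[a:b] = (vals * valid).sum(axis=1) * step
    return accum


def _render_accumulation(
    volume: Volume,
    transform: RigidTransform,
    geometry: ProjectionGeometry,
    backend: str = "auto",
) -> np.ndarray:
    """Raw line-integral accumulation image for a posed volume."""
    inv = transform.inverse()
    src = inv.apply(geometry.source)
    pix = inv.apply(geometry.pixel_centers)
    d = pix - src
    tmax = np.linalg.norm(d, axis=-1)
    if np.any(tmax == 0):
        raise ValueError("detector pixel coincides with the source")
    dirs = d / tmax[:, None]
    step = geometry.step
    use_numba = backend == "numba" or (backend == "auto" and _kernels.HAVE_NUMBA)
    if backend not in ("auto", "numba", "numpy"):
        raise ValueError(f"unknown backend {backend!r}")
    if use_numba and not _kernels.HAVE_NUMBA:
        raise RuntimeError("numba backend requested but numba is not installed")
    if use_numba:
        out = np.zeros(dirs.shape[0])
        _kernels.raycast(
            volume.data,
            volume.origin,
            volume.spacing,
            src,
            np.ascontiguousarray(dirs),
            tmax,
            step,
            out,
        )
        accum = out
    else:
        accum = _accumulate_numpy(volume, src, dirs, tmax, step)
    if not np.any(accum):
        warnings.warn("all rays missed the volume; returning an all-zero image", stacklevel=3)
    return accum.reshape(geometry.shape)


def to_grayscale(accum: np.ndarray) -> np.ndarray:
    """Linear min-max mapping of an accumulation image onto [0, 255]."""
    lo = float(accum.min())
    hi = float(accum.max())
    if hi == lo:
        return np.zeros_like(accum)
    return (accum - lo) * (255.0 / (hi - lo))


def render_drr(
    volume: Volume,
    pose: PoseParameters,
    geometry: ProjectionGeometry,
    normalize: bool = True,
    backend: str = "auto",
    transform: RigidTransform | None = None,
) -> Image2D:
    """Render one DRR of ``volume`` under ``pose`` through ``geometry``.

    With ``normalize`` the accumulation image is mapped linearly onto
    [0, 255]; without it the raw line integrals (mm-weighted intensity sums)
    are returned.  ``transform`` overrides the pose matrix directly (used for
    the lateral view, whose volume transform is view_change @ frontal).
    """
    if transform is None:
        if not isinstance(pose, PoseParameters):
            raise TypeError(f"pose must be PoseParameters, got {type(pose).__name__}")
        transform = pose_to_matrix(pose, center=volume.center)
    accum = _render_accumulation(volume, transform, geometry, backend=backend)
    pixels = to_grayscale(accum) if normalize else accum
    return Image2D(pixels=pixels, pixel_spacing=geometry.pixel_spacing)


def render_batch(
    volume: Volume,
    poses: list,
    geometry: ProjectionGeometry,
    normalize: bool = True,
    backend: str = "auto",
) -> list[Image2D]:
    """Render a batch of poses; output order matches input order.

    Each image is identical to the corresponding single :func:`render_drr`
    call.  Any invalid pose aborts the whole batch, reporting its index.
    """
    for idx, p in enumerate(poses):
        if not isinstance(p, PoseParameters):
            raise ValueError(f"invalid pose at batch index {idx}: {p!r}")
    return [render_drr(volume, p, geometry, normalize=normalize, backend=backend) for p in poses]
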