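"""Procedural CT phantom and simulated radiograph pair generation.

The default phantom emulates a short segment of spine embedded in soft
tissue: a stack of four bright cylinders (vertebral-body analogues, about
three times the soft-tissue intensity) along the patient longitudinal (Y)
axis, plus a thin posterior box standing in for the spinous processes.  The
box breaks the rotational symmetry of the cylinder stack about its long
axis; without it the rotation about Y would be unobservable in projections
and pose recovery would be ill-posed.

A fixture case packages the phantom with a known ground-truth pose and the
frontal/lateral reference radiographs rendered at that pose (8-bit grayscale
with optional additive Gaussian pixel noise), so the whole registration
pipeline can be exercised without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .drr import Image2D, ProjectionGeometry, Volume, render_drr
from .pose import PoseParameters, RigidTransform, default_view_change

__all__ = [
    "Ellipsoid",
    "Cylinder",
    "Box",
    "PhantomSpec",
    "FixtureCase",
    "default_phantom_spec",
    "generate_phantom_volume",
    "generate_fixture_case",
]


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    intensity: float

    def mask(self, x, y, z):
        c, s = self.center, self.semi_axes
        return ((x - c[0]) / s[0]) ** 2 + ((y - c[1]) / s[1]) ** 2 + ((z - c[2]) / s[2]) ** 2 <= 1.0

    def bounding_box(self):
        c = np.asarray(self.center)
        s = np.asarray(self.semi_axes)
        return c - s, c + s


@dataclass(frozen=True)
class Cylinder:
    """Circular cylinder with its axis along one world axis (0=x, 1=y, 2=z)."""

    center: tuple[float, float, float]
    radius: float
    half_length: float
    axis: int
    intensity: float

    def mask(self, x, y, z):
        coords = (x, y, z)
        ax = coords[self.axis] - self.center[self.axis]
        radial = [coords[i] - self.center[i] for i in range(3) if i != self.axis]
        return (radial[0] ** 2 + radial[1] ** 2 <= self.radius**2) & (np.abs(ax) <= self.half_length)

    def bounding_box(self):
        c = np.asarray(self.center)
        half = np.full(3, self.radius)
        half[self.axis] = self.half_length
        return c - half, c + half


@dataclass(frozen=True)
class Box:
    center: tuple[float, float, float]
    half_sizes: tuple[float, float, float]
    intensity: float

    def mask(self, x, y, z):
        c, h = self.center, self.half_sizes
        return (np.abs(x - c[0]) <= h[0]) & (np.abs(y - c[1]) <= h[1]) & (np.abs(z - c[2]) <= h[2])

    def bounding_box(self):
        c = np.asarray(self.center)
        h = np.asarray(self.half_sizes)
        return c - h, c + h


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a procedural phantom volume.

    The volume is centred on the world origin.  Primitives are rasterised in
    order (the last one wins on overlap) into a uniform soft-tissue
    background, then seeded Gaussian noise is added voxel-wise.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background: float = 100.0
    noise_sd: float = 5.0
    primitives: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 2:
            raise ValueError("phantom volume needs at least 2 voxels per axis")
        if min(self.spacing) <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        for p in self.primitives:
            if p.intensity <= self.background:
                raise ValueError(
                    f"bone primitive intensity {p.intensity} must exceed the background {self.background}"
                )

    @property
    def origin(self) -> np.ndarray:
        return -np.asarray(self.spacing) * (np.asarray(self.shape) - 1) / 2.0

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.spacing) * (np.asarray(self.shape) - 1)


def default_phantom_spec(noise_sd: float = 5.0, seed: int = 0) -> PhantomSpec:
    """Spine-like default: four vertebral cylinders plus a posterior ridge."""
    bone = 300.0
    cylinders = tuple(
        Cylinder(center=(0.0, y, 0.0), radius=12.0, half_length=7.0, axis=1, intensity=bone)
        for y in (-30.0, -10.0, 10.0, 30.0)
    )
    ridge = Box(center=(0.0, 0.0, -17.0), half_sizes=(3.0, 32.0, 5.0), intensity=bone)
    return PhantomSpec(noise_sd=noise_sd, seed=seed, primitives=cylinders + (ridge,))


def generate_phantom_volume(spec: PhantomSpec) -> Volume:
    """Rasterise the phantom described by ``spec`` into a :class:`Volume`."""
    shape = np.asarray(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    origin = spec.origin
    lo_world = origin
    hi_world = origin + spacing * (shape - 1)
    for p in spec.primitives:
        blo, bhi = p.bounding_box()
        if np.any(blo < lo_world) or np.any(bhi > hi_world):
            raise ValueError(f"primitive {p} extends outside the volume [{lo_world}, {hi_world}]")
    ax = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    data = np.full(tuple(shape), float(spec.background))
    for p in spec.primitives:
        data[p.mask(x, y, z)] = p.intensity
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    return Volume(data=data, spacing=spacing, origin=origin)


@dataclass(frozen=True)
class FixtureCase:
    """A phantom plus ground truth and its simulated reference radiographs."""

    volume: Volume
    true_pose: PoseParameters
    frontal: Image2D
    lateral: Image2D
    geometry_frontal: ProjectionGeometry
    geometry_lateral: ProjectionGeometry
    view_change: RigidTransform
    noise_sd: float
    seed: int


def _add_pixel_noise(image: Image2D, sd: float, rng) -> Image2D:
    if sd == 0:
        return image
    noisy = np.clip(image.pixels + rng.normal(0.0, sd, size=image.shape), 0.0, 255.0)
    return Image2D(pixels=noisy, pixel_spacing=image.pixel_spacing)


def generate_fixture_case(
    spec: PhantomSpec,
    true_pose: PoseParameters,
    geometry: ProjectionGeometry,
    noise_sd: float = 2.0,
    seed: int = 0,
    view_change: RigidTransform | None = None,
) -> FixtureCase:
    """Render the frontal/lateral reference pair for a known ground-truth pose.

    ``geometry`` is the frontal projection geometry; the lateral one is the
    same camera swung by the inverse of ``view_change`` (default +90 degrees
    about Y).  ``noise_sd`` is the additive Gaussian sd on the 8-bit
    grayscale, clamped to [0, 255].  With ``noise_sd = 0`` the references
    are bit-identical to direct renderer output.
    """
    vc = view_change if view_change is not None else default_view_change()
    volume = generate_phantom_volume(spec)
    geometry_lateral = geometry.transformed(vc.inverse())
    frontal = render_drr(volume, true_pose, geometry, normalize=True)
    lateral = render_drr(volume, true_pose, geometry_lateral, normalize=True)
    rng = np.random.default_rng(seed)
    # frontal noise drawn first, then lateral: a fixed interleaving order
    frontal = _add_pixel_noise(frontal, noise_sd, rng)
    lateral = _add_pixel_noise(lateral, noise_sd, rng)
    return FixtureCase(
        volume=volume,
        true_pose=true_pose,
        frontal=frontal,
        lateral=lateral,
        geometry_frontal=geometry,
        geometry_lateral=geometry_lateral,
        view_change=vc,
        noise_sd=float(noise_sd),
        seed=int(seed),
    )
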