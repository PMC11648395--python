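"""Numerical phantoms with sharp edges at controllable off-center positions.

These stand in for the physical resolution phantom and anatomy: real-valued
non-negative images on a grid with a physical field of view, built
deterministically so every test substrate is reproducible.

Coordinate convention: physical meters with the origin at the grid center
(the magnet isocenter); array index ``i`` along an axis of extent ``fov``
maps to coordinate ``-fov/2 + i*voxel_size``, so for an even matrix the
index ``n/2`` sits exactly at the isocenter.  Axes are ordered (x, y[, z]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Phantom",
    "axis_coords",
    "disk_phantom",
    "resolution_phantom",
    "two_object_phantom",
]


def axis_coords(n: int, fov: float) -> np.ndarray:
    """Voxel-center coordinates of one axis: -fov/2 + i*(fov/n), meters.

    Computed as ``(i - n//2) * voxel`` so mirrored indices carry exactly
    mirrored coordinates (keeps centered objects bit-symmetric).
    """
    vox = fov / n
    return vox * (np.arange(n) - n // 2)


@dataclass(frozen=True)
class Phantom:
    """Real non-negative image with physical geometry."""

    values: np.ndarray
    fov: float
    object_centroid: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("phantom values must be non-negative")
        if self.object_centroid is not None:
            c = np.asarray(self.object_centroid, dtype=float)
            if np.any(np.abs(c) > self.fov / 2):
                raise ValueError("object centroid lies outside the FOV")
            object.__setattr__(self, "object_centroid", c)

    @property
    def dim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_size(self) -> float:
        return self.fov / self.values.shape[0]

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size**self.dim

    def coords(self) -> list[np.ndarray]:
        """Per-axis voxel-center coordinate arrays."""
        return [axis_coords(n, self.fov) for n in self.shape]

    def meshgrid(self) -> list[np.ndarray]:
        return np.meshgrid(*self.coords(), indexing="ij")

    def mass(self) -> float:
        return float(self.values.sum())


def _radius_grid(shape, fov, center, supersample: int = 1):
    """Distance-to-center grid, optionally on a supersampled lattice."""
    center = np.asarray(center, dtype=float)
    axes = []
    for ax, n in enumerate(shape):
        vox = fov / n
        if supersample == 1:
            c = axis_coords(n, fov)
        else:
            # supersample voxel centers symmetrically inside each voxel
            base = axis_coords(n, fov)
            offs = (np.arange(supersample) + 0.5) / supersample - 0.5
            c = (base[:, None] + offs[None, :] * vox).ravel()
        axes.append(c - center[ax])
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum(m * m for m in mesh))


def _check_inside(fov: float, center, radius: float) -> None:
    center = np.asarray(center, dtype=float)
    if np.any(np.abs(center) + radius > fov / 2.0):
        raise ValueError(
            "object crosses the FOV boundary (wrap-around would corrupt "
            f"projections): center={center.tolist()}, radius={radius}, fov={fov}"
        )


def disk_phantom(
    shape,
    fov: float,
    radius: float,
    center=(0.0, 0.0),
    amplitude: float = 1.0,
    antialias: bool = False,
) -> Phantom:
    """Uniform disk (2D) or ball (3D) of the given physical radius.

    Voxel-center sampling by default, so edges are ideal steps; with
    ``antialias=True`` each voxel is 2x supersampled and averaged, giving
    smoother edges for figure-quality images.
    """
    shape = tuple(int(s) for s in shape)
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    given = np.asarray(center, dtype=float).ravel()
    center = np.zeros(len(shape))
    center[: min(len(shape), given.size)] = given[: len(shape)]
    _check_inside(fov, center, radius)
    ss = 2 if antialias else 1
    r = _radius_grid(shape, fov, center, supersample=ss)
    mask = (r <= radius).astype(float)
    if ss > 1:
        newshape = []
        for n in shape:
            newshape.extend([n, ss])
        mask = mask.reshape(newshape).mean(axis=tuple(range(1, 2 * len(shape), 2)))
    return Phantom(values=amplitude * mask, fov=fov, object_centroid=center)


def resolution_phantom(shape, fov: float, center=(0.0, 0.0)) -> Phantom:
    """2D resolution pattern: a uniform disk carrying three bar groups.

    Layout (fractions of the disk radius R = 0.3*fov):
      * uniform rim between 0.75R and R giving clean circular edges;
      * three horizontal bands inside, with dark bars of pitch 8, 6 and 4
        voxels (equal bar/gap widths), providing edges of decreasing scale.

    Background voxels are exactly 0 and all edges are ideal steps.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 2:
        raise ValueError("resolution phantom is 2D")
    center = np.asarray(center, dtype=float)
    radius = 0.3 * fov
    _check_inside(fov, center, radius)
    r = _radius_grid(shape, fov, center)
    values = (r <= radius).astype(float)

    vox = fov / shape[0]
    x = axis_coords(shape[0], fov) - center[0]
    y = axis_coords(shape[1], fov) - center[1]
    inner = r <= 0.75 * radius
    band_h = 0.4 * radius
    band_centers = [-0.5 * radius, 0.0, 0.5 * radius]
    for pitch_vox, yc in zip((8, 6, 4), band_centers):
        pitch = pitch_vox * vox
        in_band = np.abs(y[None, :] - yc) <= band_h / 2.0
        bar = (np.floor((x[:, None] + fov) / pitch) % 2) == 0
        values[inner & in_band & bar] = 0.0
    return Phantom(values=values, fov=fov, object_centroid=center)


def two_object_phantom(
    shape,
    fov: float,
    r0: float,
    theta0: float = 0.0,
    radius: float | None = None,
    amplitude: float = 1.0,
    antialias: bool = False,
) -> Phantom:
    """Two identical disks: one at the isocenter, one at polar (r0, theta0).

    The off-center object is the nominal point of interest; its position is
    recorded as the phantom's ``object_centroid``.  Overlapping placements
    (including r0 = 0) are rejected.
    """
    shape = tuple(int(s) for s in shape)
    if radius is None:
        radius = fov / 12.0
    if r0 <= 2.0 * radius:
        raise ValueError(
            f"objects overlap: need r0 > 2*radius, got r0={r0}, radius={radius}"
        )
    offc = np.array([r0 * math.cos(theta0), r0 * math.sin(theta0)])[: len(shape)]
    if len(shape) == 3:
        offc = np.append(offc, 0.0)
    zero = np.zeros(len(shape))
    a = disk_phantom(shape, fov, radius, zero, amplitude, antialias)
    b = disk_phantom(shape, fov, radius, offc, amplitude, antialias)
    return Phantom(values=a.values + b.values, fov=fov, object_centroid=offc)
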