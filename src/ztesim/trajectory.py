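"""ZTE sampling pattern: radial spokes plus a single-point-imaging core.

The ZTE sequence keeps the readout gradient magnitude constant and only
rotates its direction between repetitions, producing center-out radial spokes.
Because acquisition can only start a dead time after excitation, the sphere
|k| < gamma_bar * G * t_dead at the k-space center is never reached by the
spokes; it is filled by single point imaging (SPI), which acquires one
Cartesian k-space point per excitation at a fixed encoding time TE with
gradient G = k / (gamma_bar * TE).

k-space is measured in cycles/meter throughout (image-domain Fourier kernel
``exp(-i 2 pi k . r)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .physics import DEFAULT_CONSTANTS, PhysicsConstants

__all__ = [
    "Spoke",
    "SPIGrid",
    "Trajectory",
    "GOLDEN_ANGLE",
    "radial_directions",
    "spoke_sampling",
    "spi_grid",
    "undersample",
    "make_trajectory",
]

#: 2*pi*(1 - 1/golden ratio), the azimuthal increment of the phyllotaxis ordering.
GOLDEN_ANGLE = 2.0 * math.pi * (1.0 - 2.0 / (1.0 + math.sqrt(5.0)))


@dataclass(frozen=True)
class Spoke:
    """One radial readout: a unit direction and the sampled radii (cycles/m)."""

    direction: np.ndarray
    g_mag: float
    sample_k: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))
        object.__setattr__(self, "sample_k", np.asarray(self.sample_k, dtype=float))
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-12:
            raise ValueError("spoke direction must be a unit vector")
        if self.sample_k.size and np.any(np.diff(self.sample_k) <= 0):
            raise ValueError("sample_k must be strictly increasing")

    @property
    def theta(self) -> float:
        """Azimuth of the spoke direction, radians."""
        return math.atan2(self.direction[1], self.direction[0])

    @property
    def phi(self) -> float:
        """Polar angle from +z (pi/2 for 2D spokes), radians."""
        if self.direction.size < 3:
            return math.pi / 2
        return math.acos(max(-1.0, min(1.0, float(self.direction[2]))))

    @property
    def positions(self) -> np.ndarray:
        """Sample k-vectors, shape (n_samples, dim)."""
        return self.sample_k[:, None] * self.direction[None, :]

    @property
    def gradient(self) -> np.ndarray:
        return self.g_mag * self.direction


@dataclass(frozen=True)
class SPIGrid:
    """Cartesian SPI points filling the dead-time gap at the k-space center."""

    points: np.ndarray  # (n, dim), cycles/m
    te: float
    delta_k: float
    k_gap: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))
        if self.te <= 0:
            raise ValueError(f"SPI encoding time must be positive, got {self.te}")

    def gradients(self, constants: PhysicsConstants = DEFAULT_CONSTANTS) -> np.ndarray:
        """Per-point encoding gradient G = k / (gamma_bar * TE), T/m."""
        return self.points / (constants.gamma_bar * self.te)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class Trajectory:
    """Ordered radial spokes plus the SPI core; acquisition order = list order."""

    spokes: tuple
    spi: SPIGrid
    dead_time: float
    dwell: float
    fov: float
    dim: int

    @property
    def g_mag(self) -> float:
        return self.spokes[0].g_mag if self.spokes else 0.0

    @property
    def k_max(self) -> float:
        return max(float(s.sample_k[-1]) for s in self.spokes)

    @property
    def k_start(self) -> float:
        return float(self.spokes[0].sample_k[0]) if self.spokes else 0.0

    @property
    def dk_radial(self) -> float:
        ks = self.spokes[0].sample_k
        return float(ks[1] - ks[0]) if ks.size > 1 else self.spi.delta_k

    @property
    def n_samples(self) -> int:
        return sum(s.sample_k.size for s in self.spokes) + len(self.spi)


def radial_directions(n_spokes: int, dim: int = 3, full_circle: bool = False) -> np.ndarray:
    """Unit spoke directions in acquisition order, shape (n_spokes, dim).

    3D uses a spiral-phyllotaxis ordering covering the full sphere: spoke i
    at height ``z_i = 1 - 2(i+0.5)/n`` with azimuth ``i * golden angle``,
    which is near-uniform for any count.  2D uses uniform azimuths over the
    half circle ``theta_i = i*pi/n`` (conjugate symmetry covers the rest) or,
    with ``full_circle=True``, over the whole circle ``theta_i = i*2*pi/n``.
    """
    if n_spokes < 1:
        raise ValueError(f"need at least one spoke, got {n_spokes}")
    if dim == 2:
        span = 2.0 * math.pi if full_circle else math.pi
        theta = span * np.arange(n_spokes) / n_spokes
        return np.stack([np.cos(theta), np.sin(theta)], axis=1)
    if dim == 3:
        i = np.arange(n_spokes)
        z = 1.0 - 2.0 * (i + 0.5) / n_spokes
        rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
        az = i * GOLDEN_ANGLE
        return np.stack([rho * np.cos(az), rho * np.sin(az), z], axis=1)
    raise ValueError(f"dim must be 2 or 3, got {dim}")


def spoke_sampling(
    direction: np.ndarray,
    g_mag: float,
    dead_time: float,
    dwell: float,
    k_max: float,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> Spoke:
    """Sample radii of one spoke: ``k_j = gamma_bar*G*(dead_time + j*dwell)``.

    The time origin sits at the pulse's effective center; sampling stops at
    the first radius exceeding ``k_max`` (exclusive).
    """
    if g_mag <= 0:
        raise ValueError(f"radial g_mag must be positive, got {g_mag}")
    if dead_time < 0 or dwell <= 0:
        raise ValueError("dead_time must be >= 0 and dwell > 0")
    slope = constants.gamma_bar * g_mag
    k_start = slope * dead_time
    if k_start > k_max:
        raise ValueError(
            f"dead-time gap k_start={k_start:.3g} exceeds k_max={k_max:.3g}"
        )
    n = int(math.floor((k_max - k_start) / (slope * dwell) + 1e-9)) + 1
    k = k_start + slope * dwell * np.arange(n)
    return Spoke(direction=np.asarray(direction, float), g_mag=g_mag, sample_k=k)


def spi_grid(
    k_gap: float,
    delta_k: float,
    te: float,
    dim: int = 3,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> SPIGrid:
    """Cartesian lattice of SPI points with |k| <= k_gap at spacing delta_k.

    Each point is acquired at encoding time ``te`` with gradient
    ``G = k/(gamma_bar*te)``, so weak gradients encode the central points.
    ``k_gap = 0`` degenerates to the single DC point.
    """
    if k_gap < 0 or delta_k <= 0:
        raise ValueError("k_gap must be >= 0 and delta_k > 0")
    if te <= 0:
        raise ValueError(f"SPI encoding time must be positive, got {te}")
    if dim not in (2, 3):
        raise ValueError(f"dim must be 2 or 3, got {dim}")
    m = int(math.floor(k_gap / delta_k + 1e-9))
    axes = [delta_k * np.arange(-m, m + 1)] * dim
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([c.ravel() for c in mesh], axis=1)
    keep = np.linalg.norm(pts, axis=1) <= k_gap * (1 + 1e-12)
    return SPIGrid(points=pts[keep], te=te, delta_k=delta_k, k_gap=k_gap)


def undersample(spokes, acceleration: float):
    """Retain every ceil(acceleration)-th spoke in acquisition order.

    Azimuthal undersampling used to shorten the scan; acceleration 1 is the
    identity.
    """
    if acceleration < 1:
        raise ValueError(f"acceleration must be >= 1, got {acceleration}")
    stride = int(math.ceil(acceleration - 1e-12))
    return list(spokes)[::stride]


def make_trajectory(
    n_spokes: int,
    g_mag: float,
    fov: float,
    matrix: int,
    dead_time: float = 50e-6,
    dwell: float | None = None,
    te: float | None = None,
    dim: int = 2,
    full_circle: bool = True,
    acceleration: float = 1.0,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> Trajectory:
    """Assemble a full ZTE trajectory for an isotropic FOV.

    ``matrix`` sets the Nyquist extent ``k_max = matrix/(2*fov)``; the SPI
    core spacing is ``1/fov``; ``dwell`` defaults to the value that makes the
    radial step equal the Cartesian cell, and the SPI encoding time ``te``
    defaults to the dead time (the sequence's TE).
    """
    k_max = matrix / (2.0 * fov)
    delta_k = 1.0 / fov
    if dwell is None:
        dwell = delta_k / (constants.gamma_bar * g_mag)
    if te is None:
        te = dead_time if dead_time > 0 else 50e-6
    k_gap = constants.gamma_bar * g_mag * dead_time
    dirs = radial_directions(n_spokes, dim=dim, full_circle=full_circle)
    spokes = [
        spoke_sampling(d, g_mag, dead_time, dwell, k_max, constants) for d in dirs
    ]
    if acceleration > 1:
        spokes = undersample(spokes, acceleration)
    spi = spi_grid(k_gap, delta_k, te, dim=dim, constants=constants)
    return Trajectory(
        spokes=tuple(spokes),
        spi=spi,
        dead_time=dead_time,
        dwell=dwell,
        fov=fov,
        dim=dim,
    )
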