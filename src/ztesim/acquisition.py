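"""Forward simulation of ZTE k-space data under the three excitation schemes.

Each shot first weights the phantom by the (real) excitation profile of the
hard pulse for that shot's gradient and carrier offset, then evaluates the
discrete Fourier sum of the weighted image at the shot's k-space positions:

    s(k) = sum_r w(r) * phantom(r) * exp(-i 2 pi k . r) * voxel_volume

The direct sum (not an interpolating NUFFT) is the forward-model contract, so
simulation errors never hide behind gridding interpolation.  For radial
spokes the sum is separable along the spoke direction, which keeps the
evaluation cheap at the grid sizes used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import Phantom
from .physics import (
    DEFAULT_CONSTANTS,
    ExcitationScheme,
    PhysicsConstants,
    PulseParams,
)
from .trajectory import SPIGrid, Trajectory

__all__ = ["KSpaceData", "simulate_shot", "simulate_spi", "simulate_acquisition", "sinogram"]


@dataclass
class KSpaceData:
    """Simulated (or loaded) non-Cartesian k-space samples plus the metadata
    the reconstruction needs: sampling geometry, per-shot carrier offsets and
    the excitation-scheme tag."""

    positions: np.ndarray  # (n, dim), cycles/m
    values: np.ndarray  # (n,), complex
    shot_id: np.ndarray  # (n,), int
    delta_f_per_shot: np.ndarray  # (n_shots,), Hz
    scheme_mode: str
    fov: float
    dim: int
    is_spi: np.ndarray | None = None  # (n,), bool
    k_gap: float = 0.0
    delta_k: float = 0.0
    dk_radial: float = 0.0
    n_radial_spokes: int = 0
    noise_seed: int | None = None
    schema_version: str = "ztesim-kspace-1"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        self.shot_id = np.asarray(self.shot_id, dtype=np.int64)
        self.delta_f_per_shot = np.asarray(self.delta_f_per_shot, dtype=float)
        if self.is_spi is None:
            self.is_spi = np.zeros(self.values.shape, dtype=bool)
        else:
            self.is_spi = np.asarray(self.is_spi, dtype=bool)
        n = self.positions.shape[0]
        if not (self.values.shape[0] == n and self.shot_id.shape[0] == n):
            raise ValueError("positions, values and shot_id must have equal length")

    @property
    def k_max(self) -> float:
        return float(np.linalg.norm(self.positions, axis=1).max())

    def __len__(self) -> int:
        return self.values.shape[0]


def _weighted_image(
    phantom: Phantom,
    gradient: np.ndarray,
    scheme: ExcitationScheme,
    pulse: PulseParams,
    constants: PhysicsConstants,
):
    """Profile-weighted image and its projection coordinate along the gradient.

    Returns (wimg, proj, delta_f) with proj = unit(G) . r per voxel, or
    proj=None when the gradient is zero.
    """
    g = np.asarray(gradient, dtype=float)
    g_mag = float(np.linalg.norm(g))
    mesh = phantom.meshgrid()
    if g_mag == 0.0:
        return phantom.values, None, 0.0
    d = g / g_mag
    proj = sum(d[a] * mesh[a] for a in range(phantom.dim))
    if scheme.mode == "ideal":
        return phantom.values, proj, 0.0
    delta_f = scheme.delta_f(g, constants)
    w = np.sinc(pulse.duration_tau * (constants.gamma_bar * g_mag * proj - delta_f))
    return w * phantom.values, proj, delta_f


def simulate_shot(
    phantom: Phantom,
    gradient,
    sample_k: np.ndarray,
    scheme: ExcitationScheme,
    pulse: PulseParams,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Complex samples of one radial shot at radii ``sample_k`` along the
    gradient direction.

    The excitation profile for this shot (scheme-dependent carrier offset)
    multiplies the phantom in image space before the Fourier sum; the ideal
    scheme bypasses the profile.
    """
    g = np.asarray(gradient, dtype=float)
    if np.linalg.norm(g) == 0.0:
        raise ValueError("radial shots require a nonzero gradient")
    wimg, proj, _ = _weighted_image(phantom, g, scheme, pulse, constants)
    k = np.asarray(sample_k, dtype=float)
    phase = np.exp(-2j * np.pi * np.outer(k, proj.ravel()))
    return (phase @ wimg.ravel()) * phantom.voxel_volume


def simulate_spi(
    phantom: Phantom,
    spi: SPIGrid,
    scheme: ExcitationScheme,
    pulse: PulseParams,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Complex samples of the SPI core, one excitation per Cartesian point.

    Each point's encoding gradient ``G = k/(gamma_bar*TE)`` is much weaker
    than the radial gradient, so its excitation profile is much wider; the
    carrier offset under OffEx is recomputed per point from that gradient.
    """
    grads = spi.gradients(constants)
    mesh = phantom.meshgrid()
    flat = [m.ravel() for m in mesh]
    img = phantom.values.ravel()
    out = np.empty(len(spi), dtype=complex)
    for i in range(len(spi)):
        wimg, proj, _ = _weighted_image(phantom, grads[i], scheme, pulse, constants)
        kr = sum(spi.points[i, a] * flat[a] for a in range(phantom.dim))
        out[i] = np.exp(-2j * np.pi * kr) @ wimg.ravel() * phantom.voxel_volume
    return out


def simulate_acquisition(
    phantom: Phantom,
    traj: Trajectory,
    scheme: ExcitationScheme,
    pulse: PulseParams,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> KSpaceData:
    """Simulate the full acquisition: all radial spokes, then the SPI core.

    Optional additive complex white Gaussian noise (per-component standard
    deviation ``noise_sigma``) is reproducible from ``seed``.
    """
    if phantom.dim != traj.dim:
        raise ValueError(
            f"phantom dim {phantom.dim} does not match trajectory dim {traj.dim}"
        )
    positions, values, shot_id, delta_fs, spi_flag = [], [], [], [], []
    shot = 0
    for spoke in traj.spokes:
        g = spoke.gradient
        vals = simulate_shot(phantom, g, spoke.sample_k, scheme, pulse, constants)
        positions.append(spoke.positions)
        values.append(vals)
        shot_id.append(np.full(vals.size, shot))
        spi_flag.append(np.zeros(vals.size, dtype=bool))
        delta_fs.append(scheme.delta_f(g, constants) if scheme.mode != "ideal" else 0.0)
        shot += 1
    spi_vals = simulate_spi(phantom, traj.spi, scheme, pulse, constants)
    grads = traj.spi.gradients(constants)
    for i in range(len(traj.spi)):
        positions.append(traj.spi.points[i : i + 1])
        values.append(spi_vals[i : i + 1])
        shot_id.append(np.array([shot]))
        spi_flag.append(np.array([True]))
        delta_fs.append(
            scheme.delta_f(grads[i], constants) if scheme.mode != "ideal" else 0.0
        )
        shot += 1
    values = np.concatenate(values)
    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed)
        values = values + noise_sigma * (
            rng.standard_normal(values.size) + 1j * rng.standard_normal(values.size)
        )
    return KSpaceData(
        positions=np.concatenate(positions),
        values=values,
        shot_id=np.concatenate(shot_id),
        delta_f_per_shot=np.array(delta_fs),
        scheme_mode=scheme.mode,
        fov=traj.fov,
        dim=traj.dim,
        is_spi=np.concatenate(spi_flag),
        k_gap=traj.spi.k_gap,
        delta_k=traj.spi.delta_k,
        dk_radial=traj.dk_radial,
        n_radial_spokes=len(traj.spokes),
        noise_seed=seed,
    )


def sinogram(
    phantom: Phantom,
    angles: np.ndarray,
    scheme: ExcitationScheme,
    pulse: PulseParams,
    g_mag: float,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Projections of the profile-weighted 2D phantom, one row per angle.

    For each angle the gradient lies along the detector axis; the projection
    is obtained through the central-slice theorem: the full-diameter radial
    k-line of the weighted image is evaluated by direct Fourier sum and
    inverse-transformed to the detector grid (spacing = one voxel).  Antipodal
    spokes share the same profile weight (the sinc is even in ``G.r - df``),
    so a single weighted image per angle is exact.
    """
    if phantom.dim != 2:
        raise ValueError("sinogram requires a 2D phantom")
    n = phantom.shape[0]
    dk = 1.0 / phantom.fov
    k_line = dk * (np.arange(n) - n // 2)
    out = np.empty((len(angles), n))
    for row, th in enumerate(np.asarray(angles, dtype=float)):
        g = g_mag * np.array([np.cos(th), np.sin(th)])
        wimg, proj, _ = _weighted_image(phantom, g, scheme, pulse, constants)
        spectrum = (
            np.exp(-2j * np.pi * np.outer(k_line, proj.ravel())) @ wimg.ravel()
        ) * phantom.voxel_volume
        p = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(spectrum))) * n * dk
        out[row] = p.real
    return out
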