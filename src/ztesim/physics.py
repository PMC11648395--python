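"""Hard-pulse excitation physics for ZTE MRI.

In zero-echo-time (ZTE) imaging the frequency-encoding gradient is already on
while the short rectangular RF pulse is played out, so the pulse excites a
sinc-shaped spatial profile along the gradient direction instead of the whole
volume.  This module models that profile in the small-tip regime, together
with the per-shot carrier-frequency offset that re-centers the profile on an
off-center point of interest (OffEx), and the numerically-controlled-
oscillator (NCO) timing bookkeeping needed to keep RF and acquisition phase
coherent when the carrier is shifted.

Conventions
-----------
* ``gamma_bar`` is the reduced gyromagnetic ratio gamma/2pi in Hz/T, so every
  frequency in this module is an ordinary frequency in hertz.
* The spherical decomposition uses the physics convention: ``phi`` is the
  polar angle from +z, ``theta`` the azimuth from +x in the xy-plane.
* The time origin of the excitation profile sits at the pulse's effective
  amplitude center, so the small-tip profile is real; the measured pulse
  asymmetry only enters the NCO phase correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Union

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PhysicsConstants",
    "PulseParams",
    "GradientVector",
    "PointOfInterest",
    "ExcitationScheme",
    "UnboundedProfileError",
    "carrier_offset",
    "carrier_offset_spherical",
    "profile_weight",
    "first_zero_crossing",
    "profile_fwhm",
    "nco_lead_time",
    "nco_phase_correction",
]

#: Reduced gyromagnetic ratio of 1H in Hz/T.
GAMMA_BAR_1H = 42.577e6


class UnboundedProfileError(ValueError):
    """The excitation profile has no finite zero crossing (G or tau is 0)."""


@dataclass(frozen=True)
class PhysicsConstants:
    """Physical constants of the simulated spin system.

    Parameters
    ----------
    gamma_bar : float
        Reduced gyromagnetic ratio gamma/2pi in Hz/T (default: 1H).
    """

    gamma_bar: float = GAMMA_BAR_1H

    def __post_init__(self) -> None:
        if not self.gamma_bar > 0:
            raise ValueError(f"gamma_bar must be positive, got {self.gamma_bar}")


DEFAULT_CONSTANTS = PhysicsConstants()


@dataclass(frozen=True)
class PulseParams:
    """Rectangular hard-pulse parameters.

    Parameters
    ----------
    duration_tau : float
        Pulse duration in seconds.
    flip_angle_alpha : float
        Nominal flip angle in radians; must lie in (0, pi/2] (small-tip
        regime).  Only bookkeeping — the simulated profile is normalized.
    asymmetry : float
        Fraction in [0, 1] locating the pulse's effective amplitude center
        along its duration; an ideal rectangle has 0.5, amplifier ramp
        effects shift it (measured value on the scanner: 0.53).
    nco_granularity : float
        Minimum spacing of NCO frequency/phase events in seconds.
    """

    duration_tau: float = 8e-6
    flip_angle_alpha: float = math.radians(3.0)
    asymmetry: float = 0.53
    nco_granularity: float = 20e-6

    def __post_init__(self) -> None:
        if not self.duration_tau > 0:
            raise ValueError(f"duration_tau must be positive, got {self.duration_tau}")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError(f"asymmetry must lie in [0, 1], got {self.asymmetry}")
        if not 0.0 < self.flip_angle_alpha <= math.pi / 2:
            raise ValueError(
                f"flip_angle_alpha must lie in (0, pi/2], got {self.flip_angle_alpha}"
            )
        if not self.nco_granularity > 0:
            raise ValueError(
                f"nco_granularity must be positive, got {self.nco_granularity}"
            )


@dataclass(frozen=True)
class GradientVector:
    """Readout gradient vector (T/m).  Magnitude 0 is valid (SPI center)."""

    gx: float = 0.0
    gy: float = 0.0
    gz: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.gx, self.gy, self.gz])):
            raise ValueError("gradient components must be finite")

    def as_array(self, dim: int = 3) -> np.ndarray:
        return np.array([self.gx, self.gy, self.gz][:dim], dtype=float)

    @property
    def magnitude(self) -> float:
        return float(math.hypot(self.gx, math.hypot(self.gy, self.gz)))

    @classmethod
    def from_array(cls, g) -> "GradientVector":
        g = np.asarray(g, dtype=float)
        comps = np.zeros(3)
        comps[: g.size] = g
        return cls(*comps)


@dataclass(frozen=True)
class PointOfInterest:
    """Off-center target position r0 = (x0, y0, z0) in meters.

    The spherical coordinates (``r0``, azimuth ``theta0``, polar ``phi0``)
    are derived and round-trip with the Cartesian fields.
    """

    x0: float = 0.0
    y0: float = 0.0
    z0: float = 0.0

    def as_array(self, dim: int = 3) -> np.ndarray:
        return np.array([self.x0, self.y0, self.z0][:dim], dtype=float)

    @property
    def r0(self) -> float:
        return float(np.linalg.norm(self.as_array()))

    @property
    def theta0(self) -> float:
        """Azimuth from +x in the xy-plane, radians."""
        return math.atan2(self.y0, self.x0)

    @property
    def phi0(self) -> float:
        """Polar angle from +z, radians (0 for the origin)."""
        r = self.r0
        if r == 0.0:
            return 0.0
        return math.acos(max(-1.0, min(1.0, self.z0 / r)))

    @classmethod
    def from_spherical(cls, r0: float, theta0: float, phi0: float) -> "PointOfInterest":
        return cls(
            x0=r0 * math.sin(phi0) * math.cos(theta0),
            y0=r0 * math.sin(phi0) * math.sin(theta0),
            z0=r0 * math.cos(phi0),
        )

    @classmethod
    def from_array(cls, r) -> "PointOfInterest":
        r = np.asarray(r, dtype=float)
        comps = np.zeros(3)
        comps[: r.size] = r
        return cls(*comps)


@dataclass(frozen=True)
class ExcitationScheme:
    """Excitation scheme: ideal, isocenter (IsoEx), or off-center (OffEx).

    ``ideal`` bypasses the profile entirely (weight 1 everywhere),
    ``isocenter`` keeps the carrier fixed (delta_f = 0 every shot), and
    ``offcenter`` recomputes delta_f = gamma_bar * G . r0 for every shot so
    the profile maximum tracks the point of interest ``poi``.
    """

    mode: str = "isocenter"
    poi: PointOfInterest | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("ideal", "isocenter", "offcenter"):
            raise ValueError(f"unknown excitation mode {self.mode!r}")
        if self.mode == "offcenter" and self.poi is None:
            raise ValueError("offcenter scheme requires a point of interest")

    @classmethod
    def ideal(cls) -> "ExcitationScheme":
        return cls(mode="ideal")

    @classmethod
    def isocenter(cls) -> "ExcitationScheme":
        return cls(mode="isocenter")

    @classmethod
    def offcenter(cls, poi) -> "ExcitationScheme":
        if not isinstance(poi, PointOfInterest):
            poi = PointOfInterest.from_array(poi)
        return cls(mode="offcenter", poi=poi)

    def delta_f(
        self, g: Union[GradientVector, np.ndarray], constants: PhysicsConstants = DEFAULT_CONSTANTS
    ) -> float:
        """Per-shot carrier offset in Hz for gradient ``g``."""
        if self.mode == "offcenter":
            return carrier_offset(g, self.poi, constants)
        return 0.0


def _gradient_array(g, dim: int | None = None) -> np.ndarray:
    if isinstance(g, GradientVector):
        arr = g.as_array()
    else:
        arr = np.asarray(g, dtype=float)
    if dim is not None:
        out = np.zeros(dim)
        n = min(dim, arr.size)
        out[:n] = arr[:n]
        return out
    return arr


def carrier_offset(
    g: Union[GradientVector, np.ndarray],
    poi: Union[PointOfInterest, np.ndarray],
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> float:
    """Carrier-frequency offset delta_f = gamma_bar * (G . r0) in hertz.

    Shifting the RF carrier by this amount moves the center of the sinc
    excitation profile from the isocenter to ``poi`` for the shot whose
    readout gradient is ``g``.  Linear in each argument; zero gradient or
    zero offset give 0 Hz.
    """
    garr = _gradient_array(g)
    parr = poi.as_array() if isinstance(poi, PointOfInterest) else np.asarray(poi, float)
    n = min(garr.size, parr.size)
    return float(constants.gamma_bar * np.dot(garr[:n], parr[:n]))


def carrier_offset_spherical(
    g_mag: float,
    r0: float,
    theta: float,
    phi: float,
    theta0: float,
    phi0: float,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> float:
    """Spherical-coordinate form of :func:`carrier_offset`.

    ``(theta, phi)`` are the azimuth/polar angles of the gradient direction,
    ``(r0, theta0, phi0)`` the spherical position of the point of interest:

        delta_f = gamma_bar * G * r0 * (cos(theta - theta0) sin(phi) sin(phi0)
                                        + cos(phi) cos(phi0))
    """
    if g_mag < 0 or r0 < 0:
        raise ValueError("g_mag and r0 must be non-negative")
    cosang = math.cos(theta - theta0) * math.sin(phi) * math.sin(phi0) + math.cos(
        phi
    ) * math.cos(phi0)
    return float(constants.gamma_bar * g_mag * r0 * cosang)


def profile_weight(
    position: np.ndarray,
    g: Union[GradientVector, np.ndarray],
    pulse: PulseParams,
    delta_f: float = 0.0,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Small-tip excitation-profile weight at ``position``.

    The profile of a rectangular pulse of duration tau played in gradient G
    with carrier offset delta_f is the normalized sinc

        w(r) = nsinc( tau * (gamma_bar * (G . r) - delta_f) ),

    with ``nsinc(x) = sin(pi x)/(pi x)`` and ``nsinc(0) = 1``; side lobes are
    negative.  The weight is exactly 1 where the local resonance offset
    matches the carrier, i.e. at the profile center.

    ``position`` may be a single vector or an array of shape (..., d); the
    returned weights broadcast accordingly.
    """
    pos = np.asarray(position, dtype=float)
    squeeze = pos.ndim == 1
    if squeeze:
        pos = pos[None, :]
    dim = pos.shape[-1]
    garr = _gradient_array(g, dim=dim)
    freq = constants.gamma_bar * (pos @ garr) - delta_f
    w = np.sinc(pulse.duration_tau * freq)
    return float(w[0]) if squeeze else w


def first_zero_crossing(
    g_mag: float,
    pulse: PulseParams,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> float:
    """Radius of the first zero of the sinc profile: 1/(gamma_bar * G * tau).

    Raises
    ------
    UnboundedProfileError
        If ``g_mag`` or the pulse duration is zero: the profile is flat and
        has no finite zero crossing.
    """
    if g_mag < 0:
        raise ValueError(f"g_mag must be non-negative, got {g_mag}")
    if g_mag == 0 or pulse.duration_tau == 0:
        raise UnboundedProfileError("zero gradient or pulse duration: profile is flat")
    return 1.0 / (constants.gamma_bar * g_mag * pulse.duration_tau)


@lru_cache(maxsize=1)
def _sinc_half_maximum_arg() -> float:
    """Positive root of sin(pi x)/(pi x) = 1/2, found by bracketed bisection."""
    return float(brentq(lambda x: np.sinc(x) - 0.5, 0.3, 0.99, xtol=1e-12))


def profile_fwhm(
    g_mag: float,
    pulse: PulseParams,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> float:
    """Full width at half maximum of the main lobe of |profile| in meters.

    Equals ``2 * x_half / (gamma_bar * G * tau)`` with x_half ~ 0.6034 the
    positive solution of nsinc(x) = 1/2 (solved numerically to <1e-9).
    """
    rzc = first_zero_crossing(g_mag, pulse, constants)
    return 2.0 * _sinc_half_maximum_arg() * rzc


def nco_lead_time(pulse: PulseParams) -> float:
    """Lead time between the NCO frequency/phase event and the pulse start.

    On scanners whose NCO raster is coarser than the pulse, the frequency
    set/reset events bracket the pulse symmetrically, each
    ``(granularity - tau)/2`` away from the pulse edges.

    Raises
    ------
    ValueError
        If the pulse is longer than the NCO event raster.
    """
    if pulse.nco_granularity < pulse.duration_tau:
        raise ValueError(
            "pulse cannot fit the NCO event raster: duration "
            f"{pulse.duration_tau} exceeds granularity {pulse.nco_granularity}"
        )
    return 0.5 * (pulse.nco_granularity - pulse.duration_tau)


def nco_phase_correction(pulse: PulseParams, delta_f: float) -> float:
    """Phase (radians) accrued between the NCO frequency set and the pulse's
    effective center: ``2 pi delta_f (lead + asymmetry * tau)``.

    Applying this correction keeps the shifted RF pulse and the acquisition
    phase coherent from shot to shot; the pulse asymmetry factor locates the
    effective amplitude center within the pulse.
    """
    lead = nco_lead_time(pulse)
    return 2.0 * math.pi * delta_f * (lead + pulse.asymmetry * pulse.duration_tau)
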