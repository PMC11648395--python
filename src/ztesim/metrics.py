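"""Image-quality metrics: sigmoid edge sharpness, difference images, ROI SNR.

Edge sharpness is the slope parameter ``s`` of a base-10 sigmoid fitted to a
line profile across an edge,

    SI(i) = c1 / (1 + 10^(s (c0 - i))) + c2,

where ``i`` indexes the samples along the profile; ``c0`` is the edge
center, ``c1`` the intensity range, ``c2`` the offset, and larger ``s``
means a sharper edge (``s`` is "per sample" in decades).  Profiles are
oriented dark-to-bright before fitting so ``s >= 0`` without sign ambiguity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

__all__ = [
    "LineProfile",
    "EdgeFit",
    "FlatProfileError",
    "fit_sigmoid",
    "extract_profile",
    "fit_segments",
    "median_sharpness",
    "abs_difference",
    "roi_snr",
    "nrmse",
]

log = logging.getLogger(__name__)


class FlatProfileError(ValueError):
    """The profile has no intensity transition: no edge to fit."""


@dataclass(frozen=True)
class LineProfile:
    """Ordered intensity samples along a line segment in an image."""

    intensities: np.ndarray
    spacing: float = 1.0
    endpoints: tuple | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.size < 8:
            raise ValueError(f"profile needs >= 8 samples, got {y.size}")
        if not np.all(np.isfinite(y)):
            raise ValueError("profile contains non-finite values")
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class EdgeFit:
    """Fitted sigmoid parameters of one edge profile."""

    c0: float
    c1: float
    c2: float
    s: float
    residual_norm: float
    converged: bool
    flipped: bool = False


def _sigmoid(i: np.ndarray, c0: float, c1: float, c2: float, s: float) -> np.ndarray:
    # exponent clipped so steep trial fits cannot overflow 10**x
    expo = np.clip(s * (c0 - i), -300.0, 300.0)
    return c1 / (1.0 + 10.0**expo) + c2


def fit_sigmoid(profile: LineProfile) -> EdgeFit:
    """Nonlinear least-squares fit of the base-10 sigmoid to a line profile.

    The profile is flipped if it falls rather than rises, so the fitted
    sharpness is non-negative (``flipped`` records the orientation; ``c0``
    refers to the oriented profile).  Initialization: ``c2 = min``,
    ``c1 = range``, ``c0`` at the half-range crossing, ``s`` from the
    10-90% transition width.  Non-convergence returns the best parameters
    with ``converged=False``; a flat profile raises :class:`FlatProfileError`.
    """
    y = profile.intensities
    rng = float(y.max() - y.min())
    if rng <= 0 or rng < 1e-12 * max(1.0, abs(float(y.max()))):
        raise FlatProfileError("no edge: profile is flat")
    n = y.size
    flipped = bool(np.mean(y[n // 2 :]) < np.mean(y[: n // 2]))
    if flipped:
        y = y[::-1]
    i = np.arange(n, dtype=float)

    c2_0 = float(y.min())
    c1_0 = rng
    half = c2_0 + 0.5 * c1_0
    above = np.nonzero(y >= half)[0]
    c0_0 = float(above[0]) if above.size else n / 2.0
    lo = np.nonzero(y >= c2_0 + 0.1 * c1_0)[0]
    hi = np.nonzero(y >= c2_0 + 0.9 * c1_0)[0]
    width = max(1.0, float(hi[0] - lo[0])) if lo.size and hi.size else 2.0
    s_0 = 1.0 / width

    def resid(p):
        return _sigmoid(i, *p) - y

    res = least_squares(
        resid,
        x0=[c0_0, c1_0, c2_0, s_0],
        method="trf",
        ftol=1e-10,
        xtol=1e-10,
        gtol=1e-10,
        max_nfev=500,
    )
    c0, c1, c2, s = res.x
    if s < 0:  # fit wandered to the mirrored solution; report magnitude
        s, c1, c2 = -s, -c1, c2 + c1
    return EdgeFit(
        c0=float(c0),
        c1=float(c1),
        c2=float(c2),
        s=float(s),
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.success),
        flipped=flipped,
    )


def extract_profile(image: np.ndarray, p0, p1) -> LineProfile:
    """Line profile between index coordinates p0 and p1 at one-voxel spacing,
    sampled by linear interpolation."""
    img = np.abs(np.asarray(image))
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    n = max(8, int(np.floor(length)) + 1)
    t = np.linspace(0.0, 1.0, n)
    coords = p0[:, None] + (p1 - p0)[:, None] * t[None, :]
    vals = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
    return LineProfile(intensities=vals, spacing=length / (n - 1), endpoints=(tuple(p0), tuple(p1)))


def fit_segments(image: np.ndarray, segments) -> list[EdgeFit]:
    """Fit every segment's profile; invalid (flat) profiles are skipped."""
    fits = []
    for p0, p1 in segments:
        try:
            fits.append(fit_sigmoid(extract_profile(image, p0, p1)))
        except FlatProfileError:
            log.warning("segment %s -> %s: flat profile, skipped", p0, p1)
    return fits


def median_sharpness(image: np.ndarray, segments) -> float:
    """Median fitted sharpness over a set of edge segments.

    Each segment (pair of index coordinates) is sampled at one-voxel spacing
    and fitted; the median is taken over valid fits with a genuine intensity
    range.  The segment count is logged for reproducibility.
    """
    if len(segments) < 1:
        raise ValueError("need at least one segment")
    fits = [f for f in fit_segments(image, segments) if f.c1 != 0]
    if not fits:
        raise ValueError("no valid edge fits among the segments")
    log.info("median_sharpness over %d segments (%d valid fits)", len(segments), len(fits))
    return float(np.median([f.s for f in fits]))


def abs_difference(image_a: np.ndarray, image_b: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Scaled voxelwise absolute difference of two magnitude images."""
    a = np.abs(np.asarray(image_a))
    b = np.abs(np.asarray(image_b))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return scale * np.abs(a - b)


def roi_snr(image: np.ndarray, signal_roi: np.ndarray, noise_roi: np.ndarray) -> float:
    """Mean magnitude over the signal ROI divided by the magnitude standard
    deviation over the noise ROI (boolean masks; artifact's convention)."""
    img = np.abs(np.asarray(image))
    sig = np.asarray(signal_roi, dtype=bool)
    noi = np.asarray(noise_roi, dtype=bool)
    if not sig.any() or not noi.any():
        raise ValueError("ROIs must be non-empty")
    if np.any(sig & noi):
        raise ValueError("signal and noise ROIs must be disjoint")
    std = float(img[noi].std())
    if std == 0.0:
        raise ValueError("noise ROI has zero standard deviation")
    return float(img[sig].mean() / std)


def nrmse(a: np.ndarray, ref: np.ndarray, mask: np.ndarray | None = None) -> float:
    """||a - ref|| / ||ref||, optionally restricted to a boolean mask."""
    a = np.asarray(a)
    ref = np.asarray(ref)
    if mask is not None:
        a, ref = a[mask], ref[mask]
    denom = float(np.linalg.norm(ref))
    if denom == 0.0:
        return float(np.linalg.norm(a))
    return float(np.linalg.norm(a - ref) / denom)
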