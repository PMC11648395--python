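"""Shared fixtures and independent oracle implementations.

The oracles here (explicit adjoint DFT, rotate-and-sum projection, lattice
enumeration) deliberately avoid the package's production code paths so they
can serve as independent references.
"""

import numpy as np
import pytest
from scipy import ndimage

from ztesim.phantom import axis_coords
from ztesim.physics import PhysicsConstants, PulseParams


@pytest.fixture
def pulse() -> PulseParams:
    return PulseParams()


@pytest.fixture
def constants() -> PhysicsConstants:
    return PhysicsConstants()


def adjoint_dft_image(positions, values, weights, n, fov, dim):
    """Explicit adjoint DFT: sum_i w_i v_i exp(+i 2 pi k_i . r) on the grid."""
    c = axis_coords(n, fov)
    mesh = np.meshgrid(*([c] * dim), indexing="ij")
    r = np.stack([m.ravel() for m in mesh], axis=1)
    img = np.exp(2j * np.pi * (r @ positions.T)) @ (weights * values)
    return img.reshape((n,) * dim)


def rotate_and_sum(values, theta, vox, order=3):
    """Brute-force projection: rotate the image so the gradient direction
    aligns with axis 0 (rotation about the k-space/image origin at index
    n/2), then integrate along axis 1."""
    n = values.shape[0]
    c = np.array([n / 2.0, n / 2.0])
    R = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    rot = ndimage.affine_transform(values, R, offset=c - R @ c, order=order)
    return rot.sum(axis=1) * vox


def ball_lattice_count(k_gap, delta_k, dim):
    """Triple-loop enumeration of lattice points with |k| <= k_gap."""
    m = int(np.floor(k_gap / delta_k + 1e-9))
    count = 0
    rng = range(-m, m + 1)
    if dim == 2:
        for i in rng:
            for j in rng:
                if (i * i + j * j) * delta_k**2 <= k_gap**2 * (1 + 1e-12):
                    count += 1
    else:
        for i in rng:
            for j in rng:
                for k in rng:
                    if (i * i + j * j + k * k) * delta_k**2 <= k_gap**2 * (1 + 1e-12):
                        count += 1
    return count
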