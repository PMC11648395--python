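"""Sigmoid edge-sharpness: the scalar that scores IsoEx vs OffEx images.

A base-10 sigmoid SI(i) = c1/(1 + 10^(s(c0-i))) + c2 is fitted to a line
profile across an edge; s (decades per sample) is the sharpness.  The
script fits a clean synthetic edge, then the same edge blurred, and then
compares the rim sharpness of a reconstructed disk under isocenter vs
off-center excitation at a 10 cm offset.
"""

import numpy as np

from ztesim import (
    ExcitationScheme,
    LineProfile,
    PulseParams,
    ReconParams,
    disk_phantom,
    fit_sigmoid,
    make_trajectory,
    median_sharpness,
    reconstruct,
    simulate_acquisition,
)

i = np.arange(30, dtype=float)
clean = 100.0 / (1.0 + 10.0 ** (0.8 * (10.0 - i))) + 5.0
fit = fit_sigmoid(LineProfile(intensities=clean))
print(f"synthetic edge: fitted s = {fit.s:.3f} (truth 0.8), center c0 = {fit.c0:.2f}")
blurred = np.convolve(clean, np.ones(5) / 5, mode="same")
blurred[:2], blurred[-2:] = blurred[2], blurred[-3]
print(f"after a 5-sample box blur: s = {fit_sigmoid(LineProfile(intensities=blurred)).s:.3f}")

n, fov, g = 64, 0.4, 0.020
center = np.array([0.10, 0.0])
ph = disk_phantom((n, n), fov, 0.04, center)
traj = make_trajectory(202, g, fov, n, dead_time=6e-6, dim=2, full_circle=True)
vox = fov / n
cidx = center / vox + n / 2
segs = [((cidx[0] + 0.4 * 0.04 / vox, cidx[1]), (cidx[0] + 1.6 * 0.04 / vox, cidx[1]))]
for name, sch in (("IsoEx", ExcitationScheme.isocenter()),
                  ("OffEx", ExcitationScheme.offcenter(center))):
    data = simulate_acquisition(ph, traj, sch, PulseParams())
    img = reconstruct(data, ReconParams(grid_shape=(n, n)))
    s = median_sharpness(img.magnitude, segs)
    print(f"{name}: outward rim sharpness s = {s:.2f}")
print("The outward rim is where the profile distortion hits hardest; OffEx "
      "keeps it sharp while IsoEx blurs it away.")
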