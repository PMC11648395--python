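"""Projections of a two-object phantom under the three excitation schemes.

One disk sits at the isocenter, one at the profile's first zero crossing
(~14.7 cm at 20 mT/m).  Under fixed-carrier excitation (IsoEx) the
off-center disk all but vanishes whenever the gradient points along the
offset; per-shot off-center excitation (OffEx) re-centers the profile on
it every shot, at the price of distorting the isocenter disk.  The printed
numbers are sinogram L2 errors against the ideal (profile-free) sinogram,
restricted to each object's exclusive support.
"""

from ztesim import ExperimentConfig, run_sinogram_demo

cfg = ExperimentConfig()
cfg.phantom = {"shape": 64, "fov_m": 0.4}   # desk-sized; 128 matches the full demo
cfg.angles = 60

report = run_sinogram_demo(cfg)
errs = report["errors_vs_ideal"]
print(f"object at r0 = {report['parameters']['r0_m'] * 100:.1f} cm "
      f"(first zero crossing: {report['parameters']['first_zero_crossing_m'] * 100:.1f} cm)")
for obj in ("offcenter_object", "isocenter_object"):
    e = errs[obj]
    print(f"{obj}: IsoEx error {e['isocenter']:.3f}, OffEx error {e['offcenter']:.3f}")
print(f"OffEx improves the off-center object "
      f"{report['offcenter_object_improvement']:.1f}x; the isocenter object "
      "pays for it - the trade-off the carrier shift buys.")
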