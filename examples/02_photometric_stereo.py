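"""Recover surface gradients and albedo from a rendered capture.

Subtracts the ambient frame, solves the per-pixel Lambertian system by
least squares, and compares the recovered normals with the generator's
ground truth.  The angular error quantifies how faithfully photometric
stereo recovers the 3D relief that the venation stages rely on.
"""

import numpy as np

import leafvein as lv

spec = lv.SyntheticLeafSpec(seed=7)   # default: 0.5% noise, 5% ambient
leaf, stack = lv.simulate_leaf(spec)

corrected = lv.subtract_ambient(stack)
field = lv.solve_normals(corrected)
depth = lv.integrate_depth(field)

ang = np.degrees(np.arccos(np.clip(
    np.sum(leaf.normals() * field.normals(), axis=-1), -1, 1)))
good = leaf.foreground & field.valid

print(f"valid pixels              : {field.valid.mean() * 100:.1f}%")
print(f"median angular error      : {np.median(ang[good]):.3f} deg "
      f"(on the blade; lower is better)")
print(f"recovered albedo range    : [{field.albedo[good].min():.2f}, "
      f"{field.albedo[good].max():.2f}] "
      f"(true blade albedo varies around 0.65)")
print(f"depth map span            : {np.ptp(depth.z[leaf.foreground]):.1f} "
      f"height units (visualisation only; the pipeline uses gradients)")
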