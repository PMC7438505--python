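"""Digital refocusing, the focal-stack hourglass and depth from focus.

A point at refocus slope beta comes into focus only when the shift-and-add
slope matches: the FWHM-vs-beta curve has an hourglass shape with its
waist at the true slope, and a local focus metric turns the focal stack
into a per-pixel depth map.
"""

import numpy as np
from scipy import ndimage

from diffuserlf import (
    LightField,
    depth_map,
    focal_stack,
    fwhm,
    make_point_lightfield,
    small_geometry,
)

config = small_geometry(n_s=33, n_t=33, n_u=3, n_v=3, sensor=64)
points = [(10, 10, 0.0, 1.0), (24, 24, 2.0, 1.0)]
lf = make_point_lightfield(config, points)
arr = lf.radiance.copy()
for i in range(3):
    for j in range(3):
        arr[:, :, i, j] = ndimage.gaussian_filter(arr[:, :, i, j], 0.7)
lf = LightField(arr, config)

betas = np.arange(-1.0, 3.01, 0.5)
stack = focal_stack(lf, betas)

print("beta   FWHM through the slope-2 point (hourglass: waist at beta=2)")
for k, b in enumerate(betas):
    profile = stack.slices[k][24, :]
    width = fwhm(profile) if profile.max() > 0 else float("nan")
    print(f"{b:+.1f}   {width:.2f}")

dm = depth_map(stack, window=5)
for s, t, beta, _ in points:
    print(f"depth map at point (s={s}, t={t}): best beta = "
          f"{dm.best_beta[s, t]:+.1f} (truth {beta:+.1f})")
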