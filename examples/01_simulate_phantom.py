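"""Generate one synthetic phantom case and inspect its fields.

A phantom case mimics a single axial slice of a head-and-neck FDG-PET study:
an elliptical body with background uptake near SUV 1, Gaussian high-uptake
hotspots, a smooth planned-dose composite rescaled to 20 Gy, and a
post-radiation image simulated from known reaction-diffusion dynamics with
a linear cell-kill response.
"""

import numpy as np

from petpde import PhantomSpec, generate_case

spec = PhantomSpec(seed=0)
case = generate_case(spec, case_seed=0)

pre, dose, post = case.pre.values, case.dose.values, case.post.values
body = case.body_mask
hot = pre > 2.0

print(f"case id            : {case.case_id}")
print(f"grid               : {pre.shape}, {case.pre.grid.spacing_row_mm} mm pixels")
print(f"hotspots           : {case.ground_truth['n_hotspots']}")
print(f"pre  SUV  max/mean : {pre.max():.2f} / {pre[body].mean():.3f} (inside body)")
print(f"dose Gy   max/mean : {dose.max():.1f} / {dose[body].mean():.2f}")
print(f"post SUV  max/mean : {post.max():.2f} / {post[body].mean():.3f}")
print(f"hotspot mean SUV   : pre {pre[hot].mean():.2f} -> post {post[hot].mean():.2f}")
print()
print("The hotspot uptake drops sharply because the simulated response is a")
print("first-order kill -gamma*(dose o SUV) with gamma=0.4 at up to 20 Gy;")
print("the background changes little because its dose-uptake product is small.")
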