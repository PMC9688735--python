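"""Synthetic per-oocyte fluorescence quantification: ANOVA + Dunnett + overlap.

The study quantified mitochondrial activity and ROS level per oocyte as
fluorescence intensity in arbitrary densitometric units (ADU, 0-255) and
compared groups by one-way ANOVA with Dunnett's many-to-one test.  The actual
per-oocyte values are unpublished, so this example generates synthetic groups
with the same design (perfused groups well below control) and analyses them.
"""

import numpy as np

from mivmsim import anova_dunnett, gen_fluorescence, overlap_coefficient
from mivmsim.synth import default_fluorescence_spec

samples = gen_fluorescence(default_fluorescence_spec(seed=7))
for s in samples:
    print(f"{s.group:11s} n={s.values.size:3d} "
          f"mean={s.values.mean():6.1f} +- {s.values.std(ddof=1):4.1f} ADU")

res = anova_dunnett(samples, control_group="CTRL")
print(f"\none-way ANOVA: F = {res['anova_F']:.1f}, p = {res['anova_p']:.2g}")
for g, p in res["dunnett"].items():
    print(f"Dunnett vs CTRL: {g:11s} p = {p:.2g}")

# mitochondria/ROS colocalization of one synthetic oocyte profile
rng = np.random.default_rng(7)
mito = np.clip(rng.normal(120, 30, 64), 0, 255)
ros = np.clip(0.8 * mito + rng.normal(0, 20, 64), 0, 255)
r = overlap_coefficient(mito, ros)
print(f"\nMander overlap coefficient (mito vs ROS signal): {r:.3f}")
print("Values near 1 indicate colocalized mitochondrial and ROS signal,")
print("the marker of healthy bioenergetic status used in the study design.")
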