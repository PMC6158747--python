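"""Orientation-resolved folding distributions at fixed DNA distances.

Sweeps rigid-body orientations of the toy domain on a coarse intrinsic
z-y-z Euler grid at two separations and summarizes the distribution of
mean folded probability over clash-free poses.  Close to DNA the
distribution is broad (orientation matters: some poses present the
binding face, others do not); far away it collapses onto the apo value.
"""

import numpy as np

from electrofold import ScreeningContext, orientation_scan
from electrofold.synthetic import TOY_WSME_PARAMS, make_scene

scene = make_scene()
ctx = ScreeningContext(ionic_strength=0.1, temperature=310.0)
res = orientation_scan(scene, TOY_WSME_PARAMS, ctx, angle_step=60.0,
                       distances=[6.0, 40.0], T=310.0)

for d, g in res.table.groupby("distance"):
    ok = g.loc[~g.clash, "mean_PF"]
    print(f"distance {d:5.1f} A: {len(g)} poses, {len(ok)} clash-free, "
          f"<P_F> median {ok.median():.3f}, "
          f"IQR [{ok.quantile(0.25):.3f}, {ok.quantile(0.75):.3f}]")
print("\n(a wide interquartile range near DNA reflects pose-dependent "
      "folding; the far distribution concentrates at the apo value)")
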