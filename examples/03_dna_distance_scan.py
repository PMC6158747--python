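"""DNA as a distance-dependent chaperone: folding versus separation.

Poses the toy domain against an ideal B-DNA phosphate lattice and
rigidly retracts it along the approach axis.  At each distance the
per-residue DNA interaction field (Go-like packing within 5 A plus
screened-Coulomb attraction to every phosphate) re-weights the folding
ensemble.  Expect <P_F> and T_m to fall monotonically with distance,
and the electrostatics-free control to stay pinned at the apo value
once the protein leaves the 5 A contact shell.
"""

from electrofold import ScreeningContext, distance_scan
from electrofold.synthetic import TOY_WSME_PARAMS, make_scene

scene = make_scene()
ctx = ScreeningContext(ionic_strength=0.1, temperature=310.0)
distances = [0, 5, 10, 15, 20, 25]

full = distance_scan(scene, TOY_WSME_PARAMS, ctx, distances, T=310.0,
                     compute_tm=True, compute_profiles=False)
control = distance_scan(scene, TOY_WSME_PARAMS, ctx, distances, T=310.0,
                        include_electro=False, compute_profiles=False)

print(f"{'d (A)':>6} {'<P_F>':>7} {'T_m (K)':>8} {'<P_F> vdW-only':>15}")
for (_, row), (_, ctl) in zip(full.table.iterrows(), control.table.iterrows()):
    print(f"{row.distance:6.0f} {row.mean_PF:7.3f} {row.Tm_K:8.2f} "
          f"{ctl.mean_PF:15.3f}")
print("\n(d = 0 is the bound reference pose, ~6 A from the phosphate "
      "surface; the vdW-only column shows folding is electrostatically "
      "driven at a distance.)")
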