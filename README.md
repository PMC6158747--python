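# electrofold

Statistical-mechanical modelling of **distance-dependent
"electro-folding"** of DNA-binding domains: how the electrostatic
potential of DNA screens the frustrated charge pattern of a marginally
stable domain and folds it *before contact*, with DNA acting as a
non-specific macromolecular chaperone.

The package is aimed at protein-folding and protein–nucleic-acid
biophysicists who want a desk-scale, fully scriptable version of three
connected analyses:

1. **Screened electrostatics** — Debye–Hückel charge–charge energies
   `E = k_C q₁q₂ e^(−κr)/(εr)`, with the local (|i−j| ≤ 4) versus
   non-local decomposition that diagnoses electrostatic frustration,
   and protein–DNA interaction energies versus distance.
2. **An Ising-like (WSME) folding ensemble** — each residue native or
   unfolded, contacts alive only inside fully native stretches,
   microstate free energy
   `ΔG = Σ c_ij[ξ + ΔCp((T−T_ref) − T ln(T/T_ref))] + Σ E_elec − T·m·ΔS_conf`,
   extended with a per-residue DNA field that re-weights every
   microstate by `Π_j exp(−ΔG_j,DNA ρ_j/RT)`. Outputs: partition
   function, free-energy profiles F(n), per-residue probabilities
   ⟨ρ_j⟩, ⟨P_F⟩(T), heat capacity and melting temperatures; rigid-body
   distance and orientation scans against an ideal B-DNA phosphate
   lattice.
3. **Variable-barrier (Landau) DSC analysis** — absolute heat-capacity
   thermograms modelled through a piecewise-quartic free-energy
   functional over enthalpy with parameters (Σα, β, T0, f); forward
   simulation, barrier diagnostics, and fixed-baseline least-squares
   fitting that distinguishes one-state (β ≤ 0) from barrier-limited
   folding.

Everything runs from synthetic, programmatically generated inputs
(a frustrated toy helical domain, ideal B-DNA lattices, noisy
thermograms), and the same code paths accept user-supplied PDB files
and thermogram CSVs. See `docs/methods.md` for the models and their
assumptions.

## Worked example

Fold the default frustrated toy domain as it approaches DNA
(`examples/03_dna_distance_scan.py`):

```text
 d (A)   <P_F>  T_m (K)  <P_F> vdW-only
     0   0.746   334.41           0.213
     5   0.722   322.06           0.213
    10   0.609   314.83           0.213
    15   0.437   310.99           0.213
    20   0.327   308.94           0.213
    25   0.271   307.86           0.213
```

Reading the numbers: at the bound pose (distance 0, ~6 Å from the
phosphate surface) the domain is mostly folded (⟨P_F⟩ = 0.75) and
strongly stabilized (T_m = 334 K); retracting it along the approach
axis lowers both monotonically toward the apo values (⟨P_F⟩ ≈ 0.21,
T_m ≈ 306 K). The control without protein–DNA electrostatics stays
pinned at the apo value at every distance beyond the 5 Å contact
shell — the folding is driven by the DNA's electric field, not by
packing.

The calorimetric side (`examples/04_vb_thermogram_analysis.py`) prints
the published variable-barrier parameter sets of the CytR DNA-binding
domain at 43/600/1300 mM ionic strength, their barrier at T0
(0 / 0 / 0.12 kJ·mol⁻¹) and 298 K density modes (+33 / −51 / −146
kJ·mol⁻¹ — a native ensemble marching to lower enthalpy with salt),
then refits a noiseless simulated 1300 mM thermogram and recovers
Σα = 121.1 kJ/mol, β = 0.120 kJ/mol, T0 = 337.3 K, f = 0.903 to
machine precision.

Other examples: `01_electrostatic_frustration.py` (local/non-local
salt trends), `02_wsme_folding_ensemble.py` (apo ensemble),
`05_orientation_ensemble.py` (orientation-resolved folding
distributions).

A thin CLI wraps the same functions for config-driven runs:

```bash
electrofold vb-sim --ionic-mM 1300 --out out_sim
electrofold dna-scan --config scan.yaml --out out_scan
```

Every command writes plain CSV/JSON plus the resolved config beside
its outputs, so runs are reproducible from their own output directory.

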