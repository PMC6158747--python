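# Methods

This note documents the models implemented in `electrofold`, the
assumptions behind them, the parameters that matter, and the design
choices made where the underlying physics leaves the implementation
genuinely open.

## The problem

Small DNA-binding domains carry an excess of positive charge clustered
on their binding face. That charge pattern is electrostatically
*frustrated*: like-charge repulsion at short sequence separation
destabilizes the fold, and is only partially compensated by favorable
long-range pairs. Such domains can sit close to their folding midpoint
in isolation, and the strong negative electrostatic potential of DNA —
felt 20–25 Å from the phosphate surface at physiological ionic
strength — can screen the frustration and fold the domain *at a
distance*, before any contact is made. `electrofold` provides the
pieces needed to model this quantitatively: screened-Coulomb
electrostatics, an Ising-like folding ensemble, a per-residue
protein–DNA coupling, and the variable-barrier calorimetric analysis
used to diagnose barrierless (one-state) folding.

## Screened electrostatics

Charge–charge energies use a Debye–Hückel screened Coulomb form,

    E(r) = k_C q1 q2 exp(-kappa r) / (eps_int r),      k_C = 1389.35 kJ Å mol⁻¹ e⁻²

with two distinct dielectric roles:

* `solvent_dielectric` (default 78.5) enters only the screening
  parameter `kappa` of the 1:1 electrolyte — the screening length is a
  property of the solvent;
* `interaction_dielectric` (default 29) scales the interaction
  prefactor — an effective uniform dielectric for both intramolecular
  and protein–DNA pairs. It is configurable over [29, 74.3]; the
  distance-scan phenomenology is insensitive to the choice within this
  range.

Charges are pH-7 formal charges (Lys/Arg +1, Asp/Glu −1, His neutral;
no pKa calculation). Pair distances are measured between side-chain
charged-group centroids (NZ; NH1/NH2/CZ; OD1/OD2; OE1/OE2), falling
back to the outermost side-chain heavy atom. The local/non-local
decomposition splits pairs at sequence separation 4 (local ≤ 4); the
two sums partition the total exactly.

## The folding ensemble (WSME)

Each residue is native (1) or unfolded (0). A native contact (i, j)
contributes only when every residue i..j is native. The microstate
free energy relative to the fully unfolded reference is

    ΔG = Σ_alive c_ij [ξ + ΔCp_cont((T − T_ref) − T ln(T/T_ref))]
       + Σ_alive E_elec(i,j)  −  T m ΔS_conf  +  Σ_{j folded} g_j

with `c_ij` the number of heavy-atom pairs within the contact cutoff
(ξ is an energy *per atom pair*; at −217.1 J/mol it is far too small to
be a residue-level contact energy), ΔS_conf < 0 the per-residue
conformational entropy, ΔCp_cont a temperature-independent heat
capacity per contact anchored at a solvation reference temperature
T_ref = 385 K (the convention of this model family; the solvation term
vanishes at T_ref), and g_j an optional per-residue field (see below).
Defaults: ξ = −217.1 J/mol, ΔS_conf = −33.31 J/(mol K), ΔCp_cont =
−2.33 J/(mol K).

Intramolecular electrostatic pairs are included for *all* charged
pairs, not only contact-map pairs, under the same
all-intervening-residues-native rule (`electro_pairs="contacts"`
restricts them).

**State space.** Production runs enumerate microstates with at most
two contiguous native stretches (single + double sequence
approximation). For an N-residue chain that is 1 + N(N+1)/2 single
islands plus O(N⁴/24) island pairs — ~10⁵–10⁶ states at N ≈ 66,
evaluated in milliseconds per temperature because every term is
additive over islands (a contact can only be alive inside one island).
The partition function, the F(n) profile over the number of structured
residues n, the per-residue probabilities ⟨ρ_j⟩ and the mean enthalpy
are computed in log space with prefix/suffix aggregation; full 2^N
enumeration is retained for N ≤ 25 and is the exact oracle the engine
is tested against (agreement to 10⁻⁹ relative at N ≤ 12). Partition
functions are nested by construction: Z(1 island) ≤ Z(2 islands) ≤
Z(full).

**Observables.** ⟨P_F⟩ is the unweighted mean of ⟨ρ_j⟩. The melting
temperature is the temperature of maximum |d⟨P_F⟩/dT| (with quadratic
refinement around the grid maximum) rather than the ⟨P_F⟩ = 0.5
crossing, because downhill curves need not cross 0.5. For sharp
two-state systems this estimator agrees with the ΔG = 0 midpoint to
< 0.2 K; for broad transitions it sits a few kelvin below the
midpoint — an intrinsic property of the estimator, not an error. The
heat capacity is d⟨H⟩/dT by central differences of the ensemble mean
enthalpy, with H decomposed consistently with G = H − TS (contact
enthalpy ξ + ΔCp_cont(T − T_ref); electrostatic and field terms treated
as temperature-independent enthalpy).

**Anchoring to experiment.** This model family is parameterized in
practice by calibrating ξ so the apo ensemble reproduces an
experimental melting temperature; `calibrate_xi` does this by a
bracketed root solve of T_m(ξ) with edge-gating for transitions that
leave the temperature grid.

## Protein–DNA coupling

For a rigid pose of the protein relative to a DNA phosphate lattice,
every residue j acquires

    ΔG_j,DNA = ξ_DNA · (heavy-atom pairs between j and DNA within 5 Å)
             + Σ_phosphates E(q_j, −1, r)

and each microstate is re-weighted by Π_j exp(−ΔG_j,DNA ρ_j / RT): DNA
stabilizes only residues that are *native* in that microstate. ξ_DNA
defaults to ξ (no evidence for a distinct protein–DNA packing scale).
The van der Waals term is recomputed per pose and vanishes smoothly
outside the 5 Å shell; the electrostatic term sums over every
phosphate with no cutoff. A zero field is an exact identity on all
observables, and a uniform field g is algebraically identical to the
entropy shift ΔS_conf → ΔS_conf − g/T (both identities are tested).

**Scans.** The bound reference pose is distance 0; the approach axis
defaults to the radial direction from the DNA helical axis to the
protein centroid. Distance scans translate rigidly along that axis and
recompute the field, ⟨P_F⟩, F(n) and optionally T_m per distance.
Orientation scans sweep intrinsic z–y–z Euler angles on a uniform grid
(azimuthal angles over [0, 360), polar over [0, 180] inclusive, so a
30° step gives 12·7·12 = 1008 orientations); poses with any heavy atom
strictly within 2 Å of a phosphate are flagged as clashes and carry no
thermodynamics. Scan defaults are 310 K and 0.1 M ionic strength.

**DNA model.** Generated lattices are ideal B-form: rise 3.38 Å per
base pair, twist 36°, phosphates at 8.91 Å from the helical axis, two
antiparallel strands of n_bp − 1 phosphates each (no 5′-terminal
phosphate), one −1 e charge per phosphate. Only the phosphates are
represented; sugars, bases and counterions are not.

## Variable-barrier (Landau) DSC analysis

The enthalpy H (kJ/mol, relative to the characteristic temperature T0)
is the order parameter of a piecewise-quartic Landau functional with
side-dependent width:

    G0(H) = −2β (H/α)² + |β| (H/α)⁴,   α = α₁ for H < 0, α₂ for H ≥ 0,
    α₁ = f Σα/(1+f),  α₂ = Σα/(1+f)

For β > 0 this is a double well with minima at −α₁ and +α₂ of depth
−β, so the thermodynamic barrier at T0 is exactly β; for β ≤ 0 it is a
single well at H = 0 (one-state folding). The asymmetry factor
f = α₁/α₂ measures the sharpness of the low-enthalpy (native) side.
Away from T0 a first-order entropy closure S0(H) = H/T0 tilts the
functional: G(H, T) = G0(H) − (T − T0) H/T0. Densities are Boltzmann
weights normalized by trapezoid quadrature on an adaptive grid of
≥ 2001 points spanning ±3Σα; the absolute heat capacity is a fixed
folded baseline plus d⟨H⟩/dT (central differences; cross-checked
against the fluctuation identity d⟨H⟩/dT = Cov(H, G0 + H)/RT² to 1%).

The f convention above is internal to the package: the generator and
the fitter share it, so recovery of published parameter values is
exact by construction on synthetic data, but fitted values on real
thermograms should be compared against the original formulation of the
model before quantitative interpretation of f.

**Baselines.** The folded (native) baseline is linear in T per gram of
protein, cp(T) = 1.323 + 6.70·10⁻³ (T − 293.15) J g⁻¹ K⁻¹, converted
to molar units with a mean residue mass of 110 g/mol; it is held fixed
during fitting. An approximate quadratic unfolded baseline is provided
for plotting only and never enters a fit.

**Fitting.** Bounded nonlinear least squares (trust-region reflective)
over (Σα, β, T0, f) from eight deterministic multi-starts spanning both
signs of β and two energy-gap scales around data-driven heuristics; the
seed controls small reproducible jitter of the starts and is recorded
in the output. On noiseless synthetic thermograms the fit is a fixed
point of the forward simulation (recovery to ≲10⁻⁴ relative); with
0.5 kJ mol⁻¹ K⁻¹ Gaussian noise, parameters are recovered to a few
percent.

## Synthetic generators

All generators are deterministic under a fixed seed.

* **Toy domain** (`make_toy_dbd`): 60 residues, three ideal α-helices
  (rise 1.5 Å, 100°/residue, radius 2.3 Å — consecutive Cα spacing
  3.8 Å) connected by equal-spacing-projected linkers, at Cα + one
  pseudo side-chain site per residue. The default charge pattern is
  the deliberately frustrated layout: a binding face of four positives
  with like-charge pairs at separation 3–4 on helix 1, two negatives
  on helix 2, two further positives on helix 3; net +4. Helix axes are
  collinear with the DNA axis and spaced 10.5 Å, so favorable
  opposite-charge pairs sit on adjacent helices and unfavorable
  like-charge pairs are either sequence-local or far apart — giving a
  positive local and negative non-local electrostatic sum with the
  opposite salt trends characteristic of frustrated DNA-binding
  domains. The toy uses a 6.5 Å contact cutoff (two pseudo-atoms per
  residue resolve no 5 Å shell) and its own per-contact energy
  (ξ = −1640 J/mol, ΔCp_cont = −10 J/(mol K)) chosen once so the
  default domain is marginally stable near 310 K (apo T_m ≈ 306 K,
  apo ⟨P_F⟩(310 K) ≈ 0.2) — the regime in which a DNA field can
  visibly fold it. Scene placement solves for the translation at which
  the minimum heavy-atom-to-phosphate distance equals the bound
  distance (default 6 Å).
* **Stand-in domain** (`synthetic_dbd_pdb`): a synthetic 66-residue
  three-helix bundle written as PDB text at backbone + side-chain-tip
  resolution (~340 heavy atoms, ~820 contact atom pairs at 5 Å), with
  a CytR-like frustrated charge composition (net +6, charged face on
  one flank). It exercises the full file-based path (PDB parsing,
  charged-group centroids, 5 Å contact maps) and, with ξ calibrated to
  an apo melting temperature of 305 K, reproduces the
  distance-dependent folding phenomenology at CytR scale (⟨P_F⟩ ≈ 0.4
  beyond 20 Å rising toward 0.9 at the bound pose; T_m falling from
  ~328 K bound to ~306 K far). It is *not* a deposited structure, and
  agreement on it validates the machinery, not a structure-specific
  prediction.
* **Thermograms** (`make_thermogram`): forward VB curves plus i.i.d.
  Gaussian noise on Cp — a reasonable approximation of capillary DSC
  noise at this scale, with no scan-rate or buffer-mismatch artifacts.

What the synthetic data do **not** emulate: real side-chain packing
and rotamers, sequence-specific DNA readout, counterion release,
dielectric heterogeneity, and instrument baselines. Passing tests on
synthetic scenes therefore demonstrate correctness of the statistical
mechanics and the qualitative electro-folding phenomenology, not
quantitative agreement with any particular experimental system.

## Numerical choices

* All ensemble arithmetic in log space (logsumexp with prefix/suffix
  accumulation); no overflow up to strongly stabilizing fields.
* Contact and clash conventions: contacts use distance ≤ cutoff;
  clashes use strictly < threshold (an atom exactly at the threshold
  is not a clash).
* Heat-capacity grids: ≤ 1 K steps for the ensemble Cp, ≤ 0.5 K for
  the VB forward curve (warnings otherwise); peak heights converge to
  < 1% under step halving.
* Barrier heights from a 20001-point grid over ±2Σα with parabolic
  refinement of each extremum.
* Degenerate inputs: structures with < 2 residues give an empty
  contact map (not an error); a flat ⟨P_F⟩ curve raises "no transition
  detected"; non-normalizable densities and invalid parameter
  combinations raise immediately.

## Known limitations

* Equilibrium only: no kinetics, no association rates, no 1D-sliding /
  3D-hopping dynamics.
* Rigid-body poses: the protein does not deform as it approaches DNA;
  binding free energies and affinities are out of scope.
* The double-sequence approximation omits ≥3-island microstates;
  near the transition of a 66-residue chain their weight is small
  (the nested-Z inequality bounds the error from below only).
* The Landau entropy closure S0(H) = H/T0 is first order; strongly
  curved S0(H) would require the full formulation.
* Ionic-strength conversions assume a monovalent 1:1 electrolyte.
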