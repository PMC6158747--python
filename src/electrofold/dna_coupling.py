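"""Protein-DNA coupling of the folding ensemble.

Each residue j acquires a free energy of interaction with DNA,
dG_j,DNA = vdw_j + elec_j: a Go-like packing term (xi_dna per heavy-atom
pair between residue j and a DNA atom within a 5 A cutoff) plus the
screened-Coulomb energy between the residue's charge and every DNA
phosphate.  The ensemble is re-weighted by
prod_j exp(-dG_j,DNA * rho_j / RT), i.e. the field acts only on residues
that are folded in a microstate — DNA stabilizes native structure in a
distance-dependent way.

Scans rigidly displace the protein from its bound reference pose along
the approach axis (distance 0 = bound pose) and/or rotate it on an
intrinsic z-y-z Euler grid, skipping steric clashes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .electrostatics import (PairEnergyMatrix, ScreeningContext, pair_energy,
                             intra_protein_decomposition)
from .structures import (ChargeSet, ContactMap, DNAPhosphateLattice, Pose,
                         ProteinStructure, detect_clash, transform_pose)
from .wsme import (EnsembleSummary, WSMEEnsemble, WSMEParameters,
                   ensemble_summary, melting_temperature)


@dataclass
class DNAFieldMap:
    """Per-residue protein-DNA interaction free energies for one pose.

    All energies in J/mol; ``dG_dna[j] = vdw[j] + elec[j]``.
    """

    dG_dna: dict[int, float]
    pose: Pose | None = None
    vdw: dict[int, float] = dc_field(default_factory=dict)
    elec: dict[int, float] = dc_field(default_factory=dict)
    context: ScreeningContext | None = None

    def as_array(self, N: int) -> np.ndarray:
        out = np.zeros(N)
        for j, g in self.dG_dna.items():
            out[j - 1] = g
        return out

    def total(self) -> float:
        return float(sum(self.dG_dna.values()))


def compute_dna_field(protein: ProteinStructure, charges: ChargeSet,
                      dna: DNAPhosphateLattice, context: ScreeningContext,
                      vdw_cutoff: float = 5.0, xi_dna: float = -217.1,
                      pose: Pose | None = None,
                      include_electro: bool = True) -> DNAFieldMap:
    """dG_j,DNA for the protein *at its current pose*.

    vdw_j = xi_dna * (heavy-atom pairs between residue j and DNA within
    ``vdw_cutoff``); elec_j = screened-Coulomb sum over every phosphate
    (no cutoff).  ``include_electro=False`` zeroes the electrostatic
    component (van der Waals-only control).
    """
    if vdw_cutoff <= 0:
        raise ValueError("vdw_cutoff must be positive")
    tree = cKDTree(dna.phosphates)
    vdw: dict[int, float] = {}
    elec: dict[int, float] = {}
    for res in protein.residues:
        n_pairs = sum(len(hits) for hits in
                      tree.query_ball_point(res.heavy_atoms, vdw_cutoff))
        vdw[res.index] = xi_dna * n_pairs
        q = charges.charges.get(res.index, 0)
        if include_electro and q != 0:
            site = res.charge_site
            if site is None:
                raise ValueError(f"residue {res.index} charged but has no site")
            r = np.linalg.norm(dna.phosphates - site[None, :], axis=1)
            e_kj = pair_energy(q, dna.charge_per_phosphate, r, context).sum()
            elec[res.index] = 1000.0 * float(e_kj)
        else:
            elec[res.index] = 0.0
    dG = {j: vdw[j] + elec[j] for j in vdw}
    return DNAFieldMap(dG_dna=dG, pose=pose, vdw=vdw, elec=elec, context=context)


def apply_field(contacts: ContactMap, electro: PairEnergyMatrix | None,
                params: WSMEParameters, T: float, field: DNAFieldMap,
                max_islands: int | None = 2,
                compute_profile: bool = True) -> EnsembleSummary:
    """Ensemble observables with every microstate re-weighted by
    prod_j exp(-dG_j,DNA rho_j / RT)."""
    return ensemble_summary(contacts, electro, params, T,
                            max_islands=max_islands, field=field,
                            compute_profile=compute_profile)


@dataclass
class Scene:
    """A protein (at its bound reference pose), its contact map and
    charges, a DNA phosphate lattice, and the approach geometry."""

    protein: ProteinStructure
    contacts: ContactMap
    charges: ChargeSet
    dna: DNAPhosphateLattice
    pose: Pose = dc_field(default_factory=Pose)
    approach_axis: np.ndarray | None = None  # unit vector, protein moves +axis

    def __post_init__(self) -> None:
        if self.approach_axis is None:
            self.approach_axis = self._default_axis()
        self.approach_axis = np.asarray(self.approach_axis, dtype=float)
        self.approach_axis /= np.linalg.norm(self.approach_axis)

    def _default_axis(self) -> np.ndarray:
        """Radial direction from the DNA helical axis to the protein
        centroid at the bound pose."""
        c = self.protein.centroid()
        p0 = self.dna.axis_point()
        d = self.dna.axis_direction()
        radial = (c - p0) - np.dot(c - p0, d) * d
        n = np.linalg.norm(radial)
        if n < 1e-9:
            raise ValueError("protein centroid lies on the DNA axis; specify "
                             "approach_axis explicitly")
        return radial / n

    def protein_at(self, distance: float,
                   rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
                   ) -> ProteinStructure:
        pose = Pose(rotation=rotation, translation=distance,
                    distance_from_bound=max(distance, 0.0))
        return transform_pose(self.protein, pose, self.approach_axis)


@dataclass
class ScanResult:
    """Tidy per-pose observables plus optional free-energy profiles."""

    table: pd.DataFrame
    profiles: dict = dc_field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _pose_row(scene: Scene, params: WSMEParameters, context: ScreeningContext,
              engine: WSMEEnsemble, distance: float,
              rotation: tuple[float, float, float], T: float,
              include_electro: bool, xi_dna: float, vdw_cutoff: float,
              clash_threshold: float, want_profile: bool,
              tm_grid: np.ndarray | None):
    prot = scene.protein_at(distance, rotation)
    row = {"distance": distance, "alpha": rotation[0], "beta": rotation[1],
           "gamma": rotation[2], "clash": False, "mean_PF": np.nan,
           "Tm_K": np.nan}
    if detect_clash(prot, scene.dna, clash_threshold):
        row["clash"] = True
        return row, None
    fieldmap = compute_dna_field(prot, scene.charges, scene.dna, context,
                                 vdw_cutoff=vdw_cutoff, xi_dna=xi_dna,
                                 include_electro=include_electro)
    eng = engine.with_field(fieldmap)
    summ = eng.summary(T, compute_profile=want_profile)
    row["mean_PF"] = summ.mean_PF
    if tm_grid is not None:
        try:
            row["Tm_K"] = melting_temperature(tm_grid, eng.folding_curve(tm_grid))
        except ValueError:
            row["Tm_K"] = np.nan
    return row, (summ.profile if want_profile else None)


def distance_scan(scene: Scene, params: WSMEParameters,
                  context: ScreeningContext, distances: Sequence[float],
                  T: float = 310.0, include_electro: bool = True,
                  xi_dna: float | None = None, vdw_cutoff: float = 5.0,
                  clash_threshold: float = 2.0, compute_tm: bool = False,
                  tm_grid: Sequence[float] | None = None,
                  compute_profiles: bool = True,
                  max_islands: int = 2) -> ScanResult:
    """Thermodynamics versus protein-DNA distance along the approach
    axis (distance 0 = bound reference pose).  Clashing poses are
    flagged and carry no thermodynamics."""
    if np.any(np.asarray(distances) < 0):
        raise ValueError("distances must be >= 0")
    xi_dna = params.xi if xi_dna is None else xi_dna
    intra = intra_protein_decomposition(scene.protein, scene.charges, context)
    engine = WSMEEnsemble(scene.contacts, intra["matrix"], params,
                          max_islands=max_islands)
    grid = None
    if compute_tm:
        grid = (np.arange(250.0, 400.0, 2.0) if tm_grid is None
                else np.asarray(tm_grid, dtype=float))
    rows, profiles = [], {}
    for d in distances:
        row, prof = _pose_row(scene, params, context, engine, float(d),
                              (0.0, 0.0, 0.0), T, include_electro, xi_dna,
                              vdw_cutoff, clash_threshold, compute_profiles,
                              grid)
        rows.append(row)
        if prof is not None:
            profiles[float(d)] = prof
    return ScanResult(pd.DataFrame(rows), profiles)


def orientation_scan(scene: Scene, params: WSMEParameters,
                     context: ScreeningContext, angle_step: float,
                     distances: Sequence[float], T: float = 310.0,
                     clash_threshold: float = 2.0,
                     include_electro: bool = True,
                     xi_dna: float | None = None, vdw_cutoff: float = 5.0,
                     max_islands: int = 2) -> ScanResult:
    """Rigid-body orientation grid at each requested distance.

    Intrinsic z-y-z Euler grid: alpha, gamma in [0, 360) and polar beta
    in [0, 180] inclusive, at ``angle_step`` spacing (30 deg -> 12*7*12 =
    1008 orientations).  Clash-filtered; returns the distribution of
    mean folded probability per distance."""
    if angle_step <= 0 or 360.0 % angle_step != 0:
        raise ValueError("angle_step must divide 360 evenly")
    xi_dna = params.xi if xi_dna is None else xi_dna
    alphas = np.arange(0.0, 360.0, angle_step)
    betas = np.arange(0.0, 180.0 + 1e-9, angle_step)
    betas = betas[betas <= 180.0]
    gammas = np.arange(0.0, 360.0, angle_step)
    intra = intra_protein_decomposition(scene.protein, scene.charges, context)
    engine = WSMEEnsemble(scene.contacts, intra["matrix"], params,
                          max_islands=max_islands)
    rows = []
    for d in distances:
        any_free = False
        for a in alphas:
            for b in betas:
                for g in gammas:
                    row, _ = _pose_row(scene, params, context, engine,
                                       float(d), (float(a), float(b), float(g)),
                                       T, include_electro, xi_dna, vdw_cutoff,
                                       clash_threshold, False, None)
                    rows.append(row)
                    any_free = any_free or not row["clash"]
        if not any_free:
            warnings.warn(f"no clash-free orientation at distance {d} A")
    return ScanResult(pd.DataFrame(rows))
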