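"""Screened-Coulomb (Debye-Hueckel) electrostatics.

Charge-charge interaction energies decay as exp(-kappa*r)/r.  The
screening parameter kappa is a solvent property (computed with the
solvent dielectric), while the interaction prefactor is scaled by a
uniform effective dielectric (default 29) that stands in for the
protein / protein-DNA interaction medium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as sc

from .constants import COULOMB_KJ, SOLVENT_DIELECTRIC, UNIFORM_DIELECTRIC
from .structures import ChargeSet, DNAPhosphateLattice, ProteinStructure


def debye_kappa(ionic_strength: float, temperature: float = 298.15,
                solvent_dielectric: float = SOLVENT_DIELECTRIC) -> float:
    """Debye screening parameter kappa (1/angstrom) of a 1:1 electrolyte.

    kappa^2 = 2 e^2 N_A (1000 I) / (eps0 eps_r kB T), I in mol/L.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    if temperature <= 0 or solvent_dielectric <= 0:
        raise ValueError("temperature and dielectric must be positive")
    if ionic_strength == 0:
        return 0.0
    kappa_sq_m = (
        2.0 * sc.e**2 * sc.N_A * (1000.0 * ionic_strength)
        / (sc.epsilon_0 * solvent_dielectric * sc.k * temperature)
    )
    return math.sqrt(kappa_sq_m) * 1e-10


@dataclass
class ScreeningContext:
    """Solution conditions for screened-Coulomb energies."""

    ionic_strength: float  # mol/L, monovalent 1:1 electrolyte
    temperature: float = 298.15  # K
    solvent_dielectric: float = SOLVENT_DIELECTRIC  # sets kappa
    interaction_dielectric: float = UNIFORM_DIELECTRIC  # scales energies
    kappa: float = field(init=False)  # 1/angstrom, derived

    def __post_init__(self) -> None:
        self.kappa = debye_kappa(self.ionic_strength, self.temperature,
                                 self.solvent_dielectric)


@dataclass
class PairEnergyMatrix:
    """Pairwise charge-charge energies, kJ/mol, keyed (i, j) with i < j."""

    entries: dict[tuple[int, int], float]
    context: ScreeningContext | None = None

    def total(self) -> float:
        return float(sum(self.entries.values()))

    def get(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        return self.entries.get((i, j), 0.0)

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            {"i": i, "j": j, "separation": j - i, "energy_kJ_mol": e}
            for (i, j), e in sorted(self.entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def pair_energy(q1: float, q2: float, r, context: ScreeningContext):
    """Screened Coulomb energy in kJ/mol between point charges q1, q2 (e)
    at distance r (angstrom).  Vectorized over r."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive (self-interaction undefined)")
    if q1 == 0 or q2 == 0:
        return np.zeros_like(r) if r.ndim else 0.0
    e = COULOMB_KJ * q1 * q2 * np.exp(-context.kappa * r) / (
        context.interaction_dielectric * r
    )
    return e if r.ndim else float(e)


def _charge_sites(structure: ProteinStructure, charges: ChargeSet):
    idx, q, xyz = [], [], []
    for res in structure.residues:
        qi = charges.charges.get(res.index, 0)
        if qi == 0:
            continue
        if res.charge_site is None:
            raise ValueError(f"residue {res.index} is charged but has no charge site")
        idx.append(res.index)
        q.append(qi)
        xyz.append(res.charge_site)
    return np.array(idx, dtype=int), np.array(q, dtype=float), (
        np.array(xyz) if xyz else np.zeros((0, 3))
    )


def intra_protein_decomposition(structure: ProteinStructure, charges: ChargeSet,
                                context: ScreeningContext,
                                separation_threshold: int = 4) -> dict:
    """All intramolecular charge-pair energies, split into local
    (sequence separation <= threshold) and non-local (> threshold) sums.

    Returns ``{"local": kJ/mol, "nonlocal": kJ/mol, "matrix": PairEnergyMatrix}``;
    local + nonlocal equals the matrix total exactly.
    """
    idx, q, xyz = _charge_sites(structure, charges)
    entries: dict[tuple[int, int], float] = {}
    local = nonlocal_ = 0.0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            r = float(np.linalg.norm(xyz[a] - xyz[b]))
            e = pair_energy(q[a], q[b], r, context)
            entries[(int(idx[a]), int(idx[b]))] = e
            if idx[b] - idx[a] <= separation_threshold:
                local += e
            else:
                nonlocal_ += e
    return {"local": local, "nonlocal": nonlocal_,
            "matrix": PairEnergyMatrix(entries, context)}


def protein_dna_energy(protein: ProteinStructure, charges: ChargeSet,
                       dna: DNAPhosphateLattice,
                       context: ScreeningContext) -> float:
    """Net screened-Coulomb energy (kJ/mol) between the protein's charged
    residue sites and every DNA phosphate; pose must already be applied."""
    idx, q, xyz = _charge_sites(protein, charges)
    if len(idx) == 0:
        return 0.0
    diff = xyz[:, None, :] - dna.phosphates[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    e = COULOMB_KJ * q[:, None] * dna.charge_per_phosphate * np.exp(
        -context.kappa * r
    ) / (context.interaction_dielectric * r)
    return float(e.sum())
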