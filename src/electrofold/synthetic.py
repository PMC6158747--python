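"""Synthetic inputs: toy frustrated DNA-binding domains, protein-DNA
scenes, and noisy variable-barrier thermograms.

The default toy scene emulates, at contract-test scale, the physics of a
small helical DNA-binding domain with a positively charged binding face
and a deliberately frustrated charge pattern: like charges clustered at
short sequence separation (unfavorable local electrostatics), opposite
charges on neighboring helices (favorable non-local electrostatics), and
a net positive charge so the DNA phosphate field is attractive.  All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dna_coupling import Scene
from .structures import (ChargeSet, ContactMap, DNAPhosphateLattice, Pose,
                         ProteinStructure, Residue, assign_charges,
                         build_bdna_phosphates, build_contact_map,
                         detect_clash, min_distance)
from .vb import Thermogram, VBParameters, vb_cp_curve
from .wsme import WSMEParameters

#: Ideal alpha-helix geometry for C-alpha traces.
HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = 100.0  # deg per residue
HELIX_RADIUS = 2.3  # A
CA_SPACING = 3.8  # A, consecutive C-alpha distance


@dataclass
class ToySceneSpec:
    """Specification of the default frustrated toy scene.

    The charge pattern carries a binding face of positives on the first
    helix (local like-charge frustration), a complementary negative pair
    on the middle helix, and a second positive cluster on the last
    helix; net charge +4.
    """

    n_res: int = 60
    helix_layout: tuple[tuple[int, int], ...] = ((5, 20), (25, 40), (45, 58))
    charge_pattern: dict[int, int] = field(default_factory=lambda: {
        8: +1, 11: +1, 15: +1, 18: +1,   # binding face, helix 1
        29: -1, 33: -1,                  # helix 2
        48: +1, 51: +1,                  # helix 3
    })
    binding_face: tuple[int, ...] = (8, 11, 15, 18)
    dna_n_bp: int = 16
    bound_distance: float = 6.0
    seed: int = 0
    contact_cutoff: float = 6.5  # A; C-alpha + pseudo-site resolution
    min_separation: int = 2
    helix_spacing: float = 10.5  # A between neighboring helix axes

    def __post_init__(self) -> None:
        for j in self.charge_pattern:
            if not 1 <= j <= self.n_res:
                raise ValueError(f"charge index {j} outside 1..{self.n_res}")
        segs = sorted(self.helix_layout)
        for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
            if a2 <= b1:
                raise ValueError("helix segments overlap")


#: Ensemble parameters for the coarse (2 pseudo-atoms per residue) toy
#: chain: per-contact energy rescaled so that the default toy domain is
#: marginally stable near 310 K, mirroring the apo behavior the scene is
#: meant to emulate (the contact count per residue is ~20x smaller than
#: at heavy-atom resolution, so |xi| is correspondingly larger).
TOY_WSME_PARAMS = WSMEParameters(xi=-1640.0, dS_conf=-33.31,
                                 dCp_cont=-10.0, T_ref=385.0)


def _helix_points(n: int, axis_xy: tuple[float, float], z0: float,
                  direction: int, phase0: float) -> np.ndarray:
    """C-alpha coordinates of an ideal helix along +/-z."""
    t = np.arange(n)
    theta = np.radians(phase0 + direction * HELIX_TWIST * t)
    x = axis_xy[0] + HELIX_RADIUS * np.cos(theta)
    y = axis_xy[1] + HELIX_RADIUS * np.sin(theta)
    z = z0 + direction * HELIX_RISE * t
    return np.column_stack([x, y, z])


def _equalize_spacing(points: np.ndarray, spacing: float = CA_SPACING,
                      fix_first: bool = True, fix_last: bool = True,
                      n_iter: int = 400) -> np.ndarray:
    """Project a polyline toward equal bond lengths (endpoints fixed)."""
    pts = points.copy()
    n = len(pts)
    if n < 2:
        return pts
    for _ in range(n_iter):
        for k in range(n - 1):
            d = pts[k + 1] - pts[k]
            dist = np.linalg.norm(d)
            if dist < 1e-9:
                d = np.array([0.0, 1e-3, 0.0]); dist = 1e-3
            corr = 0.5 * (dist - spacing) / dist * d
            w0 = 0.0 if (fix_first and k == 0) else 1.0
            w1 = 0.0 if (fix_last and k + 1 == n - 1) else 1.0
            if w0 + w1 == 0:
                continue
            pts[k] += corr * (2 * w0 / (w0 + w1))
            pts[k + 1] -= corr * (2 * w1 / (w0 + w1))
    return pts


def _toy_ca_trace(spec: ToySceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """C-alpha coordinates and per-residue radial (site) directions."""
    n = spec.n_res
    ca = np.full((n, 3), np.nan)
    radial = np.zeros((n, 3))
    helices = sorted(spec.helix_layout)
    z_top = None
    for h, (a, b) in enumerate(helices):
        m = b - a + 1
        x_axis = h * spec.helix_spacing
        direction = 1 if h % 2 == 0 else -1
        if z_top is None:
            z0 = 0.0
        else:
            z0 = z_top if direction == -1 else 0.0
        pts = _helix_points(m, (x_axis, 0.0), z0, direction, phase0=180.0)
        ca[a - 1:b] = pts
        if z_top is None:
            z_top = float(pts[-1, 2])
        rad = pts - np.array([[x_axis, 0.0, 0.0]])
        rad[:, 2] = 0.0
        radial[a - 1:b] = rad / np.linalg.norm(rad, axis=1, keepdims=True)

    # linkers between helices: equal-spacing projection with a seed bulge
    for (a1, b1), (a2, b2) in zip(helices, helices[1:]):
        gap = list(range(b1 + 1, a2))
        if not gap:
            continue
        chain = np.vstack([ca[b1 - 1],
                           np.linspace(ca[b1 - 1], ca[a2 - 1],
                                       len(gap) + 2)[1:-1],
                           ca[a2 - 1]])
        bulge = np.array([0.0, 1.0, 0.0])
        s = np.sin(np.linspace(0, math.pi, len(chain)))
        chain = chain + 2.5 * s[:, None] * bulge[None, :]
        chain[0], chain[-1] = ca[b1 - 1], ca[a2 - 1]
        chain = _equalize_spacing(chain)
        ca[b1:a2 - 1] = chain[1:-1]
        radial[b1:a2 - 1] = np.array([0.0, 1.0, 0.0])

    # tails: straight extensions at CA spacing
    first_a = helices[0][0]
    for k in range(first_a - 1, 0, -1):
        ca[k - 1] = ca[k] + np.array([0.0, 0.0, -CA_SPACING]) * (
            1 if k == first_a - 1 or True else 1)
        radial[k - 1] = np.array([0.0, 1.0, 0.0])
    last_b = helices[-1][1]
    last_dir = 1 if (len(helices) - 1) % 2 == 0 else -1
    for k in range(last_b + 1, spec.n_res + 1):
        ca[k - 1] = ca[k - 2] + np.array([0.0, 0.0, CA_SPACING * last_dir])
        radial[k - 1] = np.array([0.0, 1.0, 0.0])
    return ca, radial


def _place_at_distance(protein: ProteinStructure, dna: DNAPhosphateLattice,
                       direction: np.ndarray, target: float
                       ) -> ProteinStructure:
    """Translate along ``direction`` so the minimum heavy-atom-to-
    phosphate distance equals ``target`` (protein ends up on the
    +direction side of the DNA)."""
    from scipy.optimize import brentq

    def f(s: float) -> float:
        moved = protein.transformed(np.eye(3), s * direction)
        return min_distance(moved, dna) - target

    s_hi = None
    for s in np.arange(0.0, 120.0, 1.0):
        if f(s) > 0:
            s_hi = s
            break
    if s_hi is None:
        raise ValueError("cannot place protein clash-free at the requested "
                         "distance")
    s_lo = max(s_hi - 1.0, 0.0)
    s_star = s_hi if f(s_lo) > 0 else brentq(f, s_lo, s_hi, xtol=1e-4)
    return protein.transformed(np.eye(3), s_star * direction)


def make_toy_dbd(spec: ToySceneSpec | None = None
                 ) -> tuple[ProteinStructure, ContactMap, ChargeSet]:
    """Idealized helical toy domain: C-alpha plus one pseudo side-chain
    charge site per residue; contacts from :func:`build_contact_map`."""
    spec = spec or ToySceneSpec()
    if spec.n_res < 10:
        raise ValueError("n_res must be >= 10")
    ca, radial = _toy_ca_trace(spec)
    residues = []
    for j in range(1, spec.n_res + 1):
        q = spec.charge_pattern.get(j, 0)
        name = "LYS" if q > 0 else ("GLU" if q < 0 else "ALA")
        site = ca[j - 1] + 1.5 * radial[j - 1]
        residues.append(Residue(index=j, name=name,
                                heavy_atoms=np.vstack([ca[j - 1], site]),
                                atom_names=["CA", "SC"],
                                charge_site=site))
    protein = ProteinStructure(residues)
    contacts = build_contact_map(protein, cutoff=spec.contact_cutoff,
                                 min_separation=spec.min_separation)
    charges = assign_charges(protein)
    return protein, contacts, charges


def make_scene(spec: ToySceneSpec | None = None) -> Scene:
    """Toy protein posed against an ideal B-DNA lattice.

    The protein is oriented with its binding face toward the DNA and
    placed so the minimum heavy-atom-to-phosphate distance equals
    ``spec.bound_distance``; the result is clash-free by construction.
    """
    spec = spec or ToySceneSpec()
    protein, contacts, charges = make_toy_dbd(spec)
    dna = build_bdna_phosphates(spec.dna_n_bp)

    # center the protein's z extent on the DNA's
    dz = float(dna.phosphates[:, 2].mean() - protein.coords()[:, 2].mean())
    protein = protein.transformed(np.eye(3), np.array([0.0, 0.0, dz]))
    # slide along +x until the closest approach equals bound_distance
    protein = _place_at_distance(protein, dna, np.array([1.0, 0.0, 0.0]),
                                 spec.bound_distance)
    d = min_distance(protein, dna)
    if not (spec.bound_distance - 0.5 <= d <= spec.bound_distance + 0.5):
        raise ValueError(f"could not place protein at {spec.bound_distance} A "
                         f"(achieved {d:.2f} A)")
    scene = Scene(protein=protein, contacts=contacts, charges=charges,
                  dna=dna, pose=Pose())
    if detect_clash(protein, dna):
        raise ValueError("bound pose clashes with DNA")
    return scene


def make_thermogram(params: VBParameters, baseline, T_grid: Sequence[float],
                    noise_sigma: float = 0.0, seed: int = 0,
                    metadata: dict | None = None) -> Thermogram:
    """Forward-simulated absolute thermogram with i.i.d. Gaussian noise
    of standard deviation ``noise_sigma`` (kJ/mol/K)."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    tg = vb_cp_curve(params, baseline, T_grid, warn_coarse=False)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        tg = Thermogram(tg.temperatures,
                        tg.cp + rng.normal(0.0, noise_sigma, len(tg.cp)),
                        baseline_spec=tg.baseline_spec,
                        metadata=tg.metadata)
    tg.metadata.update(metadata or {})
    tg.metadata.update({"noise_sigma": noise_sigma, "seed": seed})
    return tg


# ---------------------------------------------------------------------------
# Synthetic full-backbone stand-in domain
# ---------------------------------------------------------------------------

_STANDIN_POSITIVE = (10, 13, 17, 28, 31, 35, 52, 55, 59)
_STANDIN_NEGATIVE = (20, 40, 48)


def synthetic_dbd_pdb(n_res: int = 66, seed: int = 0) -> str:
    """PDB text of a SYNTHETIC stand-in for a small helical DNA-binding
    domain (it is not any deposited structure).

    Three-helix bundle at heavy-atom-like resolution (N, CA, C, O, CB
    and a charged-group tip atom on charged residues), with a frustrated
    CytR-like charge composition (net +6).  Deterministic; ``seed``
    perturbs side-chain tips by a few hundredths of an angstrom only, to
    break exact degeneracies.
    """
    if n_res != 66:
        raise ValueError("the stand-in is defined at 66 residues")
    rng = np.random.default_rng(seed)
    helices = ((4, 21), (26, 43), (48, 63))
    axes = ((0.0, 0.0), (10.5, 0.0), (5.25, 9.1))
    ca = np.full((n_res, 3), np.nan)
    radial = np.zeros((n_res, 3))
    z_top = None
    for h, (a, b) in enumerate(helices):
        m = b - a + 1
        direction = 1 if h % 2 == 0 else -1
        z0 = 0.0 if direction == 1 else (z_top if z_top is not None else 0.0)
        pts = _helix_points(m, axes[h], z0, direction, phase0=180.0 + 40.0 * h)
        ca[a - 1:b] = pts
        if z_top is None:
            z_top = float(pts[-1, 2])
        rad = pts - np.array([[axes[h][0], axes[h][1], 0.0]])
        rad[:, 2] = 0.0
        radial[a - 1:b] = rad / np.linalg.norm(rad, axis=1, keepdims=True)
    for (a1, b1), (a2, b2) in zip(helices, helices[1:]):
        gap = list(range(b1 + 1, a2))
        chain = np.linspace(ca[b1 - 1], ca[a2 - 1], len(gap) + 2)
        s = np.sin(np.linspace(0, math.pi, len(chain)))
        chain = chain + 3.0 * s[:, None] * np.array([[0.0, -1.0, 0.0]])
        chain[0], chain[-1] = ca[b1 - 1], ca[a2 - 1]
        chain = _equalize_spacing(chain)
        ca[b1:a2 - 1] = chain[1:-1]
        radial[b1:a2 - 1] = np.array([0.0, -1.0, 0.0])
    for k in range(helices[0][0] - 1, 0, -1):
        ca[k - 1] = ca[k] + np.array([0.0, 0.0, -CA_SPACING])
        radial[k - 1] = np.array([0.0, -1.0, 0.0])
    for k in range(helices[-1][1] + 1, n_res + 1):
        ca[k - 1] = ca[k - 2] + np.array([0.0, 0.0, CA_SPACING])
        radial[k - 1] = np.array([0.0, -1.0, 0.0])

    tip_atom = {"LYS": "NZ", "ARG": "NH1", "GLU": "OE1", "ASP": "OD1"}
    names = {}
    for j in range(1, n_res + 1):
        if j in _STANDIN_POSITIVE:
            names[j] = "LYS" if j % 2 == 0 else "ARG"
        elif j in _STANDIN_NEGATIVE:
            names[j] = "GLU" if j % 2 == 0 else "ASP"
        else:
            names[j] = ("ALA", "LEU", "SER")[j % 3]

    lines = ["REMARK   1 SYNTHETIC STAND-IN HELICAL DNA-BINDING DOMAIN",
             "REMARK   1 GENERATED COORDINATES - NOT A DEPOSITED STRUCTURE",
             "MODEL        1"]
    serial = 1
    tangent = np.gradient(ca, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    for j in range(1, n_res + 1):
        c = ca[j - 1]
        t = tangent[j - 1]
        r = radial[j - 1]
        up = np.cross(t, r)
        atoms = [("N", c - 1.2 * t + 0.8 * r),
                 ("CA", c),
                 ("C", c + 1.2 * t + 0.6 * r),
                 ("O", c + 1.2 * t + 0.6 * r + 1.23 * up)]
        name = names[j]
        if name != "GLY":
            atoms.append(("CB", c + 1.5 * r))
        if name in tip_atom:
            jiggle = 0.03 * rng.standard_normal(3)
            atoms.append((tip_atom[name], c + 3.2 * r + jiggle))
        for atom_name, xyz in atoms:
            lines.append(
                f"ATOM  {serial:5d}  {atom_name:<3s} {name:>3s} A{j:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {atom_name[0]:>2s}"
            )
            serial += 1
    lines += ["ENDMDL", "END"]
    return "\n".join(lines) + "\n"


def make_standin_scene(bound_distance: float = 6.0, n_bp: int = 16,
                       seed: int = 0) -> Scene:
    """Scene built from the synthetic stand-in domain at heavy-atom
    resolution, posed against an ideal B-DNA lattice with the charged
    face toward the DNA."""
    from .structures import read_structure

    protein = read_structure(synthetic_dbd_pdb(seed=seed))
    contacts = build_contact_map(protein, cutoff=5.0, min_separation=2)
    charges = assign_charges(protein)
    dna = build_bdna_phosphates(n_bp)
    dz = float(dna.phosphates[:, 2].mean() - protein.coords()[:, 2].mean())
    protein = protein.transformed(np.eye(3), np.array([0.0, 0.0, dz]))
    # the stand-in's charged face points -y, so approach the DNA from +y
    protein = _place_at_distance(protein, dna, np.array([0.0, 1.0, 0.0]),
                                 bound_distance)
    contacts = build_contact_map(protein, cutoff=5.0, min_separation=2)
    charges = assign_charges(protein)
    return Scene(protein=protein, contacts=contacts, charges=charges, dna=dna,
                 pose=Pose())
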