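"""Protein structures, native contact maps, charges, B-DNA phosphate
lattices and rigid-body poses.

The protein side of the model needs only heavy-atom coordinates grouped by
residue plus, for charged residues, the location of the side-chain charged
group.  The DNA side is reduced to its phosphate charges on an ideal
B-form double helix (axis = z through the origin for generated lattices).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation


class PDBParseError(ValueError):
    """Raised when a PDB source cannot be interpreted."""


#: pH-7 formal charges of the standard amino acids (side chains only;
#: His neutral, no pKa calculation).
PH7_CHARGES: dict[str, int] = {
    "LYS": +1,
    "ARG": +1,
    "ASP": -1,
    "GLU": -1,
}

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Atoms defining the charged-group centroid per charged residue type.
_CHARGE_GROUP_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "CZ"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class Residue:
    """One residue: heavy-atom coordinates plus an optional charge site."""

    index: int
    name: str
    heavy_atoms: np.ndarray  # (k, 3) angstrom
    atom_names: list[str] | None = None
    charge_site: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heavy_atoms = np.asarray(self.heavy_atoms, dtype=float)
        if self.heavy_atoms.ndim != 2 or self.heavy_atoms.shape[1] != 3:
            raise ValueError(f"residue {self.index}: heavy_atoms must be (k, 3)")
        if len(self.heavy_atoms) == 0:
            raise ValueError(f"residue {self.index}: needs at least one heavy atom")
        if not np.all(np.isfinite(self.heavy_atoms)):
            raise ValueError(f"residue {self.index}: non-finite coordinates")
        if self.charge_site is not None:
            self.charge_site = np.asarray(self.charge_site, dtype=float)


@dataclass
class ProteinStructure:
    """An ordered list of residues from one model of a structure file."""

    residues: list[Residue]
    model_id: int = 1

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def coords(self) -> np.ndarray:
        """All heavy-atom coordinates stacked, (n_atoms, 3)."""
        return np.concatenate([r.heavy_atoms for r in self.residues])

    def atom_residue_indices(self) -> np.ndarray:
        """Residue index (1-based model numbering) of every stacked atom."""
        return np.concatenate(
            [np.full(len(r.heavy_atoms), r.index) for r in self.residues]
        )

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    pivot: np.ndarray | None = None) -> "ProteinStructure":
        """Rigidly transformed copy: x -> R (x - pivot) + pivot + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        if pivot is None:
            pivot = self.centroid()
        if not (np.all(np.isfinite(rotation)) and np.all(np.isfinite(translation))):
            raise ValueError("non-finite transform")

        def _apply(x: np.ndarray) -> np.ndarray:
            return (x - pivot) @ rotation.T + pivot + translation

        new = []
        for r in self.residues:
            new.append(
                Residue(
                    index=r.index,
                    name=r.name,
                    heavy_atoms=_apply(r.heavy_atoms),
                    atom_names=None if r.atom_names is None else list(r.atom_names),
                    charge_site=None if r.charge_site is None else _apply(
                        r.charge_site[None, :]
                    )[0],
                )
            )
        return ProteinStructure(new, model_id=self.model_id)


@dataclass
class ContactMap:
    """Native heavy-atom contacts at atom-pair granularity.

    ``pairs[(i, j)]`` (i < j, residue numbering of the source structure)
    is the number of heavy-atom pairs across residues i and j within
    ``cutoff``; the per-contact energy scale of the ensemble model
    multiplies these counts.
    """

    pairs: dict[tuple[int, int], int]
    cutoff: float
    min_sequence_separation: int
    n_residues: int

    def __post_init__(self) -> None:
        for (i, j), c in self.pairs.items():
            if j - i < self.min_sequence_separation:
                raise ValueError(f"pair {(i, j)} violates min separation")
            if c < 1:
                raise ValueError(f"pair {(i, j)} has non-positive count")

    @property
    def n_atom_pairs(self) -> int:
        return int(sum(self.pairs.values()))


@dataclass
class ChargeSet:
    """Residue formal charges (elementary-charge units)."""

    charges: dict[int, int]

    @property
    def net_charge(self) -> int:
        return int(sum(self.charges.values()))

    def nonzero(self) -> dict[int, int]:
        return {i: q for i, q in self.charges.items() if q != 0}


@dataclass
class DNAPhosphateLattice:
    """Phosphate point charges of a DNA duplex.

    Generated lattices are ideal B-form: helical axis = z through the
    origin, no 5'-terminal phosphates, so 2*(n_bp - 1) sites in total.
    """

    phosphates: np.ndarray  # (n, 3) angstrom
    charge_per_phosphate: float = -1.0
    n_bp: int = 0
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phosphates = np.asarray(self.phosphates, dtype=float)

    @property
    def n_phosphates(self) -> int:
        return len(self.phosphates)

    def axis_point(self) -> np.ndarray:
        return np.asarray(self.geometry.get("axis_point", (0.0, 0.0, 0.0)))

    def axis_direction(self) -> np.ndarray:
        d = np.asarray(self.geometry.get("axis_direction", (0.0, 0.0, 1.0)), float)
        return d / np.linalg.norm(d)

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.phosphates, columns=["x", "y", "z"])
        df["charge"] = self.charge_per_phosphate
        df.to_csv(path, index=False)

    def to_xyz(self, path) -> None:
        lines = [str(self.n_phosphates), "B-DNA phosphate lattice"]
        lines += [f"P {x:.3f} {y:.3f} {z:.3f}" for x, y, z in self.phosphates]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass
class Pose:
    """Rigid pose: intrinsic z-y-z Euler rotation (degrees) about the
    protein centroid followed by a translation along a stated approach
    axis.  ``distance_from_bound`` = 0 labels the bound reference pose."""

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: float = 0.0
    distance_from_bound: float = 0.0

    def __post_init__(self) -> None:
        if self.distance_from_bound < 0:
            raise ValueError("distance_from_bound must be >= 0")

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("ZYZ", self.rotation, degrees=True).as_matrix()


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _validate_pdb_lines(text: str) -> None:
    for n, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise PDBParseError(f"line {n}: truncated coordinate record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(f"line {n}: unparsable coordinates") from exc


def read_structure(source, model_id: int = 1) -> ProteinStructure:
    """Read one model of a PDB file into a :class:`ProteinStructure`.

    ``source`` may be a path, raw PDB text, or a file-like object.  Only
    heavy atoms of amino-acid residues are kept; residues are renumbered
    1..n in chain order.  NMR-style multi-model files default to model 1.
    """
    import biotite.structure as bst
    from biotite.structure.io.pdb import PDBFile

    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        text = s if "\n" in s else open(s).read()
    if not text.strip():
        raise PDBParseError("empty PDB source")
    _validate_pdb_lines(text)

    pdb = PDBFile.read(io.StringIO(text))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise PDBParseError("no coordinate records found")
    if not 1 <= model_id <= n_models:
        raise ValueError(
            f"model {model_id} not present; available models: 1..{n_models}"
        )
    atoms = pdb.get_structure(model=model_id)
    mask = bst.filter_amino_acids(atoms) & (atoms.element != "H")
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise PDBParseError("no amino-acid heavy atoms found")

    residues: list[Residue] = []
    seen: dict[tuple, int] = {}
    order: list[tuple] = []
    for chain, res_id, ins in zip(atoms.chain_id, atoms.res_id,
                                  getattr(atoms, "ins_code", [""] * len(atoms))):
        key = (chain, int(res_id), ins)
        if key not in seen:
            seen[key] = len(order)
            order.append(key)
    for new_index, key in enumerate(order, start=1):
        sel = [
            k for k in range(atoms.array_length())
            if (atoms.chain_id[k], int(atoms.res_id[k]),
                getattr(atoms, "ins_code", [""] * len(atoms))[k]) == key
        ]
        residues.append(
            Residue(
                index=new_index,
                name=str(atoms.res_name[sel[0]]),
                heavy_atoms=atoms.coord[sel],
                atom_names=[str(atoms.atom_name[k]) for k in sel],
            )
        )
    return ProteinStructure(residues, model_id=model_id)


# ---------------------------------------------------------------------------
# Contacts and charges
# ---------------------------------------------------------------------------

def build_contact_map(structure: ProteinStructure, cutoff: float = 5.0,
                      min_separation: int = 2) -> ContactMap:
    """Native contacts: all heavy-atom pairs within ``cutoff`` between
    residues at sequence separation >= ``min_separation``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    pairs: dict[tuple[int, int], int] = {}
    if structure.n_residues >= 2:
        coords = structure.coords()
        res_of = structure.atom_residue_indices()
        tree = cKDTree(coords)
        for a, b in tree.query_pairs(cutoff):
            i, j = int(res_of[a]), int(res_of[b])
            if i > j:
                i, j = j, i
            if j - i >= min_separation:
                pairs[(i, j)] = pairs.get((i, j), 0) + 1
    return ContactMap(pairs, cutoff=cutoff, min_sequence_separation=min_separation,
                      n_residues=structure.n_residues)


def assign_charges(structure: ProteinStructure, scheme: str = "ph7") -> ChargeSet:
    """pH-7 formal charges (Lys/Arg +1, Asp/Glu -1, His 0).

    Side effect: residues carrying a charge get ``charge_site`` filled in
    (centroid of the charged group, falling back to the outermost
    side-chain heavy atom) unless a site was already set.
    """
    if scheme != "ph7":
        raise ValueError(f"unknown charge scheme: {scheme}")
    charges: dict[int, int] = {}
    for res in structure.residues:
        name = res.name.upper()
        if name not in STANDARD_RESIDUES:
            warnings.warn(f"unknown residue name {name!r}; assigning charge 0")
            charges[res.index] = 0
            continue
        q = PH7_CHARGES.get(name, 0)
        charges[res.index] = q
        if q != 0 and res.charge_site is None:
            res.charge_site = _charge_site(res)
    return ChargeSet(charges)


def _charge_site(res: Residue) -> np.ndarray:
    if res.atom_names is not None:
        wanted = _CHARGE_GROUP_ATOMS.get(res.name.upper(), ())
        hits = [k for k, nm in enumerate(res.atom_names) if nm in wanted]
        if hits:
            return res.heavy_atoms[hits].mean(axis=0)
        # outermost side-chain heavy atom relative to CA
        side = [k for k, nm in enumerate(res.atom_names) if nm not in _BACKBONE_ATOMS]
        if side:
            try:
                ca = res.heavy_atoms[res.atom_names.index("CA")]
            except ValueError:
                ca = res.heavy_atoms.mean(axis=0)
            d = np.linalg.norm(res.heavy_atoms[side] - ca, axis=1)
            return res.heavy_atoms[side[int(np.argmax(d))]]
    return res.heavy_atoms.mean(axis=0)


# ---------------------------------------------------------------------------
# B-DNA lattice, poses, clashes
# ---------------------------------------------------------------------------

def build_bdna_phosphates(n_bp: int, rise: float = 3.38, twist: float = 36.0,
                          radius: float = 8.91,
                          strand_phase: float = 154.0) -> DNAPhosphateLattice:
    """Ideal B-DNA phosphate double helix along z.

    Two antiparallel strands of n_bp - 1 phosphates each (5'-terminal
    phosphates omitted), all at ``radius`` from the axis, one elementary
    negative charge per phosphate.  ``strand_phase`` sets the azimuthal
    offset of the second strand (controls the groove widths).
    """
    if n_bp < 2:
        raise ValueError("n_bp must be >= 2")
    tw = math.radians(twist)
    ph = math.radians(strand_phase)
    coords = []
    for k in range(1, n_bp):  # strand A, 5'->3' up the axis
        th = k * tw
        coords.append((radius * math.cos(th), radius * math.sin(th), k * rise))
    for k in range(n_bp - 2, -1, -1):  # strand B, antiparallel listing
        th = k * tw + ph
        coords.append((radius * math.cos(th), radius * math.sin(th), k * rise))
    return DNAPhosphateLattice(
        phosphates=np.array(coords),
        charge_per_phosphate=-1.0,
        n_bp=n_bp,
        geometry={"rise": rise, "twist": twist, "radius": radius,
                  "strand_phase": strand_phase,
                  "axis_point": (0.0, 0.0, 0.0),
                  "axis_direction": (0.0, 0.0, 1.0)},
    )


def transform_pose(structure: ProteinStructure, pose: Pose,
                   axis: Sequence[float]) -> ProteinStructure:
    """Apply a rigid pose: rotate about the protein centroid, then
    translate the centroid by ``pose.translation * axis``."""
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-6:
        raise ValueError("axis must be a unit vector")
    return structure.transformed(pose.rotation_matrix(),
                                 pose.translation * axis)


def detect_clash(protein: ProteinStructure, dna: DNAPhosphateLattice,
                 threshold: float = 2.0) -> bool:
    """True iff any protein heavy atom lies strictly within ``threshold``
    of any phosphate."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    tree = cKDTree(dna.phosphates)
    d, _ = tree.query(protein.coords(), k=1)
    return bool(np.min(d) < threshold)


def min_distance(protein: ProteinStructure, dna: DNAPhosphateLattice) -> float:
    """Smallest heavy-atom-to-phosphate distance."""
    tree = cKDTree(dna.phosphates)
    d, _ = tree.query(protein.coords(), k=1)
    return float(np.min(d))


def write_pose_list(poses: Iterable[Pose], path) -> None:
    import pandas as pd

    rows = [
        {"alpha": p.rotation[0], "beta": p.rotation[1], "gamma": p.rotation[2],
         "distance": p.distance_from_bound}
        for p in poses
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
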