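"""Structure I/O and atom typing.

Reads receptors (PDB / PDBQT, fixed-column dialect) and ligand poses
(SDF / MOL2 via RDKit, PDBQT natively), assigns AutoDock-style atom types,
interaction flags and solvation parameters, and counts rotatable bonds with
the AutoDock torsion convention.

Conventions
-----------
* Coordinates are in Å, right-handed, exactly as stored in the files.
* PDBQT partial charges always win; chargeless PDB receptors get template
  charges for ionizable groups during typing.
* First model / highest-occupancy altloc for multi-model PDB files.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .ad4params import (
    COVALENT_RADII,
    ELEMENT_DEFAULT_TYPE,
    TypingError,
    params_for,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TypedAtom",
    "MoleculePose",
    "ReceptorModel",
    "ParseError",
    "TypingError",
    "parse_receptor",
    "parse_ligand",
    "assign_atom_types",
    "count_rotatable_bonds",
    "write_pdbqt",
]


class ParseError(ValueError):
    """Malformed structure file; message names the offending line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TypedAtom:
    """One atom with geometry, typing flags and solvation parameters."""

    serial: int
    element: str
    position: np.ndarray  # (3,) Å
    partial_charge: float = 0.0
    ad4_type: str | None = None
    is_hydrophobic: bool = False
    is_hbond_donor: bool = False
    is_hbond_acceptor: bool = False
    formal_charge: int = 0
    vdw_radius: float = 0.0
    solvation_volume: float = 0.0
    solvation_param: float = 0.0
    # receptor annotations (empty for ligand atoms)
    residue_name: str = ""
    residue_number: int = 0
    chain: str = ""
    atom_name: str = ""
    aromatic: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def validate(self) -> None:
        if self.ad4_type is not None:
            if self.vdw_radius <= 0:
                raise ValueError(f"atom {self.serial}: vdw_radius must be > 0")
            if not (np.isfinite(self.solvation_volume) and np.isfinite(self.solvation_param)):
                raise ValueError(f"atom {self.serial}: solvation fields not finite")
            if self.ad4_type in ("OA", "NA", "SA") and not self.is_hbond_acceptor:
                raise ValueError(f"atom {self.serial}: acceptor type without acceptor flag")

    def to_dict(self) -> dict:
        d = {
            "serial": self.serial,
            "element": self.element,
            "position": [float(x) for x in self.position],
            "partial_charge": self.partial_charge,
            "ad4_type": self.ad4_type,
            "is_hydrophobic": self.is_hydrophobic,
            "is_hbond_donor": self.is_hbond_donor,
            "is_hbond_acceptor": self.is_hbond_acceptor,
            "formal_charge": self.formal_charge,
            "vdw_radius": self.vdw_radius,
            "solvation_volume": self.solvation_volume,
            "solvation_param": self.solvation_param,
            "residue_name": self.residue_name,
            "residue_number": self.residue_number,
            "chain": self.chain,
            "atom_name": self.atom_name,
            "aromatic": self.aromatic,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TypedAtom":
        return cls(**d)


@dataclass
class MoleculePose:
    """A ligand pose: typed atoms, bonds, and its rotatable-bond count."""

    compound_id: str
    atoms: list[TypedAtom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)  # (i, j, order); indices into atoms
    n_rotatable: int = 0

    def validate(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references a missing atom")
        if self.bonds and self.n_rotatable > len(self.bonds):
            raise ValueError("n_rotatable exceeds bond count")
        if self.n_rotatable < 0:
            raise ValueError("n_rotatable must be >= 0")

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def heavy_atoms(self) -> list[TypedAtom]:
        return [a for a in self.atoms if a.is_heavy]

    def to_json(self) -> str:
        return json.dumps(
            {
                "compound_id": self.compound_id,
                "atoms": [a.to_dict() for a in self.atoms],
                "bonds": [list(b) for b in self.bonds],
                "n_rotatable": self.n_rotatable,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MoleculePose":
        d = json.loads(text)
        return cls(
            compound_id=d["compound_id"],
            atoms=[TypedAtom.from_dict(a) for a in d["atoms"]],
            bonds=[tuple(b) for b in d["bonds"]],
            n_rotatable=d["n_rotatable"],
        )


class ReceptorModel:
    """Residue-annotated receptor atoms with a radius neighbor query.

    The neighbor query is backed by a k-d tree built lazily on first use and
    returns exactly the atoms whose center lies within the query radius.
    """

    def __init__(self, atoms: list[TypedAtom]):
        for a in atoms:
            if not a.residue_name:
                raise ValueError(f"receptor atom {a.serial} lacks residue annotation")
        self.atoms = atoms
        self._tree: cKDTree | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def _kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.coordinates)
        return self._tree

    def neighbors(self, point: np.ndarray, radius: float) -> list[int]:
        """Indices of all atoms with center distance <= radius of ``point``."""
        idx = self._kdtree().query_ball_point(np.asarray(point, float), radius)
        return sorted(idx)

    def residues(self) -> list[tuple[str, int, str]]:
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.residue_name, a.residue_number, a.chain), None)
        return list(seen)

    def residue_atoms(self, residue_number: int, chain: str | None = None) -> list[TypedAtom]:
        return [
            a
            for a in self.atoms
            if a.residue_number == residue_number and (chain is None or a.chain == chain)
        ]

    def to_json(self) -> str:
        return json.dumps({"atoms": [a.to_dict() for a in self.atoms]})

    @classmethod
    def from_json(cls, text: str) -> "ReceptorModel":
        d = json.loads(text)
        return cls([TypedAtom.from_dict(a) for a in d["atoms"]])


# ---------------------------------------------------------------------------
# PDB / PDBQT reading
# ---------------------------------------------------------------------------

def _parse_float(token: str, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"line {lineno}: cannot parse {what} field {token!r}") from None


def _element_from_record(line: str, lineno: int) -> str:
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if not elem or any(c.isdigit() for c in elem):
        # fall back on the atom-name column (PDBQT type column may hold AD4 types)
        name = line[12:16].strip()
        elem = "".join(c for c in name if c.isalpha())[:2]
        if len(elem) == 2 and elem.upper() not in ELEMENT_DEFAULT_TYPE:
            elem = elem[0]
    if not elem:
        raise ParseError(f"line {lineno}: cannot determine element")
    return elem.capitalize()


_AD4_FROM_PDBQT = {t.upper(): t for t in ("H", "HD", "C", "A", "N", "NA", "OA", "S",
                                          "SA", "P", "F", "Cl", "Br", "I", "Zn",
                                          "Mg", "Ca", "Mn", "Fe")}

_PDBQT_ELEMENT = {"A": "C", "HD": "H", "NA": "N", "OA": "O", "SA": "S"}


def _read_structure_records(path: str) -> tuple[list[TypedAtom], int, str]:
    """Shared ATOM/HETATM reader; returns (atoms, branch_count, format)."""
    atoms: list[TypedAtom] = []
    branch_count = 0
    fmt = "pdbqt" if str(path).lower().endswith((".pdbqt",)) else "pdb"
    best_altloc: dict[tuple[str, int, str, str], tuple[float, int]] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6].strip()
            if rec == "ENDMDL":
                logger.warning("%s: multiple models; keeping the first", path)
                break
            if rec == "BRANCH":
                branch_count += 1
                continue
            if rec not in ("ATOM", "HETATM"):
                continue
            line = raw.rstrip("\n")
            if len(line) < 54:
                raise ParseError(f"line {lineno}: truncated ATOM record")
            x = _parse_float(line[30:38], lineno, "x-coordinate")
            y = _parse_float(line[38:46], lineno, "y-coordinate")
            z = _parse_float(line[46:54], lineno, "z-coordinate")
            serial_tok = line[6:11].strip()
            serial = int(serial_tok) if serial_tok.isdigit() else len(atoms) + 1
            name = line[12:16].strip()
            altloc = line[16]
            resname = line[17:20].strip() or "UNK"
            chain = line[21].strip() or "A"
            try:
                resnum = int(line[22:26])
            except ValueError:
                raise ParseError(f"line {lineno}: cannot parse residue number "
                                 f"{line[22:26]!r}") from None
            occupancy = 1.0
            if len(line) >= 60 and line[54:60].strip():
                try:
                    occupancy = float(line[54:60])
                except ValueError:
                    occupancy = 1.0

            charge = 0.0
            ad4 = None
            if fmt == "pdbqt" and len(line) >= 76:
                charge = _parse_float(line[70:76], lineno, "partial-charge")
                tok = line[77:79].strip() if len(line) > 77 else ""
                ad4 = _AD4_FROM_PDBQT.get(tok.upper())
            if ad4 is not None:
                element = _PDBQT_ELEMENT.get(ad4, ad4).capitalize()
            else:
                element = _element_from_record(line, lineno)

            atom = TypedAtom(
                serial=serial,
                element=element,
                position=np.array([x, y, z]),
                partial_charge=charge,
                ad4_type=ad4,
                residue_name=resname,
                residue_number=resnum,
                chain=chain,
                atom_name=name,
            )
            key = (name, resnum, chain, resname)
            if altloc not in (" ", ""):
                prev = best_altloc.get(key)
                if prev is not None:
                    if occupancy > prev[0]:
                        atoms[prev[1]] = atom
                        best_altloc[key] = (occupancy, prev[1])
                        logger.warning("line %d: altloc conflict, keeping higher occupancy", lineno)
                    continue
                best_altloc[key] = (occupancy, len(atoms))
            atoms.append(atom)
    return atoms, branch_count, fmt


def parse_receptor(path: str) -> ReceptorModel:
    """Read a PDB or PDBQT receptor and return a typed :class:`ReceptorModel`."""
    atoms, _, fmt = _read_structure_records(path)
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    receptor = ReceptorModel(atoms)
    assign_atom_types(receptor, keep_charges=(fmt == "pdbqt"))
    return receptor


def write_pdbqt(receptor: ReceptorModel, path: str) -> None:
    """Write a receptor as PDBQT (charges and AD4 types preserved)."""
    with open(path, "w") as fh:
        for a in receptor.atoms:
            name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
            fh.write(
                f"ATOM  {a.serial:>5d} {name[:4]:<4s}{a.residue_name:>4s} "
                f"{a.chain:1s}{a.residue_number:>4d}    "
                f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}    {a.partial_charge:6.3f} "
                f"{(a.ad4_type or a.element):<2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# ligand reading
# ---------------------------------------------------------------------------

def _pose_from_rdkit(mol, compound_id: str) -> MoleculePose:
    from rdkit.Chem import AllChem

    try:
        AllChem.ComputeGasteigerCharges(mol)
    except Exception:  # pragma: no cover - charge assignment is best-effort
        pass
    conf = mol.GetConformer()
    atoms: list[TypedAtom] = []
    for rd_atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(rd_atom.GetIdx())
        q = rd_atom.GetDoubleProp("_GasteigerCharge") if rd_atom.HasProp("_GasteigerCharge") else 0.0
        if not np.isfinite(q):
            q = 0.0
        atoms.append(
            TypedAtom(
                serial=rd_atom.GetIdx() + 1,
                element=rd_atom.GetSymbol(),
                position=np.array([pos.x, pos.y, pos.z]),
                partial_charge=q,
                formal_charge=rd_atom.GetFormalCharge(),
                aromatic=rd_atom.GetIsAromatic(),
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), max(1, int(b.GetBondTypeAsDouble())))
        for b in mol.GetBonds()
    ]
    pose = MoleculePose(compound_id=compound_id, atoms=atoms, bonds=bonds)
    pose.n_rotatable = count_rotatable_bonds(pose)
    return pose


def _infer_bonds(atoms: list[TypedAtom], slack: float = 1.25) -> list[tuple[int, int, int]]:
    """Distance-based bond inference for connectivity-free formats."""
    bonds = []
    pos = np.array([a.position for a in atoms])
    if len(atoms) < 2:
        return bonds
    tree = cKDTree(pos)
    for i, j in sorted(tree.query_pairs(r=2.2 * max(COVALENT_RADII.values()))):
        ri = COVALENT_RADII.get(atoms[i].element.upper(), 0.77)
        rj = COVALENT_RADII.get(atoms[j].element.upper(), 0.77)
        if np.linalg.norm(pos[i] - pos[j]) <= slack * (ri + rj):
            bonds.append((i, j, 1))
    return bonds


def parse_ligand(path: str, compound_id: str | None = None) -> MoleculePose:
    """Read a ligand pose from SDF, MOL2 or PDBQT.

    Only the first record of a multi-molecule file is used (a warning is
    logged).  Atoms, bonds and ``n_rotatable`` are populated and typed.
    """
    from rdkit import Chem

    lower = str(path).lower()
    cid = compound_id or str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    if lower.endswith(".sdf") or lower.endswith(".mol"):
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        mols = [m for m in supplier if m is not None]
        if not mols:
            raise ParseError(f"{path}: no parsable molecule")
        if len(mols) > 1:
            logger.warning("%s: %d molecules; taking the first", path, len(mols))
        pose = _pose_from_rdkit(mols[0], cid)
    elif lower.endswith(".mol2"):
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=True)
        if mol is None:
            raise ParseError(f"{path}: no parsable molecule")
        pose = _pose_from_rdkit(mol, cid)
    elif lower.endswith(".pdbqt"):
        atoms, branches, _ = _read_structure_records(path)
        if not atoms:
            raise ParseError(f"{path}: no ATOM/HETATM records")
        for a in atoms:
            a.residue_name = a.residue_name or "LIG"
            # PDBQT carries no formal charges; recover integral charges from
            # the partial-charge column (|q| >= 0.5 rounds to a formal charge)
            if a.element.upper() in ("N", "O") and abs(a.partial_charge) >= 0.5:
                a.formal_charge = int(round(a.partial_charge))
        pose = MoleculePose(
            compound_id=cid,
            atoms=atoms,
            bonds=_infer_bonds(atoms),
            n_rotatable=branches,
        )
    else:
        raise ParseError(f"{path}: unsupported ligand format")

    if not any(a.is_heavy for a in pose.atoms):
        raise ParseError(f"{path}: molecule has no heavy atoms")
    assign_atom_types(pose, keep_charges=lower.endswith(".pdbqt"))
    pose.validate()
    return pose


# ---------------------------------------------------------------------------
# atom typing
# ---------------------------------------------------------------------------

# Receptor typing templates.  For each standard residue: H-bond donor heavy
# atoms, acceptor heavy atoms, formal/partial charge assignments and carbons
# that are NOT hydrophobic because they bind heteroatoms.
_BACKBONE_DONOR = {"N"}
_BACKBONE_ACCEPTOR = {"O", "OXT"}
_POLAR_CARBON = {"C", "CA"}  # carbonyl C; CA borders N and C

_SIDECHAIN: dict[str, dict] = {
    "ALA": {},
    "GLY": {},
    "VAL": {}, "LEU": {}, "ILE": {}, "PRO": {}, "MET": {"polarC": {"CG", "CE"}},
    "PHE": {"aromatic": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}},
    "TYR": {"aromatic": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
            "donor": {"OH"}, "acceptor": {"OH"}, "polarC": {"CZ"}},
    "TRP": {"aromatic": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
            "donor": {"NE1"}, "polarC": {"CD1", "CE2"}},
    "SER": {"donor": {"OG"}, "acceptor": {"OG"}, "polarC": {"CB"}},
    "THR": {"donor": {"OG1"}, "acceptor": {"OG1"}, "polarC": {"CB"}},
    "CYS": {"polarC": {"CB"}},
    "ASN": {"donor": {"ND2"}, "acceptor": {"OD1"}, "polarC": {"CG"}},
    "GLN": {"donor": {"NE2"}, "acceptor": {"OE1"}, "polarC": {"CD"}},
    "ASP": {"acceptor": {"OD1", "OD2"}, "anionO": {"OD1", "OD2"}, "polarC": {"CG"}},
    "GLU": {"acceptor": {"OE1", "OE2"}, "anionO": {"OE1", "OE2"}, "polarC": {"CD"}},
    "LYS": {"donor": {"NZ"}, "cationN": {"NZ"}, "polarC": {"CE"}},
    "ARG": {"donor": {"NE", "NH1", "NH2"}, "cationN": {"NH1", "NH2"},
            "polarC": {"CZ", "CD"}},
    "HIS": {"aromatic": {"CG", "ND1", "CD2", "CE1", "NE2"},
            "donor": {"ND1", "NE2"}, "acceptor": {"ND1", "NE2"},
            "polarC": {"CG", "CD2", "CE1"}},
}


def _type_receptor_atom(atom: TypedAtom, keep_charges: bool) -> None:
    name, res = atom.atom_name, atom.residue_name.upper()
    elem = atom.element.upper()
    tpl = _SIDECHAIN.get(res, {})
    donor = name in _BACKBONE_DONOR | tpl.get("donor", set())
    acceptor = name in _BACKBONE_ACCEPTOR | tpl.get("acceptor", set())
    aromatic = name in tpl.get("aromatic", set())
    formal = 0
    charge = atom.partial_charge
    if name in tpl.get("cationN", set()):
        formal = 1
        if not keep_charges:
            charge = 0.5 if res == "ARG" else 1.0
    if name in tpl.get("anionO", set()):
        formal = -1
        if not keep_charges:
            charge = -0.5

    if elem == "C":
        hydrophobic = not (name in _POLAR_CARBON or name in tpl.get("polarC", set()))
        ad4 = "A" if aromatic else "C"
    elif elem == "N":
        # unknown-residue fallback: N both donor and acceptor
        if res not in _SIDECHAIN and name not in _BACKBONE_DONOR:
            donor = acceptor = True
        ad4 = "NA" if acceptor else "N"
        hydrophobic = False
        if elem == "N" and name in _BACKBONE_DONOR:
            donor = True
    elif elem == "O":
        acceptor = True
        ad4 = "OA"
        hydrophobic = False
    elif elem == "S":
        ad4 = "S"
        hydrophobic = False
    elif elem == "H":
        ad4 = "HD" if donor else "H"
        hydrophobic = False
        donor = acceptor = False
    else:
        key = elem if elem in ELEMENT_DEFAULT_TYPE else elem.capitalize()
        ad4 = ELEMENT_DEFAULT_TYPE.get(elem, None)
        if ad4 is None:
            raise TypingError(f"atom {atom.serial} ({atom.element}): element not in parameter table")
        hydrophobic = elem in ("F", "CL", "BR", "I")
        acceptor = ad4 in ("OA", "NA")

    p = params_for(ad4)
    atom.ad4_type = ad4
    atom.is_hydrophobic = hydrophobic
    atom.is_hbond_donor = donor
    atom.is_hbond_acceptor = acceptor
    atom.formal_charge = formal
    atom.partial_charge = charge
    atom.aromatic = aromatic or atom.aromatic
    atom.vdw_radius = p.vdw_radius
    atom.solvation_volume = p.solvation_volume
    atom.solvation_param = p.solvation_param


def _type_ligand_atom(atom: TypedAtom, neighbors: list[TypedAtom]) -> None:
    elem = atom.element.upper()
    heavy_nbr_elems = {n.element.upper() for n in neighbors if n.is_heavy}
    has_h = any(not n.is_heavy for n in neighbors)
    donor = acceptor = hydrophobic = False

    if elem == "C":
        hydrophobic = heavy_nbr_elems <= {"C", "F", "CL", "BR", "I"}
        ad4 = "A" if atom.aromatic else "C"
    elif elem == "N":
        donor = has_h or atom.formal_charge > 0
        acceptor = atom.formal_charge <= 0
        ad4 = "NA" if acceptor else "N"
    elif elem == "O":
        acceptor = True
        donor = has_h
        ad4 = "OA"
    elif elem == "S":
        ad4 = "S"
    elif elem == "H":
        polar = any(n.element.upper() in ("N", "O", "S") for n in neighbors)
        ad4 = "HD" if polar else "H"
    elif elem in ("F", "CL", "BR", "I"):
        hydrophobic = True
        ad4 = ELEMENT_DEFAULT_TYPE[elem]
    else:
        ad4 = ELEMENT_DEFAULT_TYPE.get(elem)
        if ad4 is None:
            raise TypingError(f"atom {atom.serial} ({atom.element}): element not in parameter table")
        acceptor = ad4 in ("OA", "NA")

    p = params_for(ad4)
    atom.ad4_type = ad4
    atom.is_hydrophobic = hydrophobic
    atom.is_hbond_donor = donor
    atom.is_hbond_acceptor = acceptor
    atom.vdw_radius = p.vdw_radius
    atom.solvation_volume = p.solvation_volume
    atom.solvation_param = p.solvation_param


def assign_atom_types(obj, keep_charges: bool = True):
    """Assign ad4_type, flags, radii and solvation parameters in place.

    Works on either a :class:`MoleculePose` (graph-context rules) or a
    :class:`ReceptorModel` (residue-template rules).  Idempotent.
    """
    if isinstance(obj, ReceptorModel):
        for atom in obj.atoms:
            _type_receptor_atom(atom, keep_charges=keep_charges)
            atom.validate()
        return obj
    if isinstance(obj, MoleculePose):
        nbrs: dict[int, list[TypedAtom]] = {i: [] for i in range(len(obj.atoms))}
        for i, j, _ in obj.bonds:
            nbrs[i].append(obj.atoms[j])
            nbrs[j].append(obj.atoms[i])
        for i, atom in enumerate(obj.atoms):
            _type_ligand_atom(atom, nbrs[i])
            atom.validate()
        return obj
    raise TypeError(f"cannot type object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# rotatable bonds (AutoDock torsion convention)
# ---------------------------------------------------------------------------

def count_rotatable_bonds(molecule: MoleculePose) -> int:
    """Count rotatable bonds: non-ring single bonds between heavy atoms that
    each carry at least one further heavy neighbor; amide C–N excluded.

    This is the AutoDock torsion-tree convention and intentionally differs
    from RDKit's default SMARTS-based count (which also excludes e.g. some
    conjugated singles).
    """
    atoms = molecule.atoms
    heavy = [i for i, a in enumerate(atoms) if a.is_heavy]
    g = nx.Graph()
    g.add_nodes_from(heavy)
    heavy_bonds = {}
    for i, j, order in molecule.bonds:
        if atoms[i].is_heavy and atoms[j].is_heavy:
            g.add_edge(i, j)
            heavy_bonds[frozenset((i, j))] = order
    if g.number_of_edges() == 0:
        return 0
    bridges = set(frozenset(e) for e in nx.bridges(g))

    def heavy_degree(i: int) -> int:
        return g.degree(i)

    def is_amide(i: int, j: int) -> bool:
        # single C-N bond where the C is double-bonded to an O
        for c, n in ((i, j), (j, i)):
            if atoms[c].element.upper() == "C" and atoms[n].element.upper() == "N":
                for k in g.neighbors(c):
                    if k != n and atoms[k].element.upper() == "O":
                        if heavy_bonds.get(frozenset((c, k)), 1) >= 2:
                            return True
        return False

    count = 0
    for key, order in heavy_bonds.items():
        i, j = tuple(key)
        if order != 1:
            continue
        if key not in bridges:  # in a ring
            continue
        if heavy_degree(i) < 2 or heavy_degree(j) < 2:
            continue
        if is_amide(i, j):
            continue
        count += 1
    return count
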