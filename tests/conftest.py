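import numpy as np
import pytest

from empiriscore.scoring import default_profile
from empiriscore.structio import (
    MoleculePose,
    ReceptorModel,
    TypedAtom,
    assign_atom_types,
)


def atom(element, pos, **kw):
    serial = kw.pop("serial", 1)
    return TypedAtom(serial=serial, element=element, position=np.asarray(pos, float), **kw)


def rec_atom(serial, element, pos, resname, resnum, name, chain="A"):
    return TypedAtom(
        serial=serial,
        element=element,
        position=np.asarray(pos, float),
        residue_name=resname,
        residue_number=resnum,
        chain=chain,
        atom_name=name,
    )


def make_receptor(atoms) -> ReceptorModel:
    rec = ReceptorModel(atoms)
    assign_atom_types(rec, keep_charges=False)
    return rec


def make_pose(atoms, bonds=(), compound_id="lig", n_rotatable=0) -> MoleculePose:
    pose = MoleculePose(
        compound_id=compound_id, atoms=atoms, bonds=list(bonds), n_rotatable=n_rotatable
    )
    assign_atom_types(pose)
    return pose


def hexagon(center, radius=1.39, normal_axis=2):
    """Six ring-atom positions in a plane perpendicular to the given axis."""
    center = np.asarray(center, float)
    pts = []
    for k in range(6):
        ang = k * np.pi / 3
        offset = np.zeros(3)
        axes = [i for i in range(3) if i != normal_axis]
        offset[axes[0]] = radius * np.cos(ang)
        offset[axes[1]] = radius * np.sin(ang)
        pts.append(center + offset)
    return pts


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture
def glu_receptor():
    """Minimal Glu172 fragment: CD + two carboxylate oxygens + a backbone O."""
    return make_receptor(
        [
            rec_atom(1, "C", (0.0, 0.0, 0.0), "GLU", 172, "CD"),
            rec_atom(2, "O", (1.2, 0.0, 0.0), "GLU", 172, "OE1"),
            rec_atom(3, "O", (-0.6, 1.0, 0.0), "GLU", 172, "OE2"),
            rec_atom(4, "O", (6.0, 6.0, 6.0), "ALA", 10, "O"),
        ]
    )


@pytest.fixture
def salt_bridge_pose():
    """Protonated piperidinium-style N placed 3.2 Å from Glu OE1."""
    n = atom("N", (1.2 + 3.2, 0.0, 0.0), formal_charge=1, serial=1)
    c = atom("C", (1.2 + 4.7, 0.0, 0.0), serial=2)
    return make_pose([n, c], bonds=[(0, 1, 1)])
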