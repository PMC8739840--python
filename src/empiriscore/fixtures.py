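"""Deterministic synthetic-data generators.

Every generator is a pure function of its spec (seed + parameters); the same
spec yields identical output.  The generated objects satisfy the invariants
of the types they emulate, so every analysis module is testable without any
external structure or affinity download.

Scales mirror the study conditions: calibration sets default to 19 records ×
9 terms with term sums placing ΔG in the −6 to −12 kcal/mol range, contact
panels default to 19 compounds, and planted correlations sit near −0.45.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibrate import CalibrationRecord
from .scoring import ScoringProfile, default_profile, torsion_divisor
from .structio import MoleculePose, ReceptorModel, TypedAtom, assign_atom_types
from .thermo_pharm import BindingCurve
from .mdcorr import ContactMatrix

__all__ = [
    "FixtureSpec",
    "make_toy_complex",
    "make_calibration_dataset",
    "make_contact_dataset",
    "make_binding_curve",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Seed plus free-form size / noise / planted-signal parameters."""

    seed: int
    params: dict = field(default_factory=dict)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


class GenerationError(RuntimeError):
    """Geometry constraints cannot be satisfied."""


# ---------------------------------------------------------------------------
# toy complexes
# ---------------------------------------------------------------------------

_RESIDUE_CYCLE = ("ALA", "LEU", "VAL", "SER", "GLU", "LYS", "PHE", "THR", "GLY", "ILE")


def _random_typed_atom(rng, serial, center, spread, fractions) -> TypedAtom:
    """One ligand-style atom; element drawn from hydrophobic/donor/acceptor
    class fractions (remainder: plain carbon with a polar neighbor flag off)."""
    u = rng.random()
    pos = center + rng.normal(0.0, spread, 3)
    f_h = fractions.get("hydrophobic", 0.5)
    f_d = fractions.get("donor", 0.15)
    f_a = fractions.get("acceptor", 0.2)
    f_c = fractions.get("charged", 0.05)
    atom = TypedAtom(serial=serial, element="C", position=pos)
    if u < f_h:
        atom.element = "C"
    elif u < f_h + f_d:
        atom.element = "N"
        atom.formal_charge = 0
    elif u < f_h + f_d + f_a:
        atom.element = "O"
    elif u < f_h + f_d + f_a + f_c:
        atom.element = "N"
        atom.formal_charge = 1
        atom.partial_charge = 1.0
    else:
        atom.element = "C"
    return atom


def make_toy_complex(
    seed: int,
    n_ligand_atoms: int = 12,
    n_receptor_atoms: int = 60,
    min_separation: float = 2.5,
    fractions: dict | None = None,
    plant_salt_bridge: bool = False,
    salt_bridge_dist: float = 3.2,
) -> tuple[MoleculePose, ReceptorModel]:
    """Typed random atom clouds with a guaranteed closest-approach distance.

    The receptor cloud sits in a shell around the origin; the ligand cloud is
    placed so no intermolecular pair comes closer than ``min_separation`` Å.
    With ``plant_salt_bridge`` a cationic ligand N is placed exactly
    ``salt_bridge_dist`` Å from a Glu carboxylate oxygen.
    """
    if n_ligand_atoms < 1 or n_receptor_atoms < 1:
        raise GenerationError("atom counts must be >= 1")
    if min_separation < 0:
        raise GenerationError("min_separation must be >= 0")
    rng = np.random.default_rng(seed)
    fr = fractions or {}

    rec_atoms: list[TypedAtom] = []
    for i in range(n_receptor_atoms):
        res = _RESIDUE_CYCLE[(i // 4) % len(_RESIDUE_CYCLE)]
        names = {"ALA": ("N", "CA", "C", "O"), "LEU": ("CA", "CB", "CD1", "O"),
                 "VAL": ("CA", "CB", "CG1", "N"), "SER": ("CA", "OG", "N", "O"),
                 "GLU": ("CD", "OE1", "OE2", "CA"), "LYS": ("NZ", "CE", "CA", "O"),
                 "PHE": ("CG", "CD1", "CE1", "CZ"), "THR": ("OG1", "CB", "CA", "N"),
                 "GLY": ("N", "CA", "C", "O"), "ILE": ("CB", "CG1", "CD1", "CA")}[res]
        rec_atoms.append(
            TypedAtom(
                serial=i + 1,
                element="".join(c for c in names[i % 4] if c.isalpha())[0],
                position=rng.normal(0.0, 6.0, 3),
                residue_name=res,
                residue_number=(i // 4) + 1,
                chain="A",
                atom_name=names[i % 4],
            )
        )
    receptor = ReceptorModel(rec_atoms)
    assign_atom_types(receptor, keep_charges=False)

    # place the ligand cloud along +x until the separation constraint holds
    rec_xyz = receptor.coordinates
    lig_atoms = [
        _random_typed_atom(rng, i + 1, np.zeros(3), 2.0, fr) for i in range(n_ligand_atoms)
    ]
    lig_xyz = np.array([a.position for a in lig_atoms])
    offset = 0.0
    for _ in range(200):
        d = np.linalg.norm(
            (lig_xyz + np.array([offset, 0.0, 0.0]))[:, None, :] - rec_xyz[None, :, :],
            axis=-1,
        ).min()
        if d >= min_separation:
            break
        offset += max(min_separation - d, 0.5)
    else:
        raise GenerationError("could not satisfy separation constraint")
    for a, p in zip(lig_atoms, lig_xyz + np.array([offset, 0.0, 0.0])):
        a.position = p

    pose = MoleculePose(compound_id=f"toy-{seed}", atoms=lig_atoms, bonds=[], n_rotatable=0)
    assign_atom_types(pose)

    if plant_salt_bridge:
        glu_o = next(
            a for a in receptor.atoms
            if a.residue_name == "GLU" and a.atom_name in ("OE1", "OE2")
        )
        nplus = next((a for a in pose.atoms if a.formal_charge >= 1), None)
        if nplus is None:
            nplus = pose.atoms[0]
            nplus.element = "N"
            nplus.formal_charge = 1
            nplus.partial_charge = 1.0
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        nplus.position = glu_o.position + salt_bridge_dist * direction
        assign_atom_types(pose)
    return pose, receptor


# ---------------------------------------------------------------------------
# calibration datasets
# ---------------------------------------------------------------------------

def default_true_weights() -> np.ndarray:
    return default_profile().weights


def make_calibration_dataset(
    seed: int,
    n_records: int = 19,
    true_weights: np.ndarray | None = None,
    noise_sd: float = 0.0,
    torsion_weight: float = 1.923,
    n_censored: int = 0,
) -> tuple[list[CalibrationRecord], dict]:
    """Seeded term vectors with ΔG = weighted model + Gaussian noise.

    Term-value magnitudes are scaled per term so that the noiseless weighted
    sums land in the −6 to −12 kcal/mol range under the default calibrated
    weights.  Returns (records, truth) with the generating weights bundled.
    """
    w = np.asarray(true_weights if true_weights is not None else default_true_weights(), float)
    n_terms = w.size
    if n_records < n_terms:
        raise ValueError("need at least as many records as terms")
    rng = np.random.default_rng(seed)

    # per-term scales chosen so each weighted contribution is O(1) kcal/mol
    scales = np.where(np.abs(w) > 1e-12, 1.0 / np.maximum(np.abs(w), 1e-12), 1.0)
    records = []
    for k in range(n_records):
        # draw raw shapes, then rescale so the noiseless model lands in the
        # realistic binding range (-6 to -12 kcal/mol)
        n_rot = int(rng.integers(0, 9))
        div = torsion_divisor(torsion_weight, n_rot)
        while True:
            tv = rng.uniform(0.4, 1.6, n_terms) * scales
            dg0 = float(w @ tv) / div
            if dg0 < -0.1:
                break
        target = float(rng.uniform(-12.0, -6.0))
        tv = tv * (target / dg0)
        dg = target + (float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0)
        records.append(
            CalibrationRecord(
                compound_id=f"syn-{k + 1}",
                term_values=tv,
                n_rotatable=n_rot,
                dg_exp=dg,
                censored=k >= n_records - n_censored,
            )
        )
    truth = {"weights": w, "torsion_weight": torsion_weight, "noise_sd": noise_sd}
    return records, truth


# ---------------------------------------------------------------------------
# contact datasets
# ---------------------------------------------------------------------------

def make_contact_dataset(
    seed: int,
    planted_rho: float = -0.45,
    planted_residue: str = "GLU172:A",
    n_compounds: int = 19,
    n_frames: int = 250,
    n_residues: int = 8,
    ki_range_nM: tuple[float, float] = (1.0, 5000.0),
) -> tuple[list[ContactMatrix], "np.ndarray", dict]:
    """Contact matrices with one residue's frequency correlated with affinity.

    The planted residue's per-compound contact probability is an affine map of
    a variable constructed to have population correlation ``planted_rho``
    against log10(Ki); all other residues are independent.  Returns
    (matrices, affinities, truth); affinities is a pandas Series of Ki nM.
    """
    import pandas as pd

    if abs(planted_rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if n_compounds < 3:
        raise ValueError("need at least 3 compounds")
    rng = np.random.default_rng(seed)

    log_ki = rng.uniform(np.log10(ki_range_nM[0]), np.log10(ki_range_nM[1]), n_compounds)
    z = (log_ki - log_ki.mean()) / log_ki.std()
    noise = rng.normal(size=n_compounds)
    noise = (noise - noise.mean()) / noise.std()
    # remove the component of noise along z so the construction is exact
    noise = noise - (noise @ z) / (z @ z) * z
    noise /= np.sqrt((noise**2).mean())
    y = planted_rho * z + np.sqrt(1.0 - planted_rho**2) * noise
    planted_p = np.clip(0.5 + 0.15 * y, 0.02, 0.98)

    labels = [planted_residue] + [f"RES{i + 1}:A" for i in range(n_residues - 1)]
    other_p = rng.uniform(0.1, 0.9, size=(n_compounds, n_residues - 1))

    matrices = []
    compound_ids = [f"cpd-{i + 1}" for i in range(n_compounds)]
    for c in range(n_compounds):
        probs = np.concatenate([[planted_p[c]], other_p[c]])
        mat = (rng.random((n_frames, n_residues)) < probs).astype(int)
        matrices.append(
            ContactMatrix(compound_id=compound_ids[c], matrix=mat, residue_labels=labels)
        )
    affinities = pd.Series(10.0**log_ki, index=compound_ids, name="ki_nM")
    truth = {"rho": planted_rho, "residue": planted_residue, "planted_p": planted_p}
    return matrices, affinities, truth


# ---------------------------------------------------------------------------
# binding curves
# ---------------------------------------------------------------------------

def make_binding_curve(
    seed: int,
    bottom: float = 0.0,
    top: float = 1.0,
    ic50_nM: float = 50.0,
    hill: float = 1.0,
    noise_sd: float = 0.0,
    n_points: int = 11,
    span_decades: float = 5.0,
    n_replicates: int = 3,
) -> BindingCurve:
    """4PL response over a half-log concentration grid centered on the IC50.

    Defaults mirror a competition-binding assay design: 11 concentrations
    spanning five decades, each measured in triplicate with independent
    Gaussian noise.
    """
    if ic50_nM <= 0:
        raise ValueError("IC50 must be positive")
    if n_replicates < 1:
        raise ValueError("need at least one replicate per concentration")
    rng = np.random.default_rng(seed)
    logs = np.linspace(
        np.log10(ic50_nM) - span_decades / 2, np.log10(ic50_nM) + span_decades / 2, n_points
    )
    x = np.repeat(10.0**logs, n_replicates)  # nM
    y = bottom + (top - bottom) / (1.0 + (x / ic50_nM) ** hill)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, x.size)
    return BindingCurve(concentrations=x, responses=y)
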