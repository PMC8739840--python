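"""MD contact-frequency and pose-stability analysis.

Builds binary frames × residues contact matrices from trajectory snapshots,
converts them to per-residue contact frequencies, correlates frequencies with
compound affinity (Pearson r against log10 Ki across a compound panel), and
computes heavy-atom RMSD stability series with optional rigid superposition.

Frames are stored 0-based internally; reports label them 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import MoleculePose, ReceptorModel

__all__ = [
    "ContactMatrix",
    "CorrelationReport",
    "contact_frequencies",
    "residue_affinity_correlation",
    "pose_stability_rmsd",
    "build_contact_matrix",
]


@dataclass
class ContactMatrix:
    """Binary (frames × residues) ligand–residue contact matrix."""

    compound_id: str
    matrix: np.ndarray
    residue_labels: list[str]
    frame_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (frames × residues)")
        if self.matrix.shape[1] != len(self.residue_labels):
            raise ValueError("residue label count mismatch")
        if len(set(self.residue_labels)) != len(self.residue_labels):
            raise ValueError("residue labels must be unique")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("binary contact matrix must contain only 0/1")
        if not self.frame_indices:
            self.frame_indices = list(range(self.matrix.shape[0]))

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    def sparsity(self) -> float:
        """Fraction of zero entries — the 'sparser matrix' comparison."""
        return float(1.0 - self.matrix.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=[i + 1 for i in self.frame_indices],  # 1-based frame labels
            columns=self.residue_labels,
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index_label="frame")

    @classmethod
    def from_csv(cls, path: str, compound_id: str | None = None) -> "ContactMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            compound_id=compound_id or str(path),
            matrix=df.to_numpy(dtype=int),
            residue_labels=[str(c) for c in df.columns],
            frame_indices=[int(i) - 1 for i in df.index],
        )


@dataclass
class CorrelationReport:
    residue_labels: list[str]
    r: np.ndarray                 # Pearson r; NaN where undefined
    defined: np.ndarray           # bool mask
    n_compounds: int
    affinity_scale: str = "log10(Ki nM)"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": self.residue_labels, "pearson_r": self.r, "defined": self.defined}
        )

    def top(self, k: int = 2) -> pd.DataFrame:
        df = self.to_frame()[self.defined]
        return df.reindex(df.pearson_r.abs().sort_values(ascending=False).index).head(k)


def contact_frequencies(matrix: ContactMatrix) -> pd.Series:
    """Per-residue contact frequency: contact frames / total frames, in [0,1]."""
    if matrix.n_frames < 1:
        raise ValueError("contact matrix has no frames")
    return pd.Series(
        matrix.matrix.mean(axis=0), index=matrix.residue_labels, name=matrix.compound_id
    )


def residue_affinity_correlation(
    frequencies: pd.DataFrame, affinities_nM: pd.Series, scale: str = "log10"
) -> CorrelationReport:
    """Pearson r between per-residue contact frequency and affinity.

    ``frequencies`` is compounds × residues; affinities are Ki in nM indexed
    by compound.  Correlation is computed against log10(Ki), so negative r
    means higher affinity ↔ more frequent contact.  Residues whose frequency
    does not vary are flagged undefined (NaN), never reported as r = 0.
    """
    if scale != "log10":
        raise ValueError("only the log10 affinity scale is supported")
    common = frequencies.index.intersection(affinities_nM.index)
    if len(common) != len(frequencies.index) or len(common) != len(affinities_nM.index):
        raise ValueError("frequency matrix and affinity vector index mismatch")
    if len(common) < 3:
        raise ValueError("need at least 3 compounds")
    aff = affinities_nM.loc[common].to_numpy(float)
    if np.any(aff <= 0):
        raise ValueError("affinities must be positive")
    y = np.log10(aff)
    F = frequencies.loc[common].to_numpy(float)

    yc = y - y.mean()
    Fc = F - F.mean(axis=0)
    f_ss = (Fc**2).sum(axis=0)
    y_ss = float((yc**2).sum())
    defined = (f_ss > 0) & (y_ss > 0)
    r = np.full(F.shape[1], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = Fc.T @ yc
        r[defined] = num[defined] / np.sqrt(f_ss[defined] * y_ss)
    return CorrelationReport(
        residue_labels=list(frequencies.columns),
        r=r,
        defined=defined,
        n_compounds=len(common),
    )


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotate/translate P onto Q (both n×3), returning the moved P."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return P0 @ R.T + qc


def pose_stability_rmsd(
    frames: list[np.ndarray], reference_index: int = 0, superpose: bool = False
) -> np.ndarray:
    """Per-frame heavy-atom RMSD (Å) against a reference frame.

    ``frames`` are (n_atoms × 3) coordinate arrays in identical atom order.
    With ``superpose`` each frame is rigidly fitted to the reference first,
    making the series invariant to global rigid motion.
    """
    arrs = [np.asarray(f, float) for f in frames]
    if not arrs:
        raise ValueError("no frames")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all frames must have identical atom count and order")
    ref = arrs[reference_index]
    out = np.empty(len(arrs))
    for k, a in enumerate(arrs):
        moved = _kabsch(a, ref) if superpose else a
        out[k] = float(np.sqrt(((moved - ref) ** 2).sum(axis=1).mean()))
    return out


def build_contact_matrix(
    trajectory_frames: list[np.ndarray],
    receptor: ReceptorModel,
    compound_id: str = "ligand",
    contact_cutoff: float = 3.5,
    ligand_is_heavy: np.ndarray | None = None,
) -> ContactMatrix:
    """Binary contacts: entry (f, residue) = 1 iff any ligand heavy atom lies
    within ``contact_cutoff`` Å of any heavy atom of that residue in frame f.

    ``trajectory_frames`` are per-frame ligand coordinate arrays aligned to
    the receptor frame; ``ligand_is_heavy`` masks heavy atoms (default: all).
    """
    from scipy.spatial import cKDTree

    residues = receptor.residues()
    labels = [f"{name}{num}:{ch}" for name, num, ch in residues]
    res_index = {res: k for k, res in enumerate(residues)}
    heavy_idx = [i for i, a in enumerate(receptor.atoms) if a.is_heavy]
    rec_coords = np.array([receptor.atoms[i].position for i in heavy_idx])
    rec_res = [
        res_index[(receptor.atoms[i].residue_name, receptor.atoms[i].residue_number,
                   receptor.atoms[i].chain)]
        for i in heavy_idx
    ]
    tree = cKDTree(rec_coords)

    mat = np.zeros((len(trajectory_frames), len(residues)), dtype=int)
    for f, coords in enumerate(trajectory_frames):
        coords = np.asarray(coords, float)
        if ligand_is_heavy is not None:
            coords = coords[np.asarray(ligand_is_heavy, bool)]
        for hits in tree.query_ball_point(coords, contact_cutoff):
            for h in hits:
                mat[f, rec_res[h]] = 1
    return ContactMatrix(compound_id=compound_id, matrix=mat, residue_labels=labels)
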