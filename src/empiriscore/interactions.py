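"""Ligand–receptor interaction typing.

Detects the contact classes used in 2D interaction diagrams — salt bridges,
longer-range electrostatics, conventional and C–H hydrogen bonds, π–π
stacking and hydrophobic contacts — and assembles them into a deterministic
per-pose fingerprint.  Pose lists can be filtered by a required salt bridge.

All cutoffs are conventional defaults and configurable; they are geometric
criteria on heavy-atom (or explicit-H) distances, not energy models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .structio import MoleculePose, ReceptorModel, TypedAtom

__all__ = [
    "InteractionEvent",
    "InteractionFingerprint",
    "FingerprintConfig",
    "detect_salt_bridges",
    "detect_hbonds",
    "detect_pi_pi",
    "detect_hydrophobic",
    "fingerprint",
    "filter_poses_by_salt_bridge",
]

KINDS = ("salt_bridge", "electrostatic", "hbond", "ch_hbond", "pi_pi", "hydrophobic")

#: receptor aromatic ring atom names per residue
_AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

_CARBOXYLATE_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


@dataclass
class InteractionEvent:
    kind: str
    ligand_atoms: tuple[int, ...]       # ligand atom indices
    residue_name: str
    residue_number: int
    chain: str
    receptor_atoms: tuple[int, ...]     # receptor atom indices
    distance: float                     # Å
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


@dataclass
class InteractionFingerprint:
    pose_id: str
    events: list[InteractionEvent]
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = sorted(
            self.events, key=lambda e: (e.residue_number, KINDS.index(e.kind), e.distance)
        )
        self.counts = {k: sum(1 for e in self.events if e.kind == k) for k in KINDS}

    def to_dict(self) -> dict:
        return {
            "pose_id": self.pose_id,
            "counts": self.counts,
            "events": [
                {
                    "kind": e.kind,
                    "residue": f"{e.residue_name}{e.residue_number}:{e.chain}",
                    "ligand_atoms": list(e.ligand_atoms),
                    "receptor_atoms": list(e.receptor_atoms),
                    "distance": round(e.distance, 3),
                    **({"geometry": e.geometry} if e.geometry else {}),
                }
                for e in self.events
            ],
        }


@dataclass
class FingerprintConfig:
    salt_bridge_max: float = 4.0
    electrostatic_max: float = 5.5      # longer-range charged-pair tier
    hbond_heavy_max: float = 3.5
    hbond_h_max: float = 2.8
    ch_hbond_enabled: bool = True
    ch_h_max: float = 2.8
    ch_heavy_max: float = 3.7
    pipi_centroid_max: float = 5.5
    pipi_parallel_angle: float = 30.0   # degrees; above 90-this => T-shaped
    hydrophobic_max: float = 4.5
    enabled: tuple = KINDS


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def _cationic_nitrogens(pose: MoleculePose) -> list[int]:
    return [
        i
        for i, a in enumerate(pose.atoms)
        if a.element.upper() == "N" and a.formal_charge >= 1
    ]


def _receptor_carboxylate_oxygens(receptor: ReceptorModel):
    for idx, a in enumerate(receptor.atoms):
        names = _CARBOXYLATE_O.get(a.residue_name.upper())
        if names and a.atom_name in names:
            yield idx, a


def detect_salt_bridges(
    pose: MoleculePose,
    receptor: ReceptorModel,
    max_dist: float = 4.0,
    kind: str = "salt_bridge",
) -> list[InteractionEvent]:
    """One event per (cationic ligand N, Asp/Glu carboxylate) pair within
    ``max_dist`` Å; the closest carboxylate oxygen distance is reported."""
    events = []
    by_residue: dict[tuple, list[tuple[int, TypedAtom]]] = {}
    for idx, a in _receptor_carboxylate_oxygens(receptor):
        by_residue.setdefault((a.residue_name, a.residue_number, a.chain), []).append((idx, a))
    for ni in _cationic_nitrogens(pose):
        npos = pose.atoms[ni].position
        for (resname, resnum, chain), oxygens in by_residue.items():
            dists = [(_dist(npos, a.position), idx) for idx, a in oxygens]
            d, oidx = min(dists)
            if d <= max_dist:
                events.append(
                    InteractionEvent(
                        kind=kind,
                        ligand_atoms=(ni,),
                        residue_name=resname,
                        residue_number=resnum,
                        chain=chain,
                        receptor_atoms=(oidx,),
                        distance=d,
                    )
                )
    return events


def _attached_hydrogens(pose: MoleculePose, heavy_idx: int) -> list[int]:
    out = []
    for i, j, _ in pose.bonds:
        if i == heavy_idx and not pose.atoms[j].is_heavy:
            out.append(j)
        elif j == heavy_idx and not pose.atoms[i].is_heavy:
            out.append(i)
    return out


def _ch_donor_carbons(pose: MoleculePose) -> list[int]:
    """Activated C–H donors: aromatic carbons and carbons alpha to a carbonyl."""
    carbonyl_c = set()
    order = {frozenset((i, j)): o for i, j, o in pose.bonds}
    adj: dict[int, list[int]] = {}
    for i, j, _ in pose.bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    for i, a in enumerate(pose.atoms):
        if a.element.upper() == "C":
            for j in adj.get(i, []):
                if pose.atoms[j].element.upper() == "O" and order.get(frozenset((i, j)), 1) >= 2:
                    carbonyl_c.add(i)
    donors = set()
    for i, a in enumerate(pose.atoms):
        if a.element.upper() != "C":
            continue
        if a.aromatic:
            donors.add(i)
        for j in adj.get(i, []):
            if j in carbonyl_c:
                donors.add(i)
    return sorted(donors)


def detect_hbonds(
    pose: MoleculePose,
    receptor: ReceptorModel,
    heavy_max: float = 3.5,
    h_max: float = 2.8,
    ch_enabled: bool = True,
    ch_h_max: float = 2.8,
    ch_heavy_max: float = 3.7,
) -> list[InteractionEvent]:
    """Conventional donor–acceptor hydrogen bonds plus optional activated
    C–H bonds.

    Distances are H···acceptor when an explicit hydrogen is present (flag
    ``geometry['distance_type'] = 'H-acceptor'``), otherwise heavy–heavy with
    the ``'heavy-heavy'`` flag.  No angle criterion is applied without
    explicit hydrogens.
    """
    events = []
    rec_acceptors = [(i, a) for i, a in enumerate(receptor.atoms) if a.is_hbond_acceptor and a.is_heavy]
    rec_donors = [(i, a) for i, a in enumerate(receptor.atoms) if a.is_hbond_donor and a.is_heavy]

    def _emit(kind, lig_atoms, ridx, ra, d, dtype):
        events.append(
            InteractionEvent(
                kind=kind,
                ligand_atoms=tuple(lig_atoms),
                residue_name=ra.residue_name,
                residue_number=ra.residue_number,
                chain=ra.chain,
                receptor_atoms=(ridx,),
                distance=d,
                geometry={"distance_type": dtype},
            )
        )

    # ligand donor -> receptor acceptor
    for li, la in enumerate(pose.atoms):
        if not (la.is_heavy and la.is_hbond_donor):
            continue
        hs = _attached_hydrogens(pose, li)
        for ridx, ra in rec_acceptors:
            d_heavy = _dist(la.position, ra.position)
            if d_heavy > heavy_max:
                continue
            if hs:
                d_h, hi = min((_dist(pose.atoms[h].position, ra.position), h) for h in hs)
                if d_h <= h_max:
                    _emit("hbond", (li, hi), ridx, ra, d_h, "H-acceptor")
            else:
                _emit("hbond", (li,), ridx, ra, d_heavy, "heavy-heavy")

    # receptor donor -> ligand acceptor (heavy-heavy; receptor H rarely present)
    for li, la in enumerate(pose.atoms):
        if not (la.is_heavy and la.is_hbond_acceptor):
            continue
        for ridx, ra in rec_donors:
            d_heavy = _dist(la.position, ra.position)
            if d_heavy <= heavy_max:
                _emit("hbond", (li,), ridx, ra, d_heavy, "heavy-heavy")

    if ch_enabled:
        for ci in _ch_donor_carbons(pose):
            ca = pose.atoms[ci]
            hs = _attached_hydrogens(pose, ci)
            for ridx, ra in rec_acceptors:
                if hs:
                    d_h, hi = min((_dist(pose.atoms[h].position, ra.position), h) for h in hs)
                    if d_h <= ch_h_max:
                        _emit("ch_hbond", (ci, hi), ridx, ra, d_h, "H-acceptor")
                else:
                    d_heavy = _dist(ca.position, ra.position)
                    if d_heavy <= ch_heavy_max:
                        _emit("ch_hbond", (ci,), ridx, ra, d_heavy, "heavy-heavy")
    return events


def _ligand_aromatic_rings(pose: MoleculePose) -> list[list[int]]:
    g = nx.Graph()
    aromatic = {i for i, a in enumerate(pose.atoms) if a.aromatic and a.is_heavy}
    for i, j, _ in pose.bonds:
        if i in aromatic and j in aromatic:
            g.add_edge(i, j)
    rings = []
    for cyc in nx.cycle_basis(g):
        if 5 <= len(cyc) <= 6:
            rings.append(sorted(cyc))
    return rings


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[-1]  # normal = direction of least variance


def detect_pi_pi(
    pose: MoleculePose,
    receptor: ReceptorModel,
    centroid_max: float = 5.5,
    parallel_angle: float = 30.0,
) -> list[InteractionEvent]:
    """Ring–ring stacking between ligand aromatic rings and Phe/Tyr/Trp/His
    side chains; annotated parallel (interplanar angle <= ``parallel_angle``)
    or T-shaped (>= 90 − ``parallel_angle``), otherwise tilted."""
    events = []
    lig_rings = _ligand_aromatic_rings(pose)
    if not lig_rings:
        return events
    # receptor rings grouped by residue
    rec_rings: dict[tuple, list[int]] = {}
    for idx, a in enumerate(receptor.atoms):
        names = _AROMATIC_RING_ATOMS.get(a.residue_name.upper())
        if names and a.atom_name in names:
            rec_rings.setdefault((a.residue_name, a.residue_number, a.chain), []).append(idx)
    for ring in lig_rings:
        lc, ln = _ring_plane(np.array([pose.atoms[i].position for i in ring]))
        for (resname, resnum, chain), idxs in rec_rings.items():
            if len(idxs) < 5:
                continue
            rc, rn = _ring_plane(np.array([receptor.atoms[i].position for i in idxs]))
            d = _dist(lc, rc)
            if d > centroid_max:
                continue
            cosang = abs(float(np.dot(ln, rn)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle <= parallel_angle:
                orientation = "parallel"
            elif angle >= 90.0 - parallel_angle:
                orientation = "t_shaped"
            else:
                orientation = "tilted"
            events.append(
                InteractionEvent(
                    kind="pi_pi",
                    ligand_atoms=tuple(ring),
                    residue_name=resname,
                    residue_number=resnum,
                    chain=chain,
                    receptor_atoms=tuple(sorted(idxs)),
                    distance=d,
                    geometry={"interplanar_angle": angle, "orientation": orientation},
                )
            )
    return events


def detect_hydrophobic(
    pose: MoleculePose, receptor: ReceptorModel, max_dist: float = 4.5
) -> list[InteractionEvent]:
    """One event per (hydrophobic ligand atom, residue with a hydrophobic atom
    within ``max_dist``); deduplicated per residue with the closest pair kept."""
    best: dict[tuple, tuple[float, int, int]] = {}
    for li, la in enumerate(pose.atoms):
        if not (la.is_heavy and la.is_hydrophobic):
            continue
        for ridx, ra in enumerate(receptor.atoms):
            if not (ra.is_heavy and ra.is_hydrophobic):
                continue
            d = _dist(la.position, ra.position)
            if d > max_dist:
                continue
            key = (ra.residue_name, ra.residue_number, ra.chain)
            if key not in best or d < best[key][0]:
                best[key] = (d, li, ridx)
    return [
        InteractionEvent(
            kind="hydrophobic",
            ligand_atoms=(li,),
            residue_name=resname,
            residue_number=resnum,
            chain=chain,
            receptor_atoms=(ridx,),
            distance=d,
        )
        for (resname, resnum, chain), (d, li, ridx) in best.items()
    ]


def fingerprint(
    pose: MoleculePose, receptor: ReceptorModel, config: FingerprintConfig | None = None
) -> InteractionFingerprint:
    """Union of all enabled detectors with deterministic event ordering."""
    cfg = config or FingerprintConfig()
    events: list[InteractionEvent] = []
    if "salt_bridge" in cfg.enabled:
        events += detect_salt_bridges(pose, receptor, max_dist=cfg.salt_bridge_max)
    if "electrostatic" in cfg.enabled:
        # the longer-range charged-pair tier, excluding pairs already counted
        # as salt bridges
        close = {
            (e.ligand_atoms, e.residue_number, e.chain)
            for e in events
            if e.kind == "salt_bridge"
        }
        for e in detect_salt_bridges(
            pose, receptor, max_dist=cfg.electrostatic_max, kind="electrostatic"
        ):
            if (e.ligand_atoms, e.residue_number, e.chain) not in close:
                events.append(e)
    if "hbond" in cfg.enabled or "ch_hbond" in cfg.enabled:
        hb = detect_hbonds(
            pose,
            receptor,
            heavy_max=cfg.hbond_heavy_max,
            h_max=cfg.hbond_h_max,
            ch_enabled=cfg.ch_hbond_enabled and "ch_hbond" in cfg.enabled,
            ch_h_max=cfg.ch_h_max,
            ch_heavy_max=cfg.ch_heavy_max,
        )
        events += [e for e in hb if e.kind in cfg.enabled]
    if "pi_pi" in cfg.enabled:
        events += detect_pi_pi(
            pose, receptor, centroid_max=cfg.pipi_centroid_max,
            parallel_angle=cfg.pipi_parallel_angle,
        )
    if "hydrophobic" in cfg.enabled:
        events += detect_hydrophobic(pose, receptor, max_dist=cfg.hydrophobic_max)
    return InteractionFingerprint(pose_id=pose.compound_id, events=events)


def filter_poses_by_salt_bridge(
    poses: list[MoleculePose],
    receptor: ReceptorModel,
    residue_number: int,
    chain: str | None = None,
    max_dist: float = 4.0,
) -> list[MoleculePose]:
    """Poses (input order preserved) that salt-bridge the named residue."""
    known = {(a.residue_number, a.chain) for a in receptor.atoms}
    if not any(rn == residue_number and (chain is None or ch == chain) for rn, ch in known):
        raise KeyError(f"residue {residue_number}{':' + chain if chain else ''} not in receptor")
    out = []
    for pose in poses:
        events = detect_salt_bridges(pose, receptor, max_dist=max_dist)
        if any(
            e.residue_number == residue_number and (chain is None or e.chain == chain)
            for e in events
        ):
            out.append(pose)
    return out
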