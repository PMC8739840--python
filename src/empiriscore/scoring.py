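"""The calibrated empirical scoring function.

A pose score is a weighted sum of nine distance-dependent atom-pair terms
accumulated over all intermolecular (ligand heavy atom, receptor heavy atom)
pairs, divided by a torsion penalty ``1 + w_rot * N_rot / 5`` and optionally
augmented by a salt-bridge reward toward a named receptor residue:

    dG = sum_t w_t * T_t(pose, receptor) / (1 + w_rot * N_rot / 5) + reward

Distances enter the steric terms through the surface distance
``d = r - R_i - R_j`` (center distance minus both vdW radii), which can be
negative at clash.  Every term is exactly zero beyond its center-distance
cutoff ``c``.  The predicted inhibition constant follows from
:func:`empiriscore.thermo_pharm.dg_to_ki` at the profile temperature.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .ad4params import DESOLVATION_SIGMA, QASP
from .structio import MoleculePose, ReceptorModel, TypedAtom

__all__ = [
    "TermSpec",
    "ScoringProfile",
    "TermVector",
    "ScoreResult",
    "SaltBridgeReward",
    "surface_distance",
    "term_value",
    "evaluate_terms",
    "score_pose",
    "default_profile",
]

TERM_KINDS = (
    "gauss",
    "repulsion",
    "hydrophobic",
    "non_dir_h_bond",
    "vdw",
    "acceptor_acceptor_quadratic",
    "donor_donor_quadratic",
    "ad4_solvation",
)

#: fallback width (Å) substituted for a degenerate zero gaussian width
DEFAULT_GAUSS_WIDTH = 0.5


class ProfileError(ValueError):
    """Invalid term kind or parameters in a scoring profile."""


@dataclass
class TermSpec:
    """One distance-dependent pairwise term: kind, parameters, weight."""

    kind: str
    params: dict = field(default_factory=dict)
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in TERM_KINDS:
            raise ProfileError(f"unknown term kind {self.kind!r}")
        p = dict(self.params)
        if self.kind == "gauss":
            if p.get("w", 0.0) <= 0.0:
                warnings.warn(
                    f"gauss width w={p.get('w', 0.0)!r} is degenerate; "
                    f"normalizing to {DEFAULT_GAUSS_WIDTH} Å",
                    stacklevel=2,
                )
                p["w"] = DEFAULT_GAUSS_WIDTH
        if self.kind == "vdw":
            p.setdefault("i", 4)
            p.setdefault("j", 8)
            p.setdefault("cap", 100.0)
            if p["cap"] <= 0:
                raise ProfileError("vdw cap must be > 0")
        if self.kind == "ad4_solvation":
            p.setdefault("sigma", DESOLVATION_SIGMA)
            p.setdefault("q_scale", QASP)
        p.setdefault("c", 8.0)
        if p["c"] <= 0:
            raise ProfileError("cutoff c must be > 0")
        self.params = p

    @property
    def cutoff(self) -> float:
        return float(self.params["c"])

    def label(self) -> str:
        inner = ", ".join(f"{k}={v:g}" for k, v in self.params.items() if k != "c")
        return f"{self.kind}({inner})" if inner else self.kind


@dataclass
class SaltBridgeReward:
    """Score bonus applied once when the pose salt-bridges a named residue."""

    residue_number: int
    chain: str | None = None
    residue_name: str | None = None
    max_dist: float = 4.0  # N+ ... carboxylate O, Å
    bonus: float = -1.0    # kcal/mol

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScoringProfile:
    """Ordered term specs plus the torsion divisor weight and temperature."""

    terms: list[TermSpec]
    torsion_weight: float = 1.923
    salt_bridge_reward: SaltBridgeReward | None = None
    temperature_K: float = 298.0

    def __post_init__(self) -> None:
        if not self.terms:
            raise ProfileError("profile needs at least one term")
        if self.torsion_weight < 0:
            raise ProfileError("torsion_weight must be >= 0")

    @property
    def weights(self) -> np.ndarray:
        return np.array([t.weight for t in self.terms])

    @property
    def max_cutoff(self) -> float:
        return max(t.cutoff for t in self.terms)

    def to_json(self) -> str:
        d = {
            "terms": [
                {"kind": t.kind, "params": t.params, "weight": t.weight}
                for t in self.terms
            ],
            "torsion_weight": self.torsion_weight,
            "salt_bridge_reward": (
                self.salt_bridge_reward.to_dict() if self.salt_bridge_reward else None
            ),
            "temperature_K": self.temperature_K,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScoringProfile":
        d = json.loads(text)
        reward = d.get("salt_bridge_reward")
        return cls(
            terms=[TermSpec(t["kind"], t["params"], t["weight"]) for t in d["terms"]],
            torsion_weight=d["torsion_weight"],
            salt_bridge_reward=SaltBridgeReward(**reward) if reward else None,
            temperature_K=d.get("temperature_K", 298.0),
        )


@dataclass
class TermVector:
    """Per-term accumulations for one pose, plus its rotatable-bond count."""

    values: np.ndarray
    n_rotatable: int
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class ScoreResult:
    compound_id: str
    term_vector: TermVector
    weighted_contributions: np.ndarray
    delta_g: float       # kcal/mol
    ki_nM: float
    salt_bridge_applied: bool


# ---------------------------------------------------------------------------
# pairwise term math
# ---------------------------------------------------------------------------

def surface_distance(atom_i: TypedAtom, atom_j: TypedAtom, r: float | None = None) -> float:
    """Surface distance d = r - R_i - R_j (Å); negative at steric clash."""
    if r is None:
        r = float(np.linalg.norm(atom_i.position - atom_j.position))
    return r - atom_i.vdw_radius - atom_j.vdw_radius


def _slide(d: float, g: float, b: float) -> float:
    """1 for d <= g, 0 for d >= b, linear in between (g < b)."""
    if d <= g:
        return 1.0
    if d >= b:
        return 0.0
    return (b - d) / (b - g)


def term_value(spec: TermSpec, atom_i: TypedAtom, atom_j: TypedAtom, r: float) -> float:
    """Value of one pairwise term at center distance ``r`` (Å).

    Zero for ``r >= c``.  Steric terms act on the surface distance
    ``d = r - R_i - R_j``; the desolvation term acts on ``r`` directly.
    """
    p = spec.params
    if r >= p["c"]:
        return 0.0
    kind = spec.kind

    if kind == "ad4_solvation":
        si = atom_i.solvation_param + p["q_scale"] * abs(atom_i.partial_charge)
        sj = atom_j.solvation_param + p["q_scale"] * abs(atom_j.partial_charge)
        return (si * atom_j.solvation_volume + sj * atom_i.solvation_volume) * math.exp(
            -(r * r) / (2.0 * p["sigma"] ** 2)
        )

    d = surface_distance(atom_i, atom_j, r)
    if kind == "gauss":
        u = (d - p.get("o", 0.0)) / p["w"]
        return math.exp(-u * u)
    if kind == "repulsion":
        o = p.get("o", 0.0)
        return (d - o) ** 2 if d < o else 0.0
    if kind == "hydrophobic":
        if atom_i.is_hydrophobic and atom_j.is_hydrophobic:
            return _slide(d, p["g"], p["b"])
        return 0.0
    if kind == "non_dir_h_bond":
        if (atom_i.is_hbond_donor and atom_j.is_hbond_acceptor) or (
            atom_j.is_hbond_donor and atom_i.is_hbond_acceptor
        ):
            return _slide(d, p["g"], p["b"])
        return 0.0
    if kind == "vdw":
        # two-exponent potential with minimum -1 at r0 = R_i + R_j,
        # e(r) = (i*(r0/r)^j - j*(r0/r)^i) / (j - i), clamped to +cap
        i_exp, j_exp = p["i"], p["j"]
        r0 = atom_i.vdw_radius + atom_j.vdw_radius
        if r <= 1e-12:
            return p["cap"]
        q = r0 / r
        val = (i_exp * q**j_exp - j_exp * q**i_exp) / (j_exp - i_exp)
        return min(val, p["cap"])
    if kind == "acceptor_acceptor_quadratic":
        if atom_i.is_hbond_acceptor and atom_j.is_hbond_acceptor:
            return (d - p.get("o", 0.0)) ** 2
        return 0.0
    if kind == "donor_donor_quadratic":
        if atom_i.is_hbond_donor and atom_j.is_hbond_donor:
            return (d - p.get("o", 0.0)) ** 2
        return 0.0
    raise ProfileError(f"unknown term kind {kind!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# pose evaluation
# ---------------------------------------------------------------------------

def _check_typed(atoms) -> None:
    for a in atoms:
        if a.ad4_type is None:
            raise TypeError(f"atom {a.serial} is untyped; run assign_atom_types first")


def evaluate_terms(
    pose: MoleculePose, receptor: ReceptorModel, profile: ScoringProfile
) -> TermVector:
    """Accumulate each profile term over intermolecular heavy-atom pairs.

    Uses the receptor's neighbor query at the largest term cutoff; result is
    independent of atom ordering (up to float summation noise well below any
    tolerance used here).
    """
    lig_heavy = pose.heavy_atoms()
    _check_typed(lig_heavy)
    _check_typed(receptor.atoms)
    values = np.zeros(len(profile.terms))
    cmax = profile.max_cutoff
    for la in lig_heavy:
        for idx in receptor.neighbors(la.position, cmax):
            ra = receptor.atoms[idx]
            if not ra.is_heavy:
                continue
            r = float(np.linalg.norm(la.position - ra.position))
            for t, spec in enumerate(profile.terms):
                values[t] += term_value(spec, la, ra, r)
    return TermVector(
        values=values,
        n_rotatable=pose.n_rotatable,
        labels=[t.label() for t in profile.terms],
    )


def torsion_divisor(torsion_weight: float, n_rotatable: int) -> float:
    """Penalty divisor 1 + w * N_rot / 5 applied to the weighted term sum."""
    return 1.0 + torsion_weight * n_rotatable / 5.0


def _salt_bridge_present(
    pose: MoleculePose, receptor: ReceptorModel, reward: SaltBridgeReward
) -> bool:
    from .interactions import detect_salt_bridges

    events = detect_salt_bridges(pose, receptor, max_dist=reward.max_dist)
    for ev in events:
        if ev.residue_number != reward.residue_number:
            continue
        if reward.chain and ev.chain != reward.chain:
            continue
        if reward.residue_name and ev.residue_name.upper() != reward.residue_name.upper():
            continue
        return True
    return False


def score_pose(
    pose: MoleculePose, receptor: ReceptorModel, profile: ScoringProfile
) -> ScoreResult:
    """Score a pose: term accumulation, torsion divisor, optional reward, Ki."""
    from .thermo_pharm import dg_to_ki

    tv = evaluate_terms(pose, receptor, profile)
    divisor = torsion_divisor(profile.torsion_weight, tv.n_rotatable)
    contributions = profile.weights * tv.values / divisor
    delta_g = float(contributions.sum())

    applied = False
    if profile.salt_bridge_reward is not None:
        if _salt_bridge_present(pose, receptor, profile.salt_bridge_reward):
            delta_g += profile.salt_bridge_reward.bonus
            applied = True

    ki_nm = dg_to_ki(delta_g, profile.temperature_K) * 1e9
    return ScoreResult(
        compound_id=pose.compound_id,
        term_vector=tv,
        weighted_contributions=contributions,
        delta_g=delta_g,
        ki_nM=ki_nm,
        salt_bridge_applied=applied,
    )


def default_profile() -> ScoringProfile:
    """The calibrated nine-term profile with its published coefficients.

    The first gaussian is specified with a degenerate zero width and is
    normalized to 0.5 Å; the two-exponent van der Waals term uses exponents
    (4, 8) with cap 100.  Torsion divisor weight 1.923, temperature 298 K,
    no salt-bridge reward (add one for receptor-specific rescoring).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the w=0 normalization is intended here
        terms = [
            TermSpec("gauss", {"o": 0.0, "w": 0.0, "c": 8.0}, -0.035579),
            TermSpec("gauss", {"o": 3.0, "w": 2.0, "c": 8.0}, -0.005156),
            TermSpec("repulsion", {"o": 0.0, "c": 8.0}, 0.840245),
            TermSpec("hydrophobic", {"g": 0.5, "b": 1.5, "c": 8.0}, -0.035069),
            TermSpec("non_dir_h_bond", {"g": -0.7, "b": 0.0, "c": 8.0}, -0.587439),
            TermSpec("vdw", {"i": 4, "j": 8, "cap": 100.0, "c": 8.0}, 0.0003),
            TermSpec("acceptor_acceptor_quadratic", {"o": 0.0, "c": 8.0}, -1.5),
            TermSpec("donor_donor_quadratic", {"o": 0.0, "c": 8.0}, -2.0),
            TermSpec("ad4_solvation", {"c": 8.0}, 0.01148),
        ]
    return ScoringProfile(terms=terms, torsion_weight=1.923, temperature_K=298.0)
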