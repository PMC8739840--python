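"""Protonation-microstate fractions of a multi-basic ligand at a given pH.

Independent-site Henderson–Hasselbalch model: each basic center i is
protonated with probability p_i = 1 / (1 + 10^(pH − pKa_i)) and a microstate
(one occupancy pattern of the n sites) has fraction Π p_i or (1 − p_i).
Optional pairwise ΔpKa shifts model site–site coupling: the effective pKa of
a site drops by the supplied shift for every *other* site already protonated
in that microstate (fractions are then renormalized Boltzmann-style).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

__all__ = ["Microstate", "MicrostateDistribution", "microstate_fractions", "dominant_states"]


@dataclass(frozen=True)
class Microstate:
    occupancy: tuple[int, ...]  # 1 = protonated, per site
    fraction: float

    @property
    def n_protonated(self) -> int:
        return sum(self.occupancy)

    def label(self, site_names=None) -> str:
        if site_names:
            on = [n for n, o in zip(site_names, self.occupancy) if o]
            return "+".join(on) if on else "neutral"
        return "".join(str(o) for o in self.occupancy)


@dataclass
class MicrostateDistribution:
    site_pkas: list[float]
    pH: float
    states: list[Microstate]
    site_names: list[str] = field(default_factory=list)

    def fraction(self, occupancy) -> float:
        occ = tuple(int(o) for o in occupancy)
        for s in self.states:
            if s.occupancy == occ:
                return s.fraction
        raise KeyError(f"no state {occ}")

    @property
    def fully_protonated_fraction(self) -> float:
        return self.fraction((1,) * len(self.site_pkas))


def microstate_fractions(
    site_pkas, pH: float, interaction_shifts: dict | None = None,
    site_names=None,
) -> MicrostateDistribution:
    """Enumerate all 2^n protonation microstates with their fractions.

    ``interaction_shifts`` maps frozenset({i, j}) site-index pairs to a ΔpKa
    penalty applied when both sites are protonated (default none).  Fractions
    are nonnegative and sum to 1.
    """
    pkas = [float(p) for p in site_pkas]
    if not pkas:
        raise ValueError("need at least one site")
    if any(not math.isfinite(p) for p in pkas):
        raise ValueError("pKa values must be finite")
    shifts = interaction_shifts or {}
    n = len(pkas)

    # unnormalized weight of a microstate: 10^(sum over protonated sites of
    # (pKa_i - pH) - pairwise penalties), the grand-canonical Boltzmann factor
    weights = []
    occupancies = list(itertools.product((0, 1), repeat=n))
    for occ in occupancies:
        expo = sum((pkas[i] - pH) for i in range(n) if occ[i])
        for pair, dpka in shifts.items():
            i, j = tuple(pair)
            if occ[i] and occ[j]:
                expo -= float(dpka)
        weights.append(10.0 ** expo)
    total = sum(weights)
    states = [Microstate(occ, w / total) for occ, w in zip(occupancies, weights)]
    return MicrostateDistribution(
        site_pkas=pkas, pH=float(pH), states=states,
        site_names=list(site_names) if site_names else [],
    )


def dominant_states(
    dist: MicrostateDistribution, threshold: float = 0.05
) -> list[tuple[Microstate, float]]:
    """States with fraction >= threshold, most populated first."""
    kept = [(s, s.fraction) for s in dist.states if s.fraction >= threshold]
    return sorted(kept, key=lambda t: -t[1])
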