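"""Independent reference implementations used as test oracles.

These deliberately re-derive the math with plain double loops and explicit
piecewise expressions, sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_term_vector(pose, receptor, profile) -> np.ndarray:
    """O(N*M) accumulation of every profile term over all heavy-atom pairs."""
    out = np.zeros(len(profile.terms))
    for la in pose.atoms:
        if la.element.upper() == "H":
            continue
        for ra in receptor.atoms:
            if ra.element.upper() == "H":
                continue
            r = math.dist(tuple(la.position), tuple(ra.position))
            for t, spec in enumerate(profile.terms):
                out[t] += pair_term(spec.kind, spec.params, la, ra, r)
    return out


def pair_term(kind: str, p: dict, a, b, r: float) -> float:
    if r >= p["c"]:
        return 0.0
    d = r - a.vdw_radius - b.vdw_radius
    if kind == "gauss":
        return math.exp(-(((d - p.get("o", 0.0)) / p["w"]) ** 2))
    if kind == "repulsion":
        o = p.get("o", 0.0)
        return max(o - d, 0.0) ** 2
    if kind == "hydrophobic":
        if not (a.is_hydrophobic and b.is_hydrophobic):
            return 0.0
        return min(max((p["b"] - d) / (p["b"] - p["g"]), 0.0), 1.0)
    if kind == "non_dir_h_bond":
        pair_ok = (a.is_hbond_donor and b.is_hbond_acceptor) or (
            b.is_hbond_donor and a.is_hbond_acceptor
        )
        if not pair_ok:
            return 0.0
        return min(max((p["b"] - d) / (p["b"] - p["g"]), 0.0), 1.0)
    if kind == "vdw":
        r0 = a.vdw_radius + b.vdw_radius
        i, j = p["i"], p["j"]
        val = (i * (r0 / r) ** j - j * (r0 / r) ** i) / (j - i)
        return min(val, p["cap"])
    if kind == "acceptor_acceptor_quadratic":
        if a.is_hbond_acceptor and b.is_hbond_acceptor:
            return (d - p.get("o", 0.0)) ** 2
        return 0.0
    if kind == "donor_donor_quadratic":
        if a.is_hbond_donor and b.is_hbond_donor:
            return (d - p.get("o", 0.0)) ** 2
        return 0.0
    if kind == "ad4_solvation":
        sa = a.solvation_param + p["q_scale"] * abs(a.partial_charge)
        sb = b.solvation_param + p["q_scale"] * abs(b.partial_charge)
        return (sa * b.solvation_volume + sb * a.solvation_volume) * math.exp(
            -(r**2) / (2 * p["sigma"] ** 2)
        )
    raise ValueError(kind)


def brute_force_score(pose, receptor, profile) -> float:
    tv = brute_force_term_vector(pose, receptor, profile)
    weighted = sum(spec.weight * v for spec, v in zip(profile.terms, tv))
    return weighted / (1.0 + profile.torsion_weight * pose.n_rotatable / 5.0)


def enumerate_microstates(pkas, ph):
    """All protonation microstates by direct per-site probability products."""
    probs = [1.0 / (1.0 + 10.0 ** (ph - pka)) for pka in pkas]
    out = {}
    for occ in itertools.product((0, 1), repeat=len(pkas)):
        f = 1.0
        for o, p in zip(occ, probs):
            f *= p if o else (1.0 - p)
        out[occ] = f
    return out


def pearson_r(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))
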