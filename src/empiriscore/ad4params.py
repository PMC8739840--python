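"""Bundled AutoDock4-style atomic parameters.

Per-type van der Waals radii (Å), atomic solvation volumes (Å³) and
solvation parameters (kcal/(mol·Å³)) for the desolvation term.  Values follow
the AutoDock4.1 force-field parameter set; the charge augmentation constant
``QASP`` scales |partial charge| into the effective solvation parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

#: charge-based atomic solvation parameter, e⁻¹·kcal/(mol·Å³)
QASP = 0.01097

#: Gaussian width of the desolvation distance kernel, Å
DESOLVATION_SIGMA = 3.6


@dataclass(frozen=True)
class AtomParams:
    vdw_radius: float        # Å (half of AD4 Rii)
    solvation_volume: float  # Å³
    solvation_param: float   # kcal/(mol·Å³)


# ad4_type -> parameters.  A = aromatic carbon, NA/OA = H-bond acceptor N/O,
# HD = polar (donor-attached) hydrogen, SA = acceptor sulfur.
AD4_PARAMETERS: dict[str, AtomParams] = {
    "H":  AtomParams(1.000, 0.0000, 0.00051),
    "HD": AtomParams(1.000, 0.0000, 0.00051),
    "C":  AtomParams(2.000, 33.5103, -0.00143),
    "A":  AtomParams(2.000, 33.5103, -0.00052),
    "N":  AtomParams(1.750, 22.4493, -0.00162),
    "NA": AtomParams(1.750, 22.4493, -0.00162),
    "O":  AtomParams(1.600, 17.1573, -0.00251),
    "OA": AtomParams(1.600, 17.1573, -0.00251),
    "S":  AtomParams(2.000, 33.5103, -0.00214),
    "SA": AtomParams(2.000, 33.5103, -0.00214),
    "P":  AtomParams(2.100, 38.7924, -0.00110),
    "F":  AtomParams(1.545, 15.4480, -0.00110),
    "Cl": AtomParams(2.045, 35.8235, -0.00110),
    "Br": AtomParams(2.165, 42.5661, -0.00110),
    "I":  AtomParams(2.360, 55.0585, -0.00110),
    "Zn": AtomParams(0.740, 1.7000, -0.00110),
    "Mg": AtomParams(0.650, 1.5600, -0.00110),
    "Ca": AtomParams(0.990, 2.7700, -0.00110),
    "Mn": AtomParams(0.650, 2.1400, -0.00110),
    "Fe": AtomParams(0.650, 1.8400, -0.00110),
}

#: bare element -> default AD4 type when no context disambiguates
ELEMENT_DEFAULT_TYPE: dict[str, str] = {
    "H": "H", "C": "C", "N": "N", "O": "OA", "S": "S", "P": "P",
    "F": "F", "CL": "Cl", "BR": "Br", "I": "I", "ZN": "Zn", "MG": "Mg",
    "CA": "Ca", "MN": "Mn", "FE": "Fe",
}

#: approximate single-bond covalent radii (Å), used only to infer bonds for
#: formats that carry no connectivity (PDBQT)
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "ZN": 1.22, "MG": 1.41,
    "CA": 1.76, "MN": 1.39, "FE": 1.32,
}


class TypingError(ValueError):
    """Raised when an atom cannot be assigned parameters."""


def params_for(ad4_type: str) -> AtomParams:
    try:
        return AD4_PARAMETERS[ad4_type]
    except KeyError:
        raise TypingError(f"no bundled parameters for AD4 type {ad4_type!r}") from None
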