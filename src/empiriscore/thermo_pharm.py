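"""Binding thermodynamics and pharmacology math.

ΔG ↔ Ki interconversion (ΔG = RT·ln Ki with Ki in molar), Cheng–Prusoff
correction of competition IC50s, four-parameter logistic (4PL) curve fitting,
σ2/σ1 selectivity ratios with censored-value handling, and replicate Ki
aggregation as geometric mean with a 95% t-interval on the log10 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "R_KCAL",
    "AffinityMeasurement",
    "BindingCurve",
    "SelectivityRatio",
    "KiAggregate",
    "dg_to_ki",
    "ki_to_dg",
    "selectivity_ratio",
    "format_ratio",
    "cheng_prusoff",
    "fit_4pl",
    "aggregate_ki",
]

#: gas constant, kcal/(mol·K)
R_KCAL = 1.9872e-3

TARGETS = ("sigma1", "sigma2", "H1", "H2", "H3", "H4")


class DegenerateFitError(RuntimeError):
    """Response carries no usable concentration dependence."""


@dataclass
class AffinityMeasurement:
    """One experimental Ki record, optionally censored ("> bound" style)."""

    compound_id: str
    target: str
    ki_nM: float
    ci_low_nM: float | None = None
    ci_high_nM: float | None = None
    censored: bool = False

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if not self.censored and self.ki_nM <= 0:
            raise ValueError("ki_nM must be > 0 for uncensored measurements")
        if self.ci_low_nM is not None and self.ci_high_nM is not None:
            if not (self.ci_low_nM <= self.ki_nM <= self.ci_high_nM):
                raise ValueError("Ki outside its confidence interval")


@dataclass
class BindingCurve:
    """Competition-binding concentration/response series with 4PL fit slots.

    Concentration units are the caller's choice; the fitted IC50 comes back
    in the same units.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    fitted: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, float)
        self.responses = np.asarray(self.responses, float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentration and response lengths differ")


# ---------------------------------------------------------------------------
# dG <-> Ki
# ---------------------------------------------------------------------------

def dg_to_ki(delta_g: float, temperature_K: float = 298.0) -> float:
    """Inhibition constant (molar) from binding free energy (kcal/mol).

    Ki = exp(ΔG / RT); multiply by 1e9 for nM.  Strictly increasing in ΔG.
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(delta_g / (R_KCAL * temperature_K))


def dg_to_ki_nM(delta_g: float, temperature_K: float = 298.0) -> float:
    return dg_to_ki(delta_g, temperature_K) * 1e9


def ki_to_dg(ki_molar: float, temperature_K: float = 298.0) -> float:
    """Binding free energy (kcal/mol) from a molar Ki; exact inverse of
    :func:`dg_to_ki`."""
    if ki_molar <= 0:
        raise ValueError("Ki must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * temperature_K * math.log(ki_molar)


# ---------------------------------------------------------------------------
# selectivity
# ---------------------------------------------------------------------------

@dataclass
class SelectivityRatio:
    value: float
    inequality: str = ""  # "", "<" or ">"

    def __str__(self) -> str:
        return f"{self.inequality}{format_ratio(self.value)}"


def format_ratio(x: float) -> str:
    """Table-style formatting: one decimal for ratios that resolve at that
    precision, '<0.1' for positive ratios that would round to 0.0, and two
    significant figures for ratios too small for the '<0.1' bucket to be
    informative."""
    if x >= 0.05:
        return f"{x:.1f}"
    if x >= 0.01:
        return "<0.1"
    if x <= 0:
        return "0.0"
    return f"{x:.2g}"


def selectivity_ratio(
    ki_sigma2_nM: float,
    ki_sigma1_nM: float,
    censored_sigma2: bool = False,
    censored_sigma1: bool = False,
) -> SelectivityRatio:
    """σ2/σ1 selectivity.  A censored numerator gives a '>' lower bound at the
    censoring limit; a censored denominator gives a '<' upper bound."""
    if ki_sigma2_nM <= 0 or ki_sigma1_nM <= 0:
        raise ValueError("Ki values must be positive")
    if censored_sigma1 and censored_sigma2:
        raise ValueError("both sides censored: ratio undefined")
    ratio = ki_sigma2_nM / ki_sigma1_nM
    if censored_sigma2:
        return SelectivityRatio(ratio, ">")
    if censored_sigma1:
        return SelectivityRatio(ratio, "<")
    return SelectivityRatio(ratio, "")


# ---------------------------------------------------------------------------
# Cheng-Prusoff and 4PL
# ---------------------------------------------------------------------------

def cheng_prusoff(ic50_nM: float, radioligand_conc_nM: float, radioligand_kd_nM: float) -> float:
    """Ki = IC50 / (1 + [L]/Kd): competition IC50 corrected for radioligand
    occupancy.  Homogeneous of degree 1 in IC50."""
    if min(ic50_nM, radioligand_conc_nM, radioligand_kd_nM) <= 0:
        raise ValueError("all inputs must be positive")
    return ic50_nM / (1.0 + radioligand_conc_nM / radioligand_kd_nM)


def _logistic4(x, bottom, top, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def fit_4pl(curve: BindingCurve, variance_tol: float = 1e-12) -> dict:
    """Least-squares four-parameter logistic fit.

    Returns {'bottom','top','ic50','hill','converged','ic50_in_range'};
    parameters are also stored on ``curve.fitted``.  Raises
    :class:`DegenerateFitError` when the response is flat.
    """
    x = curve.concentrations
    y = curve.responses
    if len(np.unique(x)) < 5:
        raise ValueError("need >= 5 distinct concentrations")
    if np.var(y) < variance_tol:
        raise DegenerateFitError("response variance below tolerance; no dose dependence")

    top0, bot0 = float(y.max()), float(y.min())
    half = 0.5 * (top0 + bot0)
    # initialize IC50 at the concentration whose response is nearest half-max
    ic50_0 = float(x[np.argmin(np.abs(y - half))])
    ic50_0 = max(ic50_0, x[x > 0].min() if np.any(x > 0) else 1e-12)
    p0 = [bot0, top0, ic50_0, 1.0]
    popt, _ = optimize.curve_fit(
        _logistic4, x, y, p0=p0,
        bounds=([-np.inf, -np.inf, 1e-18, 0.05], [np.inf, np.inf, 1e12, 20.0]),
        maxfev=20000,
    )
    bottom, top, ic50, hill = (float(v) for v in popt)
    in_range = bool(x.min() <= ic50 <= x.max())
    if not in_range:
        import warnings

        warnings.warn("fitted IC50 lies outside the sampled concentration range")
    result = {
        "bottom": bottom,
        "top": top,
        "ic50": ic50,
        "hill": hill,
        "converged": True,
        "ic50_in_range": in_range,
    }
    curve.fitted = result
    return result


# ---------------------------------------------------------------------------
# replicate aggregation
# ---------------------------------------------------------------------------

@dataclass
class KiAggregate:
    mean_nM: float          # geometric mean
    ci_low_nM: float | None
    ci_high_nM: float | None
    n: int
    ci_available: bool


def aggregate_ki(replicates_nM, confidence: float = 0.95) -> KiAggregate:
    """Geometric mean of replicate Ki values with a back-transformed
    t-interval on log10(Ki).  For n = 1 the CI is flagged absent."""
    reps = np.asarray(list(replicates_nM), float)
    if reps.size == 0:
        raise ValueError("need at least one replicate")
    if np.any(reps <= 0):
        raise ValueError("replicates must be positive")
    logs = np.log10(reps)
    gm = float(10 ** logs.mean())
    n = int(reps.size)
    if n == 1:
        return KiAggregate(gm, None, None, 1, False)
    sd = logs.std(ddof=1)
    half = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1) * sd / math.sqrt(n)
    return KiAggregate(gm, float(10 ** (logs.mean() - half)), float(10 ** (logs.mean() + half)), n, True)
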