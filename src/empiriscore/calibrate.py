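"""Weight calibration of the scoring function against experimental affinities.

The score is linear in the term weights once the torsion divisor is fixed,
so calibration is (optionally sign-constrained) linear least squares on the
ΔG scale: row i of the design matrix is term_vector_i / (1 + w_rot·N_rot,i/5)
and the response is the experimental ΔG from ki_to_dg.  The torsion weight
itself enters nonlinearly and is handled by a 1-D grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .scoring import ScoringProfile, TermSpec, torsion_divisor

__all__ = [
    "CalibrationRecord",
    "CalibrationResult",
    "IllPosedFitError",
    "build_design_matrix",
    "fit_weights",
    "evaluate_fit",
]


class IllPosedFitError(RuntimeError):
    """Design matrix rank-deficient (collinear or insufficient records)."""


@dataclass
class CalibrationRecord:
    compound_id: str
    term_values: np.ndarray   # raw per-term accumulations
    n_rotatable: int
    dg_exp: float             # kcal/mol, from ki_to_dg of the measured Ki
    censored: bool = False    # dg_exp is then a lower bound (Ki "> limit")

    def __post_init__(self) -> None:
        self.term_values = np.asarray(self.term_values, float)


@dataclass
class CalibrationResult:
    profile: ScoringProfile
    weights: np.ndarray
    torsion_weight: float
    r2: float
    residuals: np.ndarray
    predictions: np.ndarray
    responses: np.ndarray
    compound_ids: list[str] = field(default_factory=list)

    def prediction_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "compound_id": self.compound_ids,
                "dg_exp": self.responses,
                "dg_pred": self.predictions,
                "residual": self.residuals,
            }
        )


def build_design_matrix(
    records: list[CalibrationRecord],
    torsion_weight: float,
    include_censored: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Torsion-scaled term matrix and experimental-ΔG response vector.

    Censored records are excluded unless ``include_censored`` (they are then
    handled by the hinge option in :func:`fit_weights`, not here).
    """
    kept = [r for r in records if include_censored or not r.censored]
    if not kept:
        raise IllPosedFitError("all records censored; nothing to fit")
    n_terms = len(kept[0].term_values)
    if any(len(r.term_values) != n_terms for r in kept):
        raise ValueError("inconsistent term-vector lengths")
    if len(kept) < n_terms:
        raise IllPosedFitError(
            f"{len(kept)} usable records for {n_terms} weights: underdetermined"
        )
    X = np.array([r.term_values / torsion_divisor(torsion_weight, r.n_rotatable) for r in kept])
    y = np.array([r.dg_exp for r in kept])
    rank = np.linalg.matrix_rank(X)
    if rank < n_terms:
        # name the most nearly-collinear columns via the smallest singular vectors
        _, s, vt = np.linalg.svd(X)
        bad = np.where(np.abs(vt[-1]) > 0.3)[0].tolist()
        raise IllPosedFitError(f"design matrix rank {rank} < {n_terms}; collinear terms {bad}")
    return X, y, [r.compound_id for r in kept]


def _solve(X: np.ndarray, y: np.ndarray, signs) -> np.ndarray:
    if signs is None:
        w, *_ = np.linalg.lstsq(X, y, rcond=None)
        return w
    lo = np.array([0.0 if s == "+" else (-np.inf) for s in signs])
    hi = np.array([0.0 if s == "-" else (np.inf) for s in signs])
    lo = np.where([s == "-" for s in signs], -np.inf, lo)
    res = optimize.lsq_linear(X, y, bounds=(lo, hi))
    return res.x


def fit_weights(
    records: list[CalibrationRecord],
    sign_constraints=None,
    torsion_weight: float | None = 1.923,
    torsion_grid=None,
    censored_hinge: bool = False,
) -> CalibrationResult:
    """Least-squares weight fit; optionally grid over the torsion weight.

    sign_constraints: sequence over terms of '+', '-' or None (free).
    torsion_grid: iterable of candidate torsion weights; the SSE-optimal one
    is returned (overrides ``torsion_weight``).
    censored_hinge: add one-sided penalties max(0, dg_bound - dg_pred)^2 for
    censored records (their true ΔG is above the bound).
    """
    grid = list(torsion_grid) if torsion_grid is not None else [torsion_weight]
    best = None
    for tw in grid:
        X, y, ids = build_design_matrix(records, tw)
        w = _solve(X, y, sign_constraints)
        sse = float(np.sum((X @ w - y) ** 2))
        if censored_hinge:
            for r in records:
                if r.censored:
                    pred = float(r.term_values / torsion_divisor(tw, r.n_rotatable) @ w)
                    sse += max(0.0, r.dg_exp - pred) ** 2
        if best is None or sse < best[0]:
            best = (sse, tw, w, X, y, ids)
    _, tw, w, X, y, ids = best

    pred = X @ w
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    terms = [
        TermSpec("gauss", {"o": 0.0, "w": 0.5, "c": 8.0}, float(wi)) for wi in w
    ]  # placeholder kinds replaced below when a template profile is known
    profile = ScoringProfile(terms=terms, torsion_weight=tw)
    return CalibrationResult(
        profile=profile,
        weights=np.asarray(w, float),
        torsion_weight=tw,
        r2=r2,
        residuals=y - pred,
        predictions=pred,
        responses=y,
        compound_ids=ids,
    )


def apply_weights(profile: ScoringProfile, result: CalibrationResult) -> ScoringProfile:
    """Return a copy of ``profile`` carrying the fitted weights and torsion
    weight (term kinds/params kept from the template)."""
    if len(profile.terms) != len(result.weights):
        raise ValueError("weight count does not match profile term count")
    terms = [
        TermSpec(t.kind, dict(t.params), float(w))
        for t, w in zip(profile.terms, result.weights)
    ]
    return ScoringProfile(
        terms=terms,
        torsion_weight=result.torsion_weight,
        salt_bridge_reward=profile.salt_bridge_reward,
        temperature_K=profile.temperature_K,
    )


def evaluate_fit(
    result_or_weights, records: list[CalibrationRecord], torsion_weight: float | None = None
):
    """R² and a prediction table for a fitted weight vector on new records.

    ``result_or_weights`` may be a :class:`CalibrationResult` or a plain
    weight vector (then ``torsion_weight`` is required).
    """
    import pandas as pd

    if isinstance(result_or_weights, CalibrationResult):
        w = result_or_weights.weights
        tw = result_or_weights.torsion_weight
    else:
        w = np.asarray(result_or_weights, float)
        if torsion_weight is None:
            raise ValueError("torsion_weight required with a bare weight vector")
        tw = torsion_weight
    kept = [r for r in records if not r.censored]
    if len(kept) < 2:
        raise ValueError("R² undefined for fewer than 2 records")
    X = np.array([r.term_values / torsion_divisor(tw, r.n_rotatable) for r in kept])
    y = np.array([r.dg_exp for r in kept])
    pred = X @ w
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    table = pd.DataFrame(
        {"compound_id": [r.compound_id for r in kept], "dg_exp": y, "dg_pred": pred}
    )
    return r2, table
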