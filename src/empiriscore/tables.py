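"""Bundled published affinity tables.

Two plain-CSV resources ship with the package: the calculated ΔG / Ki table
(per compound and receptor) and the experimental Ki table with 95% CIs,
censoring flags and the printed σ2/σ1 selectivity column.  They serve as
replay inputs for the thermodynamic mapping and the selectivity math.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_calculated_affinities",
    "load_experimental_affinities",
    "load_printed_selectivity",
    "last_digit_unit",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("empiriscore.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype={"compound": str})


def load_calculated_affinities() -> pd.DataFrame:
    """Rows (compound, target, dg_kcal, ki_calc_printed); the printed Ki is
    kept as a string so its printed precision is recoverable."""
    with resources.files("empiriscore.data").joinpath("calculated_affinities.csv").open() as fh:
        return pd.read_csv(fh, dtype={"compound": str, "ki_calc_printed": str})


def load_experimental_affinities() -> pd.DataFrame:
    """Rows (compound, target, ki_nM, ci_low_nM, ci_high_nM, censored)."""
    df = _read("experimental_affinities.csv")
    df["censored"] = df["censored"].astype(bool)
    return df


def load_printed_selectivity() -> pd.DataFrame:
    """Rows (compound, printed_ratio) with the printed σ2/σ1 column, kept as
    strings to preserve inequality markers like '<0.1'."""
    with resources.files("empiriscore.data").joinpath("selectivity_printed.csv").open() as fh:
        return pd.read_csv(fh, dtype=str)


def last_digit_unit(printed: str) -> float:
    """One unit in the last printed digit of a decimal string: '3.11' → 0.01,
    '46.37' → 0.01, '65.0' → 0.1, '13' → 1."""
    s = printed.strip().lstrip("<>")
    if "." not in s:
        return 1.0
    return 10.0 ** -(len(s) - s.index(".") - 1)
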