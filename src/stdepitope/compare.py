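"""Experiment-vs-prediction scoring: NOE R-factor and epitope tables.

The agreement between experimental STD values and values back-calculated
from a candidate complex structure is summarized by the unweighted NOE
R-factor

    r = sqrt( sum_k (STD_k^exp - STD_k^calc)^2 / sum_k (STD_k^exp)^2 ),

summed over all compared proton (and optionally time) points: r = 0 is a
perfect match, r = 1 is the score of an all-zero prediction.  An
optional per-point weight vector is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .buildup import EpitopeMap, epitope_map

__all__ = ["RFactorResult", "EpitopeComparison", "noe_r_factor", "compare_epitopes"]


@dataclass(frozen=True)
class RFactorResult:
    r: float
    per_proton_residuals: Dict[str, Tuple[float, float, float]]  # (exp, calc, diff)
    n_points: int


@dataclass(frozen=True)
class EpitopeComparison:
    table: pd.DataFrame  # proton, exp_percent, calc_percent, diff
    missing_in_calc: list
    missing_in_exp: list
    r: float


def _as_point_dict(x) -> Dict:
    """Flatten scalar-per-proton mappings or proton x time frames into
    {key: value} with keys (proton,) or (proton, t)."""
    if isinstance(x, pd.DataFrame):
        out = {}
        for pid, row in x.iterrows():
            for col, v in row.items():
                if not pd.isna(v):
                    out[(pid, col)] = float(v)
        return out
    if isinstance(x, pd.Series):
        return {(k,): float(v) for k, v in x.items() if not pd.isna(v)}
    return {(k,): float(v) for k, v in dict(x).items() if not pd.isna(v)}


def noe_r_factor(
    exp: Union[Mapping, pd.Series, pd.DataFrame],
    calc: Union[Mapping, pd.Series, pd.DataFrame],
    weights: Optional[Mapping] = None,
) -> RFactorResult:
    """Unweighted (or point-weighted) NOE R-factor between matching sets.

    ``exp`` and ``calc`` must share exactly the same proton (or
    proton x time) keys; NA cells are dropped on both sides before the
    key check, so masked experimental cells simply do not contribute.
    """
    e = _as_point_dict(exp)
    c = _as_point_dict(calc)
    if not e:
        raise ValueError("no experimental points to compare")
    if set(e) != set(c):
        only_e = sorted(set(e) - set(c))
        only_c = sorted(set(c) - set(e))
        raise ValueError(
            "experimental and calculated keys differ; "
            f"only in exp: {only_e}; only in calc: {only_c}"
        )
    keys = list(e.keys())
    ev = np.array([e[k] for k in keys])
    cv = np.array([c[k] for k in keys])
    if weights is not None:
        w = np.array([float(weights[k]) for k in keys])
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    else:
        w = np.ones_like(ev)
    denom = float(np.sum(w * ev**2))
    if denom <= 0:
        raise ValueError("sum of squared experimental values is zero")
    r = float(np.sqrt(np.sum(w * (ev - cv) ** 2) / denom))
    residuals = {
        (k[0] if len(k) == 1 else k): (e[k], c[k], e[k] - c[k]) for k in keys
    }
    return RFactorResult(r=r, per_proton_residuals=residuals, n_points=len(keys))


def compare_epitopes(exp: EpitopeMap, calc: EpitopeMap) -> EpitopeComparison:
    """Side-by-side relative-epitope table with residuals and R-factor.

    Both maps are already normalized (100 % at the reference proton), so
    the comparison mirrors relative-STD plots.  Protons present on one
    side only are reported separately, never silently dropped; the
    R-factor covers the overlap.
    """
    exp_ids = list(exp.values.keys())
    calc_ids = list(calc.values.keys())
    overlap = [p for p in exp_ids if p in calc.values]
    if not overlap:
        raise ValueError("experimental and calculated epitopes share no protons")
    rows = [
        {
            "proton": p,
            "exp_percent": exp.values[p],
            "calc_percent": calc.values[p],
            "diff": exp.values[p] - calc.values[p],
        }
        for p in overlap
    ]
    res = noe_r_factor(
        {p: exp.values[p] for p in overlap}, {p: calc.values[p] for p in overlap}
    )
    return EpitopeComparison(
        table=pd.DataFrame(rows),
        missing_in_calc=[p for p in exp_ids if p not in calc.values],
        missing_in_exp=[p for p in calc_ids if p not in exp.values],
        r=res.r,
    )
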