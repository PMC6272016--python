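"""STD build-up curve analysis and binding-epitope mapping.

The fractional STD of a ligand proton grows with saturation time as a
saturating mono-exponential

    STD(t_sat) = STD_max * (1 - exp(-k_sat * t_sat)),

where STD_max is the plateau (percent) and k_sat (1/s) the apparent
saturation rate.  Relative STD intensities at a single long saturation
time are biased by differential relaxation and rebinding; the unbiased
epitope descriptor is the initial slope

    STD0 = STD_max * k_sat,

the derivative of the fitted curve at t_sat = 0.  The binding epitope is
the set of per-proton STD0 (or fixed-time STD) values normalized to 100 %
at the largest one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
import lmfit

__all__ = [
    "DEFAULT_TSAT_GRID",
    "BuildupSeries",
    "BuildupFit",
    "EpitopeMap",
    "fractional_std",
    "fit_buildup",
    "initial_slope",
    "epitope_map",
    "read_buildup_table",
    "fit_table",
]

#: Standard saturation-time grid (s) for STD build-up experiments.
DEFAULT_TSAT_GRID = np.array([0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0])

# deterministic fit policy
_KSAT_INIT_CLIP = (0.01, 10.0)  # 1/s
_STDMAX_BOUNDS = (0.0, 100.0)   # percent
_KSAT_BOUNDS = (0.0, 50.0)      # 1/s


@dataclass(frozen=True)
class BuildupSeries:
    """Per-proton (t_sat, STD%) observations; t_sat strictly increasing."""

    proton_id: str
    t_sat: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t_sat, float)
        s = np.asarray(self.std, float)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("t_sat and std must be 1-D arrays of equal length")
        if np.any(t <= 0):
            raise ValueError("saturation times must be positive")
        if np.any(np.diff(t) <= 0):
            raise ValueError("saturation times must be strictly increasing")
        object.__setattr__(self, "t_sat", t)
        object.__setattr__(self, "std", s)

    def __len__(self):
        return len(self.t_sat)


@dataclass(frozen=True)
class BuildupFit:
    """Fitted (STD_max, k_sat) with STD0 = STD_max * k_sat."""

    proton_id: str
    std_max: float
    k_sat: float
    std0: float
    covariance: np.ndarray  # 2x2 for (std_max, k_sat); NaN if unavailable
    rss: float

    @property
    def se_std_max(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def se_k_sat(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    @property
    def se_std0(self) -> float:
        """Delta-method standard error of STD0 = STD_max * k_sat."""
        g = np.array([self.k_sat, self.std_max])
        return float(np.sqrt(g @ self.covariance @ g))


@dataclass(frozen=True)
class EpitopeMap:
    """Relative STD percentages with the 100 % reference proton."""

    values: Dict[str, float]
    reference_id: str

    def __post_init__(self):
        vmax = max(self.values.values())
        if abs(vmax - 100.0) > 1e-9:
            raise ValueError("epitope map maximum must equal 100")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name="relative_std_percent")


def buildup_model(t, std_max, k_sat):
    """Mono-exponential STD build-up."""
    return std_max * (1.0 - np.exp(-k_sat * np.asarray(t, float)))


def fractional_std(i0: float, isat: float) -> float:
    """Fractional STD percentage eta = (I0 - Isat) / I0 * 100.

    ``i0`` is the reference (off-resonance) intensity and ``isat`` the
    on-resonance (saturated) intensity of the same signal.
    """
    if i0 <= 0:
        raise ValueError("reference intensity I0 must be positive")
    return (i0 - isat) / i0 * 100.0


def fit_buildup(series: BuildupSeries) -> BuildupFit:
    """Nonlinear least-squares fit of the mono-exponential build-up.

    Deterministic: initialization is ``std_max0 = max(std)`` and
    ``k_sat0 = -ln(1 - STD(t1)/std_max0)/t1`` clipped to [0.01, 10] 1/s;
    bounds std_max in [0, 100] %, k_sat in [0, 50] 1/s; unweighted
    residuals.

    Raises
    ------
    ValueError
        Fewer than 3 points, or all-zero STD values.
    RuntimeError
        Solver failure (with lmfit diagnostics).
    """
    if len(series) < 3:
        raise ValueError(
            f"proton {series.proton_id!r}: need >=3 saturation times to fit, "
            f"got {len(series)}"
        )
    if np.allclose(series.std, 0.0):
        raise ValueError(f"proton {series.proton_id!r}: all-zero STD series")

    std_max0 = float(np.max(series.std))
    ratio = series.std[0] / std_max0
    if 0.0 < ratio < 1.0:
        k0 = -math.log1p(-ratio) / series.t_sat[0]
    else:
        k0 = 1.0
    k0 = float(np.clip(k0, *_KSAT_INIT_CLIP))

    params = lmfit.Parameters()
    params.add("std_max", value=std_max0, min=_STDMAX_BOUNDS[0], max=_STDMAX_BOUNDS[1])
    params.add("k_sat", value=k0, min=_KSAT_BOUNDS[0], max=_KSAT_BOUNDS[1])

    def residual(p):
        return buildup_model(series.t_sat, p["std_max"], p["k_sat"]) - series.std

    result = lmfit.minimize(residual, params, method="least_squares",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if not result.success:
        raise RuntimeError(
            f"proton {series.proton_id!r}: build-up fit failed: {result.message}"
        )
    std_max = float(result.params["std_max"].value)
    k_sat = float(result.params["k_sat"].value)
    if result.covar is not None:
        cov = np.asarray(result.covar, float)
    else:
        cov = np.full((2, 2), np.nan)
    return BuildupFit(
        proton_id=series.proton_id,
        std_max=std_max,
        k_sat=k_sat,
        std0=std_max * k_sat,
        covariance=cov,
        rss=float(np.sum(result.residual**2)),
    )


def initial_slope(fit: BuildupFit) -> float:
    """STD0 = STD_max * k_sat, the build-up slope at zero saturation time."""
    return fit.std_max * fit.k_sat


def epitope_map(values: Mapping[str, float]) -> EpitopeMap:
    """Normalize per-proton values to 100 % at the maximum.

    Accepts initial slopes (STD0) or fixed-time STD values.  Ties for
    the maximum resolve to the first proton in input order.
    """
    if not values:
        raise ValueError("epitope_map needs at least one proton value")
    keys = list(values.keys())
    arr = np.array([values[k] for k in keys], float)
    if np.any(arr < 0):
        raise ValueError("epitope values must be non-negative")
    vmax = arr.max()
    if vmax <= 0:
        raise ValueError("all epitope values are zero; nothing to normalize")
    ref = keys[int(np.argmax(arr))]
    rel = {k: float(v / vmax * 100.0) for k, v in zip(keys, arr)}
    return EpitopeMap(values=rel, reference_id=ref)


# ---------------------------------------------------------------------------
# tabular I/O

def read_buildup_table(path_or_buf, sep: str = None) -> Dict[str, BuildupSeries]:
    """Read build-up curves from CSV/TSV.

    Long format needs columns ``proton_id, t_sat_s, std_percent``; wide
    format needs a ``proton_id`` column and one numeric column per
    saturation time (header = t_sat in seconds).
    """
    df = pd.read_csv(path_or_buf, sep=sep, engine="python")
    cols = set(df.columns)
    out: Dict[str, BuildupSeries] = {}
    if {"proton_id", "t_sat_s", "std_percent"} <= cols:
        for pid, grp in df.groupby("proton_id", sort=False):
            grp = grp.sort_values("t_sat_s")
            out[str(pid)] = BuildupSeries(
                str(pid), grp["t_sat_s"].to_numpy(float), grp["std_percent"].to_numpy(float)
            )
    elif "proton_id" in cols:
        tcols = [c for c in df.columns if c != "proton_id"]
        tvals = np.array([float(c) for c in tcols])
        order = np.argsort(tvals)
        for _, row in df.iterrows():
            pid = str(row["proton_id"])
            out[pid] = BuildupSeries(
                pid, tvals[order], row[tcols].to_numpy(float)[order]
            )
    else:
        raise ValueError(
            "unrecognized build-up table layout: need long columns "
            "(proton_id, t_sat_s, std_percent) or wide (proton_id + one "
            "column per saturation time)"
        )
    return out


def fit_table(curves: Mapping[str, BuildupSeries]) -> pd.DataFrame:
    """Fit every proton and tabulate (std_max, k_sat, std0, SEs, rss)."""
    rows = []
    for pid, series in curves.items():
        f = fit_buildup(series)
        rows.append(
            {
                "proton_id": pid,
                "std_max": f.std_max,
                "k_sat": f.k_sat,
                "std0": f.std0,
                "se_std_max": f.se_std_max,
                "se_k_sat": f.se_k_sat,
                "se_std0": f.se_std0,
                "rss": f.rss,
            }
        )
    return pd.DataFrame(rows)
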