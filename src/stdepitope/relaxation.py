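"""Relaxation-matrix prediction of STD intensities ("CORCEMA-style").

Given a protonated 3-D structure of a protein–ligand complex and the
two-site exchange kinetics (free ligand + protein <-> complex), this
module predicts the percentage fractional intensity change

    S_calc,k(t) = (I_0k - I_k(t)) * 100 / I_0k

of every ligand proton k over a grid of saturation times.  The engine:

1. builds the dipolar relaxation matrix of the bound complex (Solomon
   cross- and auto-relaxation rates, isotropic rigid tumbling at
   tau_c_bound) and of the free ligand (intra-ligand terms only, at
   tau_c_free);
2. couples bound and free ligand magnetization with pseudo-first-order
   exchange rates k_off (bound->free) and k_on*[P]_free (free->bound),
   balanced by the equilibrium populations so total ligand magnetization
   is conserved;
3. clamps the saturated protein protons at zero z-magnetization
   (instantaneous, complete saturation) and propagates the remaining
   deviations from thermal equilibrium in closed form via matrix
   exponentials of the reduced generator;
4. reports the population-weighted (fast-exchange averaged) ligand
   observable as S_calc percentages.

All rates are SI; distances enter in Å, correlation times in ns and the
spectrometer frequency in MHz at the interface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.constants import hbar, mu_0, physical_constants

from .structure import ProtonSet, distance_matrix

__all__ = [
    "ExchangeModel",
    "SpinSystem",
    "GeneratorBasis",
    "STDPrediction",
    "Populations",
    "equilibrium_populations",
    "dipolar_rates",
    "assemble_generator",
    "simulate_std",
    "predict_for_structure",
    "average_equivalent",
    "DEFAULT_KOFF",
]

#: Default dissociation rate (1/s) assumed when only K_d is supplied;
#: typical of the fast-exchange regime where STD works well.
DEFAULT_KOFF = 100.0

GAMMA_H = physical_constants["proton gyromag. ratio"][0]  # rad/s/T

#: Dipolar prefactor q = (1/10) (mu0/4pi)^2 gammaH^4 hbar^2, in m^6/s^2.
DIPOLAR_Q = 0.1 * (mu_0 / (4 * math.pi)) ** 2 * GAMMA_H**4 * hbar**2


# ---------------------------------------------------------------------------
# exchange model and populations

@dataclass(frozen=True)
class ExchangeModel:
    """Two-site (free <-> bound) exchange and NMR parameters.

    Either ``kd`` (M) or the pair (``k_on`` in 1/M/s, ``k_off`` in 1/s)
    must be given.  With only ``kd``, ``k_off`` defaults to
    :data:`DEFAULT_KOFF` and ``k_on = k_off / kd``.

    Concentrations in M, correlation times in ns, ``larmor`` in MHz,
    ``leak_rate`` (1/s) is an external relaxation added to every
    auto-relaxation rate.
    """

    p_total: float
    l_total: float
    tau_c_free: float
    tau_c_bound: float
    larmor: float
    kd: Optional[float] = None
    k_on: Optional[float] = None
    k_off: Optional[float] = None
    leak_rate: float = 0.0

    def __post_init__(self):
        if self.kd is None:
            if self.k_on is None or self.k_off is None:
                raise ValueError("give kd, or both k_on and k_off")
            if self.k_on <= 0:
                raise ValueError("k_on must be positive when kd is derived from it")
            object.__setattr__(self, "kd", self.k_off / self.k_on)
        else:
            k_off = self.k_off if self.k_off is not None else DEFAULT_KOFF
            object.__setattr__(self, "k_off", k_off)
            object.__setattr__(self, "k_on", k_off / self.kd)
        for name in ("p_total", "l_total", "tau_c_free", "tau_c_bound", "larmor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kd is not None and self.kd <= 0:
            raise ValueError("kd must be positive")
        # zero exchange rates are the frozen-exchange limit (K == 0)
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("exchange rates must be >= 0")
        if self.leak_rate < 0:
            raise ValueError("leak_rate must be >= 0")

    @property
    def omega0(self) -> float:
        """Proton Larmor angular frequency, rad/s."""
        return 2 * math.pi * self.larmor * 1e6


@dataclass(frozen=True)
class Populations:
    """Equilibrium species concentrations for 1:1 binding (M)."""

    pl_bound: float
    p_free: float
    l_free: float
    f_bound_ligand: float


def equilibrium_populations(m: ExchangeModel) -> Populations:
    """Solve the 1:1 binding equilibrium for the complex concentration.

    The physical root of ``[PL]^2 - [PL](P_t + L_t + K_d) + P_t L_t = 0``
    in ``[0, min(P_t, L_t)]`` is taken; ``f_bound_ligand = [PL]/L_t`` is
    the bound fraction of ligand that weights the exchange coupling.
    """
    pt, lt, kd = m.p_total, m.l_total, m.kd
    b = pt + lt + kd
    disc = b * b - 4.0 * pt * lt
    pl = (b - math.sqrt(disc)) / 2.0
    pl = min(max(pl, 0.0), min(pt, lt))
    return Populations(
        pl_bound=pl,
        p_free=pt - pl,
        l_free=lt - pl,
        f_bound_ligand=pl / lt,
    )


# ---------------------------------------------------------------------------
# dipolar rates

def _spectral_density(omega: float, tau_c: float) -> float:
    """Lorentzian spectral density J(w) = tau_c / (1 + w^2 tau_c^2), s."""
    return tau_c / (1.0 + (omega * tau_c) ** 2)


def dipolar_rates(
    d: np.ndarray, tau_c: float, larmor: float, leak_rate: float = 0.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Homonuclear dipolar cross-/auto-relaxation rates for a rigid tumbler.

    Parameters
    ----------
    d : (n, n) array
        Interproton distances in Å (zero diagonal).
    tau_c : float
        Rotational correlation time in ns.
    larmor : float
        Spectrometer proton frequency in MHz.
    leak_rate : float
        External relaxation (1/s) added to every auto rate.

    Returns
    -------
    sigma : (n, n) array
        Cross-relaxation rates (1/s), zero diagonal:
        ``sigma_ij = q r^-6 [6 J(2 w0) - J(0)]``.
    rho : (n,) array
        Auto-relaxation rates (1/s):
        ``rho_i = sum_j q r^-6 [6 J(2 w0) + 3 J(w0) + J(0)] + leak``.

    Notes
    -----
    In extreme narrowing (w0 tau_c << 1) sigma is positive and the
    pairwise sigma/rho ratio tends to 1/2; for slow tumbling
    (w0 tau_c >> 1, the spin-diffusion limit relevant to protein
    complexes) sigma is negative.
    """
    d = np.asarray(d, float)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] <= 0):
        raise ValueError("off-diagonal interproton distances must be positive")

    tau = tau_c * 1e-9
    w0 = 2 * math.pi * larmor * 1e6
    j0 = _spectral_density(0.0, tau)
    j1 = _spectral_density(w0, tau)
    j2 = _spectral_density(2 * w0, tau)

    r6 = np.zeros_like(d)
    r6[off] = (d[off] * 1e-10) ** -6.0
    sigma = DIPOLAR_Q * r6 * (6.0 * j2 - j0)
    rho_pair = DIPOLAR_Q * r6 * (6.0 * j2 + 3.0 * j1 + j0)
    rho = rho_pair.sum(axis=1) + leak_rate
    return sigma, rho


# ---------------------------------------------------------------------------
# generator assembly

@dataclass(frozen=True)
class SpinSystem:
    """Proton basis of the coupled bound/free system.

    ``bound_protons`` holds the complex (ligand + protein roles); every
    ligand proton implicitly has a free-state counterpart relaxing with
    the free-ligand correlation time on the same intra-ligand geometry.
    ``saturated_ids`` must be protein protons of the bound set.
    """

    bound_protons: ProtonSet
    saturated_ids: frozenset

    def __post_init__(self):
        protein_ids = {p.id for p in self.bound_protons if p.role == "protein"}
        extra = set(self.saturated_ids) - protein_ids
        if extra:
            raise ValueError(f"saturated ids are not protein protons: {sorted(extra)}")
        object.__setattr__(self, "saturated_ids", frozenset(self.saturated_ids))

    @property
    def ligand_ids(self) -> list:
        return [p.id for p in self.bound_protons if p.role == "ligand"]


@dataclass(frozen=True)
class GeneratorBasis:
    """Ordered state labels of the generator: bound block then free block.

    ``labels`` is a tuple of ``(proton_id, state)`` with state in
    {"bound", "free"}; ``f_bound``/``f_free`` are the equilibrium ligand
    fractions used to form the fast-exchange averaged observable.
    """

    labels: tuple
    f_bound: float
    f_free: float
    #: explicit observed-proton ids; None = protons with a free-state label
    #: (or, lacking any, every bound label — bound-only toy bases)
    observed: tuple = None

    def index(self, proton_id: str, state: str) -> int:
        return self.labels.index((proton_id, state))

    @property
    def ligand_ids(self) -> list:
        """Observed ligand protons, in basis order."""
        if self.observed is not None:
            return list(self.observed)
        free = [pid for pid, st in self.labels if st == "free"]
        if free:
            return free
        return [pid for pid, st in self.labels]


def assemble_generator(
    sys: SpinSystem, m: ExchangeModel
) -> Tuple[np.ndarray, GeneratorBasis]:
    """Build the relaxation + exchange generator D (1/s).

    The magnetization deviations from thermal equilibrium evolve as
    ``dm/dt = -D m``.  D = R + K: R is block diagonal with the full
    dipolar matrix of the complex (at ``tau_c_bound``) and the
    intra-ligand dipolar matrix of the free ligand (at ``tau_c_free``);
    K exchanges each bound ligand proton with its free counterpart at
    rates k_off and k_on*[P]_free, which satisfy detailed balance with
    the equilibrium populations and conserve total ligand magnetization.
    """
    ps = sys.bound_protons
    ids = ps.ids
    roles = [p.role for p in ps]
    lig_idx = [i for i, r in enumerate(roles) if r == "ligand"]
    if not lig_idx:
        raise ValueError("bound proton set contains no ligand protons")
    n = len(ps)
    n_lig = len(lig_idx)

    # bound block: full dipolar matrix of the complex
    sigma_b, rho_b = dipolar_rates(
        distance_matrix(ps), m.tau_c_bound, m.larmor, m.leak_rate
    )
    R_b = sigma_b.copy()
    np.fill_diagonal(R_b, rho_b)

    # free block: intra-ligand dipolar terms on the same ligand geometry
    lig_set = ProtonSet([ps[i] for i in lig_idx], provenance="free ligand mirror")
    sigma_f, rho_f = dipolar_rates(
        distance_matrix(lig_set), m.tau_c_free, m.larmor, m.leak_rate
    )
    R_f = sigma_f.copy()
    np.fill_diagonal(R_f, rho_f)

    D = np.zeros((n + n_lig, n + n_lig))
    D[:n, :n] = R_b
    D[n:, n:] = R_f

    pops = equilibrium_populations(m)
    k_bf = m.k_off                     # bound -> free, per bound molecule
    k_fb = m.k_on * pops.p_free        # free -> bound, per free molecule
    for j, i in enumerate(lig_idx):
        fi = n + j
        D[i, i] += k_bf
        D[i, fi] -= k_bf
        D[fi, fi] += k_fb
        D[fi, i] -= k_fb

    labels = tuple((ids[i], "bound") for i in range(n)) + tuple(
        (ids[i], "free") for i in lig_idx
    )
    basis = GeneratorBasis(
        labels=labels, f_bound=pops.f_bound_ligand, f_free=1.0 - pops.f_bound_ligand
    )
    return D, basis


# ---------------------------------------------------------------------------
# propagation

@dataclass
class STDPrediction:
    """Predicted S_calc percentages over protons x saturation times."""

    values: pd.DataFrame  # index: proton_id, columns: t_sat (s)
    t_sats: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("predicted STD values must be finite")

    def to_tsv(self, path_or_buf) -> None:
        out = self.values.copy()
        out.index.name = "proton_id"
        out.to_csv(path_or_buf, sep="\t")

    def at_time(self, t: float) -> Dict[str, float]:
        col = self.values.columns[np.argmin(np.abs(np.asarray(self.values.columns, float) - t))]
        return self.values[col].to_dict()

    def initial_slopes(self) -> Dict[str, float]:
        """Finite-difference S_calc slope at the earliest time point,
        S(t1)/t1; adequate for toy systems, use fine grids for accuracy."""
        t1 = float(self.values.columns[0])
        return {k: v / t1 for k, v in self.values.iloc[:, 0].to_dict().items()}


def _clamped_partition(D, basis, saturated_ids):
    sat = set(saturated_ids)
    clamped = [i for i, (pid, st) in enumerate(basis.labels) if st == "bound" and pid in sat]
    free_running = [i for i in range(len(basis.labels)) if i not in clamped]
    return np.array(free_running, int), np.array(clamped, int)


def _observable(basis: GeneratorBasis, m_full: np.ndarray) -> Dict[str, float]:
    """Fast-exchange averaged S_calc per ligand proton from the full
    deviation vector (clamped entries included at -1)."""
    lookup = {lab: i for i, lab in enumerate(basis.labels)}
    out = {}
    for pid in basis.ligand_ids:
        s = 0.0
        if (pid, "bound") in lookup:
            s += basis.f_bound * m_full[lookup[(pid, "bound")]]
        if (pid, "free") in lookup:
            s += basis.f_free * m_full[lookup[(pid, "free")]]
        out[pid] = -100.0 * s
    return out


def simulate_std(
    D: np.ndarray,
    basis: GeneratorBasis,
    saturated_ids,
    t_sats: Sequence[float],
) -> STDPrediction:
    """Propagate the clamped-saturation system and report S_calc,k.

    The saturated protein protons are held at zero z-magnetization
    (deviation -M0) from t = 0; the remaining deviations obey
    ``dm_r/dt = -D_rr m_r - D_rs m_s`` and are propagated in closed form,
    ``m_r(t) = (I - exp(-D_rr t)) m_ss`` with ``D_rr m_ss = -D_rs m_s``.
    The observed ligand intensity is the population-weighted sum of the
    bound and free counterparts.  A singular reduced generator (no
    relaxation pathway) falls back to numerical integration with a
    warning.
    """
    t_sats = np.asarray(t_sats, float)
    if np.any(t_sats < 0):
        raise ValueError("saturation times must be >= 0")
    n = len(basis.labels)
    if D.shape != (n, n):
        raise ValueError("generator shape does not match basis")

    run, clamp = _clamped_partition(D, basis, saturated_ids)
    lig_ids = basis.ligand_ids
    if clamp.size == 0:
        values = pd.DataFrame(0.0, index=lig_ids, columns=t_sats)
        return STDPrediction(values=values, t_sats=t_sats,
                             metadata={"note": "empty saturated set"})

    D_rr = D[np.ix_(run, run)]
    forcing = D[np.ix_(run, clamp)] @ np.full(clamp.size, -1.0)

    m_full = np.zeros((len(t_sats), n))
    m_full[:, clamp] = -1.0
    try:
        m_ss = np.linalg.solve(D_rr, -forcing)
        if not np.all(np.isfinite(m_ss)):
            raise np.linalg.LinAlgError("non-finite steady state")
        for k, t in enumerate(t_sats):
            if t == 0.0:
                continue
            m_full[k, run] = m_ss - scipy.linalg.expm(-D_rr * t) @ m_ss
    except np.linalg.LinAlgError:
        warnings.warn(
            "reduced relaxation generator is singular; falling back to "
            "numerical integration", RuntimeWarning
        )
        from scipy.integrate import solve_ivp

        tmax = float(t_sats.max()) if t_sats.size else 0.0
        if tmax > 0:
            sol = solve_ivp(
                lambda t, y: -D_rr @ y - forcing,
                (0.0, tmax), np.zeros(run.size),
                method="Radau", rtol=1e-10, atol=1e-12,
                t_eval=np.unique(t_sats[t_sats > 0]),
            )
            if not sol.success:
                raise RuntimeError(f"fallback integration failed: {sol.message}")
            for k, t in enumerate(t_sats):
                if t > 0:
                    m_full[k, run] = sol.y[:, np.searchsorted(sol.t, t)]

    rows = {pid: [] for pid in lig_ids}
    for k in range(len(t_sats)):
        obs = _observable(basis, m_full[k])
        for pid in lig_ids:
            rows[pid].append(obs[pid])
    values = pd.DataFrame(rows, index=t_sats).T
    values = values.loc[lig_ids]
    return STDPrediction(values=values, t_sats=t_sats, metadata={})


# ---------------------------------------------------------------------------
# end-to-end pipeline

def predict_for_structure(
    ps_complex: ProtonSet,
    m: ExchangeModel,
    cutoff: float = 8.0,
    t_sats: Sequence[float] = None,
    on_resonance: float = 0.75,
    bandwidth: float = math.inf,
    drop_exchangeable: bool = True,
) -> STDPrediction:
    """Full prediction pipeline for a protonated complex.

    Stages: exchangeable-proton filter -> binding-site cutoff ->
    saturated-set assignment -> generator assembly -> clamped
    propagation.  The default grid is the nine standard saturation
    times (0.5–6 s).
    """
    from .buildup import DEFAULT_TSAT_GRID
    from .structure import assign_saturated_set, filter_exchangeable, select_binding_site

    if t_sats is None:
        t_sats = DEFAULT_TSAT_GRID
    ps = filter_exchangeable(ps_complex) if drop_exchangeable else ps_complex
    ps = select_binding_site(ps, cutoff)
    saturated = assign_saturated_set(ps, on_resonance, bandwidth)
    if not saturated:
        raise ValueError(
            f"no saturated protein protons within {cutoff} Å of the ligand; "
            "increase the cutoff or check the structure"
        )
    sys = SpinSystem(bound_protons=ps, saturated_ids=frozenset(saturated))
    D, basis = assemble_generator(sys, m)
    pred = simulate_std(D, basis, saturated, t_sats)
    pred.metadata.update(
        {
            "cutoff_a": cutoff,
            "n_protons": len(ps),
            "n_saturated": len(saturated),
            "kd_m": m.kd,
            "k_on_per_m_s": m.k_on,
            "k_off_per_s": m.k_off,
            "tau_c_bound_ns": m.tau_c_bound,
            "tau_c_free_ns": m.tau_c_free,
            "larmor_mhz": m.larmor,
            "leak_per_s": m.leak_rate,
        }
    )
    return pred


def average_equivalent(
    pred: STDPrediction, groups: Mapping[str, Sequence[str]]
) -> STDPrediction:
    """Average predicted STD over user-declared equivalent protons.

    Methyl and other degenerate protons appear as one experimental peak;
    this post-hoc averaging replaces each declared group by the mean of
    its members' predictions under the group label.  Protons not listed
    in any group pass through unchanged.
    """
    grouped = set()
    rows = {}
    for label, members in groups.items():
        missing = [p for p in members if p not in pred.values.index]
        if missing:
            raise KeyError(f"group {label!r}: protons not in prediction: {missing}")
        rows[label] = pred.values.loc[list(members)].mean(axis=0)
        grouped.update(members)
    for pid in pred.values.index:
        if pid not in grouped:
            rows[pid] = pred.values.loc[pid]
    values = pd.DataFrame(rows).T
    meta = dict(pred.metadata)
    meta["equivalence_groups"] = {k: list(v) for k, v in groups.items()}
    return STDPrediction(values=values, t_sats=pred.t_sats, metadata=meta)
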