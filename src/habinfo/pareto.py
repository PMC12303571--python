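"""Stationary information-dissipation Pareto optimization over (beta, sigma).

Under a prolonged constant signal H_st the system settles into a stationary
state; the two competing objectives are the stationary readout-signal
information I_st (nats) and the total energy consumption per unit energy

    E_tot_st = delta_Q_R_st + E_int_st,

with delta_Q_R the receptor cycle dissipation per unit temperature and
E_int = tau_S J_prod / sigma the storage-production term.  At a 1-D
birth-death stationary state the *net* storage flux vanishes identically, so
the energy bookkeeping uses the one-way production flux by default (the net
flux remains available as a mode for transient budgets).

The Pareto functional L = gamma I_st - (1 - gamma) E_tot_st is maximized by
grid search; sweeping gamma in [0, 1] traces the optimal front in the
(E_tot_st, I_st) plane.  Allowing the inhibition strength to adapt to the
signal, kappa = H_max / (alpha sigma), collapses the fronts for different
signal strengths onto a single curve.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .info import mutual_information_UH, production_flux, internal_flux, receptor_dissipation
from .params import ModelParams, SignalProtocol
from .tss import TSSSolver

__all__ = [
    "ParetoPoint",
    "stationary_objectives",
    "objective_grid",
    "pareto_front",
    "nondominated",
    "adaptive_kappa_front",
    "front_distance",
]


@dataclass(frozen=True)
class ParetoPoint:
    beta: float
    sigma: float
    gamma: float
    I_st: float
    E_int_st: float
    dQ_R_st: float
    E_tot_st: float
    L: float


def stationary_objectives(
    params: ModelParams,
    H_st: float,
    solver: Optional[TSSSolver] = None,
    flux_mode: str = "production",
) -> Tuple[float, float, float, float]:
    """(I_st, E_tot_st, dQ_R_st, E_int_st) at the stationary state under H_st."""
    solver = solver or TSSSolver(params)
    p = solver.params
    q = solver.stationary_q(H_st)
    I_st = mutual_information_UH(solver, q, H_st)
    joint = solver.joint_from_q(q, H_st)
    if flux_mode == "production":
        J = production_flux(p, joint)
    elif flux_mode == "net":
        J = internal_flux(p, joint)
    else:
        raise ValueError(f"unknown flux_mode {flux_mode!r}")
    E_int = p.tau_S * J / p.sigma
    dQ = receptor_dissipation(p, H_st, float(q @ solver.grid_s))
    return I_st, dQ + E_int, dQ, E_int


def _grid_params(base: ModelParams, beta: float, sigma: float,
                 adaptive_H: Optional[float]) -> ModelParams:
    kw = {}
    if adaptive_H is not None:
        kw["kappa_override"] = adaptive_H / (base.alpha * sigma)
    return replace(base, beta=beta, sigma=sigma,
                   V=float("nan"), c=float("nan"), kappa=float("nan"), **kw)


def objective_grid(
    base_params: ModelParams,
    beta_grid: Sequence[float],
    sigma_grid: Sequence[float],
    H_st: float,
    adaptive_kappa: bool = False,
    flux_mode: str = "production",
) -> pd.DataFrame:
    """Stationary objectives on the full (beta, sigma) grid."""
    rows = []
    for beta, sigma in itertools.product(beta_grid, sigma_grid):
        p = _grid_params(base_params, beta, sigma, H_st if adaptive_kappa else None)
        I, E, dQ, Ei = stationary_objectives(p, H_st, flux_mode=flux_mode)
        rows.append({"beta": beta, "sigma": sigma, "I_st": I,
                     "E_tot_st": E, "dQ_R_st": dQ, "E_int_st": Ei})
    return pd.DataFrame(rows)


def pareto_front(
    base_params: ModelParams,
    beta_grid: Sequence[float],
    sigma_grid: Sequence[float],
    gamma_grid: Optional[Sequence[float]] = None,
    H_st: float = 10.0,
    adaptive_kappa: bool = False,
    grid: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Maximizers of L = gamma I - (1-gamma) E_tot for each gamma, deduplicated.

    The returned frame has one row per distinct optimal (beta, sigma), with
    the smallest gamma selecting it, sorted by E_tot_st.  Also attaches, per
    beta, the optimal sigma at the information-greedy end (``attrs['sigma_opt']``).
    """
    gamma_grid = np.arange(0.0, 1.0 + 1e-12, 0.01) if gamma_grid is None else gamma_grid
    if grid is None:
        grid = objective_grid(base_params, beta_grid, sigma_grid, H_st, adaptive_kappa)
    if grid["I_st"].isna().all():
        raise ValueError("objective grid is all-NaN")
    I = grid["I_st"].to_numpy()
    E = grid["E_tot_st"].to_numpy()
    rows = []
    seen = {}
    for gamma in gamma_grid:
        L = gamma * I - (1.0 - gamma) * E
        i = int(np.nanargmax(L))
        key = (grid["beta"].iloc[i], grid["sigma"].iloc[i])
        if key not in seen:
            seen[key] = ParetoPoint(
                beta=float(key[0]), sigma=float(key[1]), gamma=float(gamma),
                I_st=float(I[i]), E_int_st=float(grid["E_int_st"].iloc[i]),
                dQ_R_st=float(grid["dQ_R_st"].iloc[i]),
                E_tot_st=float(E[i]), L=float(L[i]),
            )
    front = pd.DataFrame([vars(p) for p in seen.values()]).sort_values("E_tot_st")
    front = front.reset_index(drop=True)
    # optimal sigma at fixed beta (information-dissipation compromise curve)
    sig_opt = {}
    for beta in np.unique(grid["beta"]):
        sub = grid[grid["beta"] == beta]
        on_front = front[front["beta"] == beta]
        if len(on_front):
            sig_opt[float(beta)] = float(on_front["sigma"].iloc[0])
    front.attrs["sigma_opt"] = sig_opt
    return front


def nondominated(points: pd.DataFrame) -> pd.DataFrame:
    """Rows not dominated in (minimize E_tot_st, maximize I_st)."""
    E = points["E_tot_st"].to_numpy()
    I = points["I_st"].to_numpy()
    keep = np.ones(len(points), dtype=bool)
    for i in range(len(points)):
        dom = (E <= E[i]) & (I >= I[i]) & ((E < E[i]) | (I > I[i]))
        if dom.any():
            keep[i] = False
    return points[keep].sort_values("E_tot_st").reset_index(drop=True)


def front_distance(f1: pd.DataFrame, f2: pd.DataFrame) -> float:
    """Mean |I_1(E) - I_2(E)| over the overlapping E range, after interpolation."""
    e_lo = max(f1["E_tot_st"].min(), f2["E_tot_st"].min())
    e_hi = min(f1["E_tot_st"].max(), f2["E_tot_st"].max())
    if e_hi <= e_lo:
        return float("nan")  # disjoint budgets: no disagreement measurable
    E = np.linspace(e_lo, e_hi, 200)
    def interp(f):
        idx = np.argsort(f["E_tot_st"].to_numpy())
        return np.interp(E, f["E_tot_st"].to_numpy()[idx], f["I_st"].to_numpy()[idx])
    return float(np.mean(np.abs(interp(f1) - interp(f2))))


def adaptive_kappa_front(
    base_params: ModelParams,
    H_max_list: Sequence[float],
    beta_grid: Sequence[float],
    sigma_grid: Sequence[float],
    gamma_grid: Optional[Sequence[float]] = None,
) -> dict:
    """Fronts per signal strength, with and without the adaptive inhibition.

    Returns ``{"adaptive": {H: front}, "fixed": {H: front},
    "collapse_adaptive": max pairwise distance among adaptive fronts,
    "spread_fixed": max pairwise distance among fixed-kappa fronts}``.
    """
    out = {"adaptive": {}, "fixed": {}}
    for H in H_max_list:
        ga = objective_grid(base_params, beta_grid, sigma_grid, H, adaptive_kappa=True)
        gf = objective_grid(base_params, beta_grid, sigma_grid, H, adaptive_kappa=False)
        out["adaptive"][H] = nondominated(ga)
        out["fixed"][H] = nondominated(gf)

    def max_pairwise(fronts):
        ds = [front_distance(a, b) for a, b in itertools.combinations(fronts, 2)]
        ds = [d for d in ds if math.isfinite(d)]
        return max(ds) if ds else 0.0

    out["collapse_adaptive"] = max_pairwise(list(out["adaptive"].values()))
    out["spread_fixed"] = max_pairwise(list(out["fixed"].values()))
    return out
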