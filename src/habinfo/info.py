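"""Information-theoretic and thermodynamic observables.

All information quantities are reported in nats and are computed from the
timescale-separation conditionals: given the storage marginal q(s) at time t
and the exponential signal law of mean <H>(t), the readout law conditioned
on the signal is a two-Poisson mixture

    p(u | h) = a(h) Poi_A(u) + (1 - a(h)) Poi_P(u),   a(h) = sum_s q(s) p_A(s, h),

and the (U, S) pair conditioned on the signal factorizes as
p(u, s | h) = q(s) [p_A(s,h) Poi_A(u) + (1-p_A(s,h)) Poi_P(u)].  A direct
consequence of this structure is that the storage alone carries no signal
information, I_{S,H} = 0 identically: the storage feels the environment only
through the already-equilibrated readout.

The thermodynamic observables are the net internal energy flux of storage
production J_int, the receptor cycle dissipation per unit temperature
delta_Q_R = beta (H + kappa sigma <S>/N_S), and the stationary energy
budget used by the Pareto optimization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .hallmarks import NotHabituatingError, habituation_time, peak_responses
from .params import ModelParams, SignalProtocol
from .tss import JointDistribution, TSSSolver

__all__ = [
    "entropy",
    "mutual_information_UH",
    "mutual_information_SH",
    "feedback_information",
    "internal_flux",
    "receptor_dissipation",
    "info_gain",
    "info_scan",
    "InfoGain",
]

NATS_TO_BITS = 1.0 / math.log(2.0)


def entropy(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy in nats, with the 0 log 0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(p), 0.0)
    return -t.sum(axis=axis)


def _mix_entropy(solver: TSSSolver, a: np.ndarray) -> np.ndarray:
    """Entropy of the two-Poisson mixture for each activation weight in ``a``."""
    a = np.atleast_1d(np.asarray(a, dtype=float))
    mix = a[..., None] * solver.pU[1] + (1.0 - a[..., None]) * solver.pU[0]
    return entropy(mix, axis=-1)


def _lam_cache(solver: TSSSolver, mean_signal: float) -> dict:
    cache = getattr(solver, "_info_cache", None)
    if cache is None:
        cache = solver._info_cache = {}
    key = float(mean_signal)
    if key not in cache:
        h, w = solver.h_nodes(mean_signal)
        pa = solver.receptor_stationary_given_sh(solver.grid_s[:, None], h[None, :])
        abar_s = pa @ w  # E_h[p_A | s]
        # entropy of the u-mixture conditional on (s, h_j), h-averaged per s
        cond_ent = _mix_entropy(solver, pa) @ w
        marg_ent_s = _mix_entropy(solver, abar_s)
        cache[key] = {
            "pa": pa, "w": w, "abar_s": abar_s,
            "cond_ent_s": cond_ent, "marg_ent_s": marg_ent_s,
        }
    return cache[key]


def mutual_information_UH(solver: TSSSolver, q: np.ndarray, mean_signal: float) -> float:
    """I_{U,H}(t) = H[p_U] - E_h H[p_{U|h}] for storage marginal ``q``."""
    c = _lam_cache(solver, mean_signal)
    a_h = q @ c["pa"]  # activation probability given h_j
    a_bar = float(a_h @ c["w"])
    I = float(_mix_entropy(solver, a_bar)[0] - _mix_entropy(solver, a_h) @ c["w"])
    return max(I, 0.0)


def mutual_information_SH(solver: TSSSolver, q: np.ndarray, mean_signal: float) -> float:
    """I_{S,H} computed literally from the marginalized conditionals.

    Under timescale separation p_{S|H}(s|h) = q(s) for every h, so the value
    is zero to machine precision; the sum is carried out explicitly rather
    than short-circuited.
    """
    c = _lam_cache(solver, mean_signal)
    pa = c["pa"]
    # sum over u and r of p(u|r) p(r|s,h) q(s): the u-sums are exactly 1
    sum_pU = solver.pU.sum(axis=1)  # (2,)
    p_S_given_h = q[:, None] * (pa * sum_pU[1] + (1.0 - pa) * sum_pU[0])
    p_S_given_h /= p_S_given_h.sum(axis=0, keepdims=True)
    H_cond = entropy(p_S_given_h, axis=0) @ c["w"]
    p_S = (p_S_given_h * c["w"][None, :]).sum(axis=1)
    return float(entropy(p_S) - H_cond)


def feedback_information(
    solver: TSSSolver, q: np.ndarray, mean_signal: float
) -> Tuple[float, float]:
    """(I_{(U,S),H}, Delta I_f): joint information and its excess over I_{U,H}."""
    c = _lam_cache(solver, mean_signal)
    I_USH = float(q @ (c["marg_ent_s"] - c["cond_ent_s"]))
    I_UH = mutual_information_UH(solver, q, mean_signal)
    return I_USH, I_USH - I_UH


def internal_flux(params: ModelParams, p_US: JointDistribution) -> float:
    """Net internal energy flux J_int of storage production (sign free).

    sigma * sum over the s -> s+1 cuts of (birth current - death current),
    respecting the capacity cap: births are forbidden at s = N_S.
    """
    vals = p_US.values
    u = p_US.grid_u.astype(float)
    s = p_US.grid_s.astype(float)
    G = params.Gamma_S0
    ebs = math.exp(-params.beta * params.sigma)
    birth = ebs * G * float(u @ vals[:, :-1].sum(axis=1))  # s < N_S only
    death = G * float(vals.sum(axis=0) @ s)
    return params.sigma * (birth - death)


def production_flux(params: ModelParams, p_US: JointDistribution) -> float:
    """One-way storage production energy flux sigma * sum Gamma_{s->s+1} p."""
    vals = p_US.values
    u = p_US.grid_u.astype(float)
    ebs = math.exp(-params.beta * params.sigma)
    return params.sigma * ebs * params.Gamma_S0 * float(u @ vals[:, :-1].sum(axis=1))


def receptor_dissipation(params: ModelParams, H_st: float, mean_S: float) -> float:
    """Receptor cycle affinity per unit temperature, beta (H + kappa sigma <S>/N_S)."""
    if H_st < 0:
        raise ValueError("H_st must be >= 0")
    if not (0 <= mean_S <= params.N_S):
        raise ValueError("mean_S outside [0, N_S]")
    return params.beta * (H_st + params.kappa * params.sigma * mean_S / params.N_S)


@dataclass
class InfoGain:
    """Differences of the observables between first and habituated stimulus."""

    n_hab: int
    I_UH_in: float
    I_UH_hab: float
    DeltaI_UH: float
    DeltaI_f_in: float
    DeltaI_f_hab: float
    DeltaDeltaI_f: float
    J_int_in: float
    J_int_hab: float
    DeltaJ_int: float
    DeltaU: float


def info_gain(
    solver: TSSSolver,
    protocol: SignalProtocol,
    hab_threshold: float = 0.005,
    traj=None,
) -> InfoGain:
    """Information gain and flux change between first and habituated stimulus.

    Both states are sampled at the same phase of their stimulus window (the
    trajectory's sampling phase, end of window by default).
    """
    traj = solver.evolve(protocol, record=False) if traj is None else traj
    peaks = peak_responses(traj, protocol)
    _, n_hab = habituation_time(peaks, protocol, hab_threshold)
    if n_hab is None:
        raise NotHabituatingError("protocol does not habituate; info gain undefined")
    s_in = traj.stim_samples[0]
    s_hab = traj.stim_samples[n_hab - 1]
    lam_mean = protocol.H_max
    I_in = mutual_information_UH(solver, s_in["q"], lam_mean)
    I_hab = mutual_information_UH(solver, s_hab["q"], lam_mean)
    _, dIf_in = feedback_information(solver, s_in["q"], lam_mean)
    _, dIf_hab = feedback_information(solver, s_hab["q"], lam_mean)
    J_in = internal_flux(solver.params, solver.joint_from_q(s_in["q"], lam_mean))
    J_hab = internal_flux(solver.params, solver.joint_from_q(s_hab["q"], lam_mean))
    return InfoGain(
        n_hab=n_hab,
        I_UH_in=I_in, I_UH_hab=I_hab, DeltaI_UH=I_hab - I_in,
        DeltaI_f_in=dIf_in, DeltaI_f_hab=dIf_hab, DeltaDeltaI_f=dIf_hab - dIf_in,
        J_int_in=J_in, J_int_hab=J_hab, DeltaJ_int=J_hab - J_in,
        DeltaU=s_hab["U"] - s_in["U"],
    )


def info_scan(
    base_params: ModelParams,
    beta_grid: Sequence[float],
    sigma_grid: Sequence[float],
    protocol: Optional[SignalProtocol] = None,
    track_min_dIf: bool = True,
) -> pd.DataFrame:
    """Sweep (beta, sigma) under a switching protocol.

    Returns one row per grid point with the first/habituated information,
    feedback information and internal flux, their changes, the habituation
    strength, and (optionally) the minimum Delta I_f over all epoch-boundary
    states of the run.  Non-habituating points carry NaN deltas.
    """
    from dataclasses import replace

    protocol = protocol or SignalProtocol(n_stimuli=25)
    rows = []
    for beta in beta_grid:
        for sigma in sigma_grid:
            params = replace(base_params, beta=beta, sigma=sigma,
                             V=float("nan"), c=float("nan"), kappa=float("nan"))
            solver = TSSSolver(params)
            traj = solver.evolve(protocol, record=False)
            row = {"beta": beta, "sigma": sigma}
            try:
                g = info_gain(solver, protocol, traj=traj)
                row.update(
                    n_hab=g.n_hab, I_in=g.I_UH_in, I_hab=g.I_UH_hab, dI=g.DeltaI_UH,
                    dIf_in=g.DeltaI_f_in, dIf_hab=g.DeltaI_f_hab, ddIf=g.DeltaDeltaI_f,
                    J_in=g.J_int_in, J_hab=g.J_int_hab, dJ=g.DeltaJ_int, dU=g.DeltaU,
                )
            except NotHabituatingError:
                row.update({k: float("nan") for k in
                            ("n_hab", "I_in", "I_hab", "dI", "dIf_in", "dIf_hab",
                             "ddIf", "J_in", "J_hab", "dJ", "dU")})
            if track_min_dIf:
                m = np.inf
                for snap in traj.snapshots:
                    _, dIf = feedback_information(solver, snap["q"], snap["mean_signal"])
                    m = min(m, dIf)
                row["min_dIf"] = m
            rows.append(row)
    return pd.DataFrame(rows)
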