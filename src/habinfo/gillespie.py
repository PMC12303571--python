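"""Exact stochastic simulation of the full four-variable model (r, u, s, h).

This is the brute-force oracle for the timescale-separation solver: the
stochastic simulation algorithm over the seven reaction channels (receptor
activation/deactivation along both pathways, readout birth/death, storage
birth/death with the capacity cap) plus an environment channel.  The
environment is a jump process: ``h`` is redrawn from the exponential law of
the current epoch at exponential waiting times of mean tau_H, and at every
protocol switch, which reproduces the prescribed time-dependent marginal and
decorrelation across redraws.

Between events (and epoch boundaries) all rates are constant, so advancing
to a boundary and redrawing the waiting time is exact.  Each trajectory
consumes its own counter-derived seed, making ensembles bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .params import ModelParams, SignalProtocol, derive_energies
from .tss import TSSSolver

__all__ = ["EnsembleTrajectories", "simulate", "ensemble_moments", "joint_histogram",
           "flux_estimate", "SignalOverflowError", "reduced_model_params",
           "reduced_validation_protocol"]


def reduced_model_params() -> ModelParams:
    """Reduced model used for solver/simulation cross-validation.

    Small storage capacity and readout means keep the state space tiny; the
    mild drive (H_ref = 3 with beta = 1) keeps every Arrhenius exponent in a
    range where the exact simulation is affordable, and the deep timescale
    ladder tau_U : tau_R : tau_H : tau_S = 1e-3 : 4e-3 : 2e-2 : 1 puts the
    simulation inside the timescale-separation regime the solver assumes.
    """
    return derive_energies(ModelParams(
        N_S=5, U_mean_passive=5.0, U_mean_active=20.0,
        beta=1.0, sigma=0.5, H_ref=3.0, Gamma_S0=1.0,
        tau_R=4e-3, tau_U=1e-3, tau_H=2e-2, max_tau_ratio=100.0,
    ))


def reduced_validation_protocol() -> SignalProtocol:
    """Three-stimulus square wave matched to the reduced model's timescales."""
    return SignalProtocol(H_min=0.1, H_max=3.0, T_s=1.5, Delta_T=1.5, n_stimuli=3)


class SignalOverflowError(OverflowError):
    """A sampled signal drove exp(beta h) beyond float range."""


@dataclass
class EnsembleTrajectories:
    n_traj: int
    seed: int
    sample_times: np.ndarray
    states: np.ndarray    # (n_traj, n_samples, 4): r, u, s, h
    counters: np.ndarray  # (n_traj, n_samples, 3): storage births, deaths, internal cycles
    params: ModelParams
    protocol: SignalProtocol

    def observable(self, name: str) -> np.ndarray:
        idx = {"r": 0, "u": 1, "s": 2, "h": 3}[name]
        return self.states[:, :, idx]


@njit(cache=True)
def _ssa_kernel(seeds, r0, u0, s0, h0, sample_times, epoch_ends, epoch_means,
                beta, DeltaE, GH, GI, kap_fac, birthP, birthA, inv_tauU,
                sb_fac, inv_tauS, hr, N_S, t_start, states, counters):
    n_traj = seeds.shape[0]
    n_samp = sample_times.shape[0]
    for i in range(n_traj):
        np.random.seed(seeds[i])
        r = r0[i]
        u = u0[i]
        s = s0[i]
        h = h0[i]
        t = t_start
        isamp = 0
        iep = 0
        nb = 0
        nd = 0
        nc = 0
        while iep < epoch_ends.shape[0] - 1 and epoch_ends[iep] <= t:
            iep += 1
        recompute = True
        rr1 = 0.0
        rr2 = 0.0
        ub = 0.0
        while isamp < n_samp:
            if recompute:
                if beta * h > 700.0:
                    return i, h  # overflow; caller raises
                if r == 0:
                    rr1 = math.exp(beta * (h - DeltaE)) * GH
                    rr2 = math.exp(-beta * DeltaE) * GI
                    ub = birthP
                else:
                    rr1 = GH
                    rr2 = math.exp(kap_fac * s) * GI
                    ub = birthA
                recompute = False
            ud = u * inv_tauU
            sb = sb_fac * u if s < N_S else 0.0
            sd = s * inv_tauS
            total = rr1 + rr2 + ub + ud + sb + sd + hr
            dt_ev = -math.log(np.random.random()) / total
            # next scheduled break: sample or epoch boundary
            t_samp = sample_times[isamp]
            t_ep = epoch_ends[iep]
            t_break = t_samp if t_samp <= t_ep else t_ep
            if t + dt_ev >= t_break:
                t = t_break
                if t_samp <= t_ep:
                    states[i, isamp, 0] = r
                    states[i, isamp, 1] = u
                    states[i, isamp, 2] = s
                    states[i, isamp, 3] = h
                    counters[i, isamp, 0] = nb
                    counters[i, isamp, 1] = nd
                    counters[i, isamp, 2] = nc
                    isamp += 1
                else:
                    iep += 1
                    h = -epoch_means[iep] * math.log(np.random.random())
                    recompute = True
                continue
            t += dt_ev
            x = np.random.random() * total
            if x < rr1:
                r = 1 - r
                recompute = True
            elif x < rr1 + rr2:
                if r == 1:
                    nc += 1  # internal-pathway deactivation completes a cycle
                r = 1 - r
                recompute = True
            elif x < rr1 + rr2 + ub:
                u += 1
            elif x < rr1 + rr2 + ub + ud:
                u -= 1
            elif x < rr1 + rr2 + ub + ud + sb:
                s += 1
                nb += 1
                if r == 1:
                    recompute = True
            elif x < rr1 + rr2 + ub + ud + sb + sd:
                s -= 1
                nd += 1
                if r == 1:
                    recompute = True
            else:
                h = -epoch_means[iep] * math.log(np.random.random())
                recompute = True
    return -1, 0.0


def simulate(
    params: ModelParams,
    protocol: SignalProtocol,
    n_traj: int,
    seed: int,
    sample_times: Sequence[float],
    t_end: Optional[float] = None,
    burn_in: Optional[float] = None,
    solver: Optional[TSSSolver] = None,
) -> EnsembleTrajectories:
    """Exact SSA ensemble under a square-wave protocol.

    Trajectories start from the background stationary law (storage marginal
    from the timescale-separation fixed point, fast variables sampled from
    their conditionals) and are burned in under the background signal for
    ``burn_in`` time units (default 2 tau_S) before t = 0.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if not params.is_derived:
        params = derive_energies(params)
    sample_times = np.asarray(sorted(sample_times), dtype=float)
    t_end = float(sample_times[-1]) if t_end is None else float(t_end)
    burn_in = 2.0 * params.tau_S if burn_in is None else float(burn_in)

    solver = solver or TSSSolver(params)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 2744]))
    q0 = solver.stationary_q(protocol.H_min)
    s0 = rng.choice(solver.grid_s, size=n_traj, p=q0).astype(np.int64)
    h0 = rng.exponential(protocol.H_min, size=n_traj)
    pa = solver.receptor_stationary_given_sh(s0.astype(float), h0)
    r0 = (rng.random(n_traj) < pa).astype(np.int64)
    means = np.where(r0 == 1, params.U_mean_active, params.U_mean_passive)
    u0 = rng.poisson(means).astype(np.int64)
    seeds = rng.integers(0, 2**31 - 1, size=n_traj).astype(np.int64)

    # epoch table covering [-burn_in, t_end] (+ sentinel end)
    eps = [(-burn_in if burn_in > 0 else 0.0, protocol.H_min)]
    bounds, emeans = [], []
    t = 0.0
    for dur, mean in protocol.epochs(t_end=max(t_end, protocol.t_end)):
        bounds.append(t + dur)
        emeans.append(mean)
        t += dur
    epoch_ends = np.array([0.0] + bounds + [max(t_end, t) + 1.0])
    epoch_means = np.array([protocol.H_min] + emeans + [emeans[-1] if emeans else protocol.H_min])
    if burn_in <= 0:
        epoch_ends = epoch_ends[1:]
        epoch_means = epoch_means[1:]

    p = params
    states = np.zeros((n_traj, len(sample_times), 4))
    counters = np.zeros((n_traj, len(sample_times), 3))
    bad, hbad = _ssa_kernel(
        seeds, r0, u0, s0, h0, sample_times, epoch_ends, epoch_means,
        p.beta, p.DeltaE, 1.0 / p.tau_R, 1.0 / (p.g * p.tau_R),
        p.beta * p.kappa * p.sigma / p.N_S,
        p.U_mean_passive / p.tau_U, p.U_mean_active / p.tau_U, 1.0 / p.tau_U,
        math.exp(-p.beta * p.sigma) * p.Gamma_S0, p.Gamma_S0, 1.0 / p.tau_H_eff,
        p.N_S, -burn_in, states, counters,
    )
    if bad >= 0:
        raise SignalOverflowError(
            f"exp(beta*h) overflow at h={hbad:g} in trajectory {bad}"
        )
    return EnsembleTrajectories(
        n_traj=n_traj, seed=seed, sample_times=sample_times,
        states=states, counters=counters, params=params, protocol=protocol,
    )


def ensemble_moments(ens: EnsembleTrajectories):
    """Per-sample-time mean, variance and standard error of r, u, s, h."""
    import pandas as pd

    if ens.n_traj < 2:
        raise ValueError("need at least 2 trajectories for moments")
    rows = {}
    for name in ("r", "u", "s", "h"):
        x = ens.observable(name)
        rows[f"{name}_mean"] = x.mean(axis=0)
        rows[f"{name}_var"] = x.var(axis=0, ddof=1)
        rows[f"{name}_se"] = x.std(axis=0, ddof=1) / math.sqrt(ens.n_traj)
    df = pd.DataFrame(rows)
    df.insert(0, "time", ens.sample_times)
    return df


def joint_histogram(ens: EnsembleTrajectories, time_index: int,
                    U_max: Optional[int] = None) -> np.ndarray:
    """Empirical p_{U,S} at one sample time; normalized (U_max+1, N_S+1) table."""
    u = ens.states[:, time_index, 1].astype(int)
    s = ens.states[:, time_index, 2].astype(int)
    U_max = int(u.max()) if U_max is None else U_max
    H = np.zeros((U_max + 1, ens.params.N_S + 1))
    np.add.at(H, (np.clip(u, 0, U_max), s), 1.0)
    return H / H.sum()


def flux_estimate(ens: EnsembleTrajectories) -> np.ndarray:
    """Event-count estimate of J_int on each inter-sample interval:
    sigma * (storage births - deaths) / (n_traj * dt)."""
    db = np.diff(ens.counters[:, :, 0], axis=1).sum(axis=0)
    dd = np.diff(ens.counters[:, :, 1], axis=1).sum(axis=0)
    dt = np.diff(ens.sample_times)
    return ens.params.sigma * (db - dd) / (ens.n_traj * dt)
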