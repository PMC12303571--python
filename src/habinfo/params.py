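"""Model parameters and transition rates of the receptor-readout-storage network.

The model couples four degrees of freedom:

* a two-state receptor ``r`` (passive/active) sensing an exponentially
  distributed signal ``h`` through a stimulated pathway and inhibited through
  an internal pathway fed by the storage,
* a readout birth-death population ``u`` pumped up while the receptor is
  active (the observable of habituation),
* a slow, capacity-limited storage population ``s`` produced catalytically by
  the readout, providing the negative feedback,
* the environment ``H``, a square-wave schedule of the signal mean.

All rates follow effective Arrhenius laws; the free energy scales are the
inverse temperature ``beta`` and the storage cost ``sigma``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ModelParams",
    "SignalProtocol",
    "InvalidParameterError",
    "derive_energies",
    "receptor_rates",
    "readout_rates",
    "storage_rates",
]


class InvalidParameterError(ValueError):
    """Raised when a parameter set violates the model's domain constraints."""


@dataclass(frozen=True)
class ModelParams:
    """All rate and energy constants of the model.

    The readout energies ``V`` and ``c`` are not free: they are derived from
    the target readout means ``U_mean_passive`` (= exp(-beta*V)) and
    ``U_mean_active`` (= exp(-beta*(V-c))).  Likewise the inhibition strength
    ``kappa`` is fixed by the balance condition kappa = H_ref/(alpha*sigma)
    unless overridden explicitly (e.g. kappa=0 switches the feedback off).
    """

    beta: float = 3.0
    sigma: float = 0.6
    DeltaE: float = 1.0
    N_S: int = 30
    U_mean_passive: float = 30.0
    U_mean_active: float = 150.0
    Gamma_S0: float = 0.002
    g: float = 1.0
    alpha: float = 2.0 / 3.0
    H_ref: float = 10.0
    tau_U: float = 0.01
    tau_R: float = 1.0
    tau_H: Optional[float] = None
    kappa_override: Optional[float] = None
    max_tau_ratio: float = 10.0  # allowed spread between tau_S and tau_H
    # derived (filled by derive_energies)
    V: float = field(default=float("nan"))
    c: float = field(default=float("nan"))
    kappa: float = field(default=float("nan"))

    @property
    def tau_S(self) -> float:
        """Storage timescale, the inverse of ``Gamma_S0``."""
        return 1.0 / self.Gamma_S0

    @property
    def Gamma_U0(self) -> float:
        return 1.0 / self.tau_U

    def _validate(self) -> None:
        if not (self.beta > 0):
            raise InvalidParameterError("beta must be > 0")
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")
        if self.N_S < 1:
            raise InvalidParameterError("N_S must be >= 1")
        if not (self.Gamma_S0 > 0):
            raise InvalidParameterError("Gamma_S0 must be > 0")
        if not (self.g > 0):
            raise InvalidParameterError("g must be > 0")
        if not (0 < self.alpha <= 1):
            raise InvalidParameterError("alpha must be in (0, 1]")
        if not (self.H_ref > 0):
            raise InvalidParameterError("H_ref must be > 0")
        if not (self.U_mean_passive > 0 and self.U_mean_active > 0):
            raise InvalidParameterError("readout target means must be > 0")
        if not (self.U_mean_active > self.U_mean_passive):
            raise InvalidParameterError(
                "U_mean_active must exceed U_mean_passive (active pumping)"
            )
        if not (self.tau_U < self.tau_R < self.tau_S):
            raise InvalidParameterError(
                "timescale ordering tau_U < tau_R < tau_S violated"
            )
        tau_H = self.tau_H if self.tau_H is not None else self.tau_S
        ratio = self.tau_S / tau_H
        if not (1.0 / self.max_tau_ratio <= ratio <= self.max_tau_ratio):
            raise InvalidParameterError("tau_S and tau_H must be comparable")
        if self.sigma == 0 and self.kappa_override is None:
            raise InvalidParameterError(
                "sigma=0 makes kappa singular; supply kappa_override"
            )

    @property
    def tau_H_eff(self) -> float:
        return self.tau_H if self.tau_H is not None else self.tau_S

    @property
    def is_derived(self) -> bool:
        return not (math.isnan(self.V) or math.isnan(self.c) or math.isnan(self.kappa))


def derive_energies(params: ModelParams) -> ModelParams:
    """Fill in the derived energies ``V``, ``c`` and the inhibition ``kappa``.

    Inverts the stationary readout means of the birth-death process,
    ``<U>_P = exp(-beta V)`` and ``<U>_A = exp(-beta (V - c))``, and applies
    the feedback balance condition ``kappa = H_ref / (alpha sigma)`` (skipped
    when an explicit override is given).  Idempotent.
    """
    params._validate()
    beta = params.beta
    V = -math.log(params.U_mean_passive) / beta
    c = math.log(params.U_mean_active / params.U_mean_passive) / beta
    if params.kappa_override is not None:
        kappa = float(params.kappa_override)
    else:
        kappa = params.H_ref / (params.alpha * params.sigma)
    out = replace(params, V=V, c=c, kappa=kappa)
    # round-trip identities must hold to machine precision
    assert math.isclose(math.exp(-beta * V), params.U_mean_passive, rel_tol=1e-12)
    assert math.isclose(math.exp(-beta * (V - c)), params.U_mean_active, rel_tol=1e-12)
    return out


def _require_derived(params: ModelParams) -> None:
    if not params.is_derived:
        raise InvalidParameterError(
            "derived energies missing: call derive_energies(params) first"
        )


def receptor_rates(params: ModelParams, s: float, h: float):
    """Four receptor switching rates at storage count ``s`` and signal ``h``.

    Returns ``(sens_PA, sens_AP, int_PA, int_AP)``: activation/deactivation
    along the sensing pathway (driven by the signal energy ``beta h``) and
    along the internal pathway (inhibited by the stored energy
    ``kappa sigma s / N_S``).
    """
    _require_derived(params)
    if not (0 <= s <= params.N_S):
        raise InvalidParameterError(f"s={s} outside [0, {params.N_S}]")
    if h < 0:
        raise InvalidParameterError(f"h={h} must be >= 0")
    b = params.beta
    GH = 1.0 / params.tau_R
    GI = GH / params.g
    sens_PA = math.exp(b * (h - params.DeltaE)) * GH
    sens_AP = GH
    int_PA = math.exp(-b * params.DeltaE) * GI
    int_AP = math.exp(b * params.kappa * params.sigma * s / params.N_S) * GI
    return sens_PA, sens_AP, int_PA, int_AP


def readout_rates(params: ModelParams, r: int, u: int):
    """Birth and death rates of the readout population given receptor state."""
    _require_derived(params)
    if r not in (0, 1):
        raise InvalidParameterError(f"r={r} must be 0 or 1")
    if u < 0:
        raise InvalidParameterError(f"u={u} must be >= 0")
    birth = math.exp(-params.beta * (params.V - params.c * r)) * params.Gamma_U0
    death = u * params.Gamma_U0
    return birth, death


def storage_rates(params: ModelParams, u: int, s: int):
    """Birth and death rates of the storage population (hard cap at N_S)."""
    if u < 0:
        raise InvalidParameterError(f"u={u} must be >= 0")
    if not (0 <= s <= params.N_S):
        raise InvalidParameterError(f"s={s} outside [0, {params.N_S}]")
    birth = 0.0 if s >= params.N_S else u * math.exp(-params.beta * params.sigma) * params.Gamma_S0
    death = s * params.Gamma_S0
    return birth, death


@dataclass(frozen=True)
class SignalProtocol:
    """Square-wave schedule of the signal mean <H>(t).

    ``n_stimuli`` windows of length ``T_s`` at mean ``H_max`` separated by
    pauses ``Delta_T`` at mean ``H_min``; first onset at ``t_start``.  At any
    time the signal law is exponential with density lambda*exp(-lambda h),
    lambda(t) = 1/<H>(t).
    """

    H_min: float = 0.1
    H_max: float = 10.0
    T_s: float = 100.0
    Delta_T: float = 100.0
    n_stimuli: int = 10
    t_start: float = 0.0
    adaptive_kappa: bool = False

    def __post_init__(self):
        if not (self.H_min > 0):
            raise InvalidParameterError("H_min must be > 0")
        if self.H_max < self.H_min:
            raise InvalidParameterError("H_max must be >= H_min")
        if not (self.T_s > 0):
            raise InvalidParameterError("T_s must be > 0")
        if self.Delta_T < 0:
            raise InvalidParameterError("Delta_T must be >= 0")
        if self.n_stimuli < 1:
            raise InvalidParameterError("n_stimuli must be >= 1")

    def onset(self, k: int) -> float:
        """Onset time of stimulus ``k`` (1-based)."""
        return self.t_start + (k - 1) * (self.T_s + self.Delta_T)

    @property
    def t_end(self) -> float:
        return self.onset(self.n_stimuli) + self.T_s + self.Delta_T

    def mean_signal(self, t: float) -> float:
        """<H>(t): H_max inside stimulus windows, H_min elsewhere."""
        if t >= self.t_start:
            period = self.T_s + self.Delta_T
            k = int(np.floor((t - self.t_start) / period))
            if k < self.n_stimuli and (t - self.t_start) - k * period < self.T_s:
                return self.H_max
        return self.H_min

    def epochs(self, t_end: Optional[float] = None):
        """Piecewise-constant epochs ``[(duration, mean), ...]`` covering [0, t_end]."""
        t_end = self.t_end if t_end is None else t_end
        out = []
        t = 0.0
        if self.t_start > 0:
            out.append((min(self.t_start, t_end), self.H_min))
            t = self.t_start
        k = 0
        while t < t_end - 1e-12:
            if k < self.n_stimuli:
                dur = min(self.T_s, t_end - t)
                out.append((dur, self.H_max))
                t += dur
                if t >= t_end - 1e-12:
                    break
                if self.Delta_T > 0:
                    dur = min(self.Delta_T, t_end - t)
                    out.append((dur, self.H_min))
                    t += dur
                k += 1
            else:
                out.append((t_end - t, self.H_min))
                t = t_end
        return out
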