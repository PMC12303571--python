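"""Timescale-separation solution of the habituation master equation.

With tau_U << tau_R << tau_S ~ tau_H, the readout and receptor are
conditionally stationary: p(u | r) is Poisson with mean exp(-beta(V - c r))
and p(r=1 | s, h) follows from the 2-state receptor balance.  The joint law
of the slow pair (U, S) then obeys a Chapman-Kolmogorov recursion

    p(u, s, t+dt) = K(u, s; lambda(t+dt)) * sum_{s', u'} P(s'->s | u') p(u', s', t)

where P is the storage propagator at frozen readout u' and

    K(u, s; lambda) = Abar(s) Poi(u; mu_A) + (1 - Abar(s)) Poi(u; mu_P),

with Abar(s) the receptor activation probability averaged over the
exponential signal law (Gauss-Laguerre quadrature).  Because every updated
joint has this product form K * q, the solver propagates only the storage
marginal q(s) through a stochastic matrix M = mix(Abar) . Pbar, which makes
long protocols cheap; the full-table single step is kept for cross-checks.

The storage propagator is built by eigendecomposition of the generator
truncated to the n nearest neighbours of the initial state (default n=2),
with the diagonal set to minus the column sums so probability is conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit, gammaln

from .params import InvalidParameterError, ModelParams, SignalProtocol, derive_energies

__all__ = [
    "JointDistribution",
    "ConditionalLaws",
    "TrajectoryRecord",
    "TSSSolver",
    "GridTooSmallError",
    "StepTooLargeError",
    "ConvergenceError",
]


class GridTooSmallError(RuntimeError):
    """Truncated probability mass on the readout grid exceeds tolerance."""


class StepTooLargeError(RuntimeError):
    """A propagator step violates the jump-probability rule; subdivide dt."""


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach the requested residual."""


@dataclass
class JointDistribution:
    """Probability table p(u, s) on the truncated grid, at a given time."""

    grid_u: np.ndarray
    grid_s: np.ndarray
    values: np.ndarray  # shape (len(grid_u), len(grid_s))
    time: Optional[float] = None

    def normalize_check(self, tol: float = 1e-10) -> None:
        total = float(self.values.sum())
        if abs(total - 1.0) > tol or (self.values < -tol).any():
            raise ValueError(f"joint distribution not normalized (sum={total})")

    @property
    def p_S(self) -> np.ndarray:
        return self.values.sum(axis=0)

    @property
    def p_U(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def mean_U(self) -> float:
        return float(self.grid_u @ self.p_U)

    def mean_S(self) -> float:
        return float(self.grid_s @ self.p_S)


@dataclass
class ConditionalLaws:
    """The fast-variable conditional stationary laws used by the recursion."""

    p_U_given_R: np.ndarray  # (2, U+1): rows r=0, r=1
    p_A_given_SH: np.ndarray  # (S+1, n_quad): P(r=1 | s, h_j)
    h_nodes: np.ndarray
    h_weights: np.ndarray


@dataclass
class TrajectoryRecord:
    """Time series produced by :meth:`TSSSolver.evolve`."""

    times: np.ndarray
    U_mean: np.ndarray
    S_mean: np.ndarray
    # one entry per stimulus: (index, sample time, <U> at sample, q(s), mean signal)
    stim_samples: List[dict] = field(default_factory=list)
    snapshots: List[dict] = field(default_factory=list)  # epoch-boundary states
    protocol: Optional[SignalProtocol] = None
    final_q: Optional[np.ndarray] = None


def _poisson_pmf(mean: float, grid: np.ndarray) -> np.ndarray:
    logp = grid * math.log(mean) - mean - gammaln(grid + 1.0)
    return np.exp(logp)


class TSSSolver:
    """Iterative timescale-separation solver for one parameter set.

    Parameters
    ----------
    params : ModelParams
        Model constants; derived energies are filled in if missing.
    n_quad : int
        Number of signal-quadrature nodes (midpoint rule in the exponential
        CDF domain; 512 by default).  The receptor response is nearly a step
        in h at large beta, so the nodes are placed uniformly in cumulative
        probability, which resolves the switch wherever it falls; because
        every information functional is then an exact mutual information of
        the node-sampled discrete joint, information inequalities hold to
        machine precision at any order.
    propagator_n : int
        Nearest-neighbour truncation of the storage propagator (None for the
        dense eigendecomposition of the full generator).
    jump_factor : float
        Step rule: max single-jump rate times dt must stay below this.
    u_grid_sigmas : float
        Readout grid extends to max mean + this many sqrt(mean).
    """

    def __init__(
        self,
        params: ModelParams,
        n_quad: int = 512,
        propagator_n: Optional[int] = 2,
        jump_factor: float = 0.2,
        u_grid_sigmas: float = 8.0,
        truncation_tol: float = 1e-8,
    ):
        if not params.is_derived:
            params = derive_energies(params)
        else:
            params._validate()
        self.params = params
        self.n_quad = int(n_quad)
        self.propagator_n = propagator_n
        self.jump_factor = float(jump_factor)
        p = params
        max_mean = max(p.U_mean_passive, p.U_mean_active)
        self.U_max = int(math.ceil(max_mean + u_grid_sigmas * math.sqrt(max_mean)))
        self.grid_u = np.arange(self.U_max + 1)
        self.grid_s = np.arange(p.N_S + 1)
        # conditional stationary readout laws (truncated, renormalized Poisson)
        self.pU = np.empty((2, self.U_max + 1))
        self.muU = np.empty(2)
        for r, mean in enumerate((p.U_mean_passive, p.U_mean_active)):
            pmf = _poisson_pmf(mean, self.grid_u)
            lost = 1.0 - pmf.sum()
            if lost > truncation_tol:
                raise GridTooSmallError(
                    f"truncated readout mass {lost:.2e} exceeds {truncation_tol:.0e}"
                )
            pmf = pmf / pmf.sum()
            self.pU[r] = pmf
            self.muU[r] = float(self.grid_u @ pmf)
        # midpoint rule in the CDF domain of the unit-mean exponential law:
        # y_i = (i + 1/2)/n uniform in cumulative probability, x_i = -ln(1-y_i)
        y = (np.arange(self.n_quad) + 0.5) / self.n_quad
        self._quad_x = -np.log1p(-y)
        self._quad_w = np.full(self.n_quad, 1.0 / self.n_quad)
        self._prop_cache: Dict[float, np.ndarray] = {}
        self._pbar_cache: Dict[float, Tuple[np.ndarray, np.ndarray]] = {}
        self._abar_cache: Dict[float, np.ndarray] = {}

    # ------------------------------------------------------------------
    # fast-variable conditional laws
    # ------------------------------------------------------------------

    def readout_stationary_given_r(self, r: int) -> np.ndarray:
        """Truncated-renormalized Poisson law of U given receptor state."""
        if r not in (0, 1):
            raise InvalidParameterError("r must be 0 or 1")
        return self.pU[r].copy()

    def receptor_stationary_given_sh(self, s, h):
        """P(receptor active | s, h) = k_on / (k_on + k_off), in log space.

        Vectorized over broadcastable ``s`` and ``h`` arrays.
        """
        p = self.params
        s = np.asarray(s, dtype=float)
        h = np.asarray(h, dtype=float)
        if (s < 0).any() or (s > p.N_S).any():
            raise InvalidParameterError("s outside [0, N_S]")
        if (h < 0).any():
            raise InvalidParameterError("h must be >= 0")
        log_g = math.log(p.g)
        # rates carry a common 1/tau_R which cancels in the ratio
        log_kon = np.logaddexp(p.beta * (h - p.DeltaE), -p.beta * p.DeltaE - log_g)
        log_koff = np.logaddexp(0.0, p.beta * p.kappa * p.sigma * s / p.N_S - log_g)
        return expit(log_kon - log_koff)

    def h_nodes(self, mean_signal: float) -> Tuple[np.ndarray, np.ndarray]:
        """Quadrature nodes/weights for the exponential law of mean <H>."""
        return self._quad_x * mean_signal, self._quad_w

    def abar(self, mean_signal: float) -> np.ndarray:
        """Signal-averaged activation probability Abar(s) = E_h[p_A(s, h)]."""
        key = float(mean_signal)
        if key not in self._abar_cache:
            h, w = self.h_nodes(mean_signal)
            pa = self.receptor_stationary_given_sh(
                self.grid_s[:, None], h[None, :]
            )
            self._abar_cache[key] = pa @ w
        return self._abar_cache[key]

    def conditional_laws(self, mean_signal: float) -> ConditionalLaws:
        h, w = self.h_nodes(mean_signal)
        pa = self.receptor_stationary_given_sh(self.grid_s[:, None], h[None, :])
        return ConditionalLaws(self.pU.copy(), pa, h, w)

    def channel(self, mean_signal: float) -> np.ndarray:
        """K(u, s) = Abar(s) Poi_A(u) + (1-Abar(s)) Poi_P(u), shape (U+1, S+1)."""
        a = self.abar(mean_signal)
        return self.pU[1][:, None] * a[None, :] + self.pU[0][:, None] * (1.0 - a[None, :])

    def u_cond_mean(self, mean_signal: float) -> np.ndarray:
        """ubar(s): conditional readout mean given the storage count."""
        a = self.abar(mean_signal)
        return self.muU[0] + (self.muU[1] - self.muU[0]) * a

    # ------------------------------------------------------------------
    # storage propagator
    # ------------------------------------------------------------------

    @property
    def _max_jump_rate(self) -> float:
        p = self.params
        return p.Gamma_S0 * max(p.N_S, math.exp(-p.beta * p.sigma) * self.U_max)

    @property
    def dt_max(self) -> float:
        """Largest step allowed by the jump rule over the whole grid."""
        return self.jump_factor / self._max_jump_rate

    def _check_step(self, dt: float) -> None:
        if dt < 0:
            raise StepTooLargeError("dt must be >= 0")
        if dt * self._max_jump_rate > self.jump_factor * (1 + 1e-9):
            raise StepTooLargeError(
                f"dt={dt:g} violates jump rule (dt_max={self.dt_max:g}); subdivide"
            )

    def _window(self, s0: int) -> np.ndarray:
        n = self.propagator_n
        if n is None:
            return self.grid_s
        return np.arange(max(0, s0 - n), min(self.params.N_S, s0 + n) + 1)

    def _propagator_columns(self, dt: float, s0: int, u_vals: np.ndarray) -> np.ndarray:
        """P(s0 -> s | u') for all u' in ``u_vals``; shape (len(u_vals), S+1)."""
        p = self.params
        win = self._window(s0)
        k = len(win)
        idx0 = int(np.where(win == s0)[0][0])
        G = p.Gamma_S0
        ebs = math.exp(-p.beta * p.sigma)
        nu = len(u_vals)
        A = np.zeros((nu, k, k))
        for i, s in enumerate(win):
            if i + 1 < k:  # birth s -> s+1 (forbidden at the capacity cap)
                if s < p.N_S:
                    A[:, i + 1, i] = u_vals * ebs * G
            if i - 1 >= 0:  # death s -> s-1
                A[:, i - 1, i] = s * G
        # conservation: diagonal = -(column sums)
        A[:, np.arange(k), np.arange(k)] = -A.sum(axis=1)
        lam, V = np.linalg.eig(A)
        e0 = np.zeros(k)
        e0[idx0] = 1.0
        coef = np.linalg.solve(V, np.broadcast_to(e0, (nu, k))[..., None].copy())[..., 0]
        cols_win = np.einsum("nij,nj->ni", V, coef * np.exp(lam * dt)).real
        cols_win = np.clip(cols_win, 0.0, None)
        cols_win /= cols_win.sum(axis=1, keepdims=True)
        cols = np.zeros((nu, p.N_S + 1))
        cols[:, win] = cols_win
        return cols

    def storage_propagator(self, u0: int, s0: int, dt: float) -> np.ndarray:
        """Distribution over s after dt, starting from s0 at frozen readout u0."""
        p = self.params
        if not (0 <= s0 <= p.N_S):
            raise InvalidParameterError("s0 outside [0, N_S]")
        if u0 < 0:
            raise InvalidParameterError("u0 must be >= 0")
        if dt == 0:
            out = np.zeros(p.N_S + 1)
            out[s0] = 1.0
            return out
        rate = p.Gamma_S0 * max(p.N_S, math.exp(-p.beta * p.sigma) * u0)
        if dt * rate > self.jump_factor * (1 + 1e-9):
            raise StepTooLargeError(
                f"dt={dt:g} too large for u0={u0} (jump rule); subdivide"
            )
        return self._propagator_columns(dt, s0, np.array([float(u0)]))[0]

    def propagator_tensor(self, dt: float) -> np.ndarray:
        """P(s' -> s | u') for the full grids; shape (U+1, S+1 source, S+1 dest)."""
        self._check_step(dt)
        key = round(float(dt), 15)
        if key not in self._prop_cache:
            p = self.params
            T = np.empty((self.U_max + 1, p.N_S + 1, p.N_S + 1))
            uv = self.grid_u.astype(float)
            for s0 in self.grid_s:
                T[:, s0, :] = self._propagator_columns(dt, int(s0), uv)
            self._prop_cache[key] = T
        return self._prop_cache[key]

    def _pbar(self, dt: float) -> Tuple[np.ndarray, np.ndarray]:
        """Propagators averaged over the conditional readout laws (r=0, 1)."""
        key = round(float(dt), 15)
        if key not in self._pbar_cache:
            T = self.propagator_tensor(dt)
            pbar0 = np.einsum("u,usk->sk", self.pU[0], T)
            pbar1 = np.einsum("u,usk->sk", self.pU[1], T)
            self._pbar_cache[key] = (pbar0, pbar1)
        return self._pbar_cache[key]

    def step_matrix(self, mean_signal: float, dt: float) -> np.ndarray:
        """One-step storage-marginal map M(s', s) for a product-form state."""
        pbar0, pbar1 = self._pbar(dt)
        a = self.abar(mean_signal)
        return a[:, None] * pbar1 + (1.0 - a)[:, None] * pbar0

    # ------------------------------------------------------------------
    # Chapman-Kolmogorov iteration
    # ------------------------------------------------------------------

    def step_joint(
        self, p: JointDistribution, mean_signal_next: float, dt: float
    ) -> JointDistribution:
        """One full-table Chapman-Kolmogorov step of the (U, S) joint law."""
        self._check_step(dt)
        p.normalize_check(1e-8)
        T = self.propagator_tensor(dt)
        q = np.einsum("usk,us->k", T, p.values)
        K = self.channel(mean_signal_next)
        values = K * q[None, :]
        defect = abs(values.sum() - 1.0)
        if defect > 1e-8:
            raise ConvergenceError(f"normalization defect {defect:.2e} after step")
        values /= values.sum()
        t = None if p.time is None else p.time + dt
        return JointDistribution(self.grid_u, self.grid_s, values, t)

    def joint_from_q(
        self, q: np.ndarray, mean_signal: float, time: Optional[float] = None
    ) -> JointDistribution:
        return JointDistribution(
            self.grid_u, self.grid_s, self.channel(mean_signal) * q[None, :], time
        )

    def stationary_q(self, H_st: float, dt: Optional[float] = None) -> np.ndarray:
        """Stationary storage marginal under a constant mean signal."""
        if not (H_st > 0):
            raise InvalidParameterError("H_st must be > 0")
        dt = self.dt_max if dt is None else dt
        M = self.step_matrix(H_st, dt)
        lam, V = np.linalg.eig(M.T)
        i = int(np.argmin(np.abs(lam - 1.0)))
        q = np.real(V[:, i])
        q = np.clip(q * np.sign(q.sum()), 0.0, None)
        q /= q.sum()
        for _ in range(5):  # polish
            q = q @ M
            q /= q.sum()
        resid = 0.5 * np.abs(q @ M - q).sum()
        if resid > 1e-9:
            raise ConvergenceError(f"stationary residual {resid:.2e} > 1e-9")
        return q

    def stationary_solve(self, H_st: float, dt: Optional[float] = None) -> JointDistribution:
        """Fixed point of the step under constant signal, as a joint table."""
        q = self.stationary_q(H_st, dt)
        return self.joint_from_q(q, H_st)

    # ------------------------------------------------------------------
    # protocol evolution
    # ------------------------------------------------------------------

    def run_schedule(
        self,
        q0: np.ndarray,
        schedule: Sequence[Tuple[float, float, Optional[int]]],
        t0: float = 0.0,
        record: bool = True,
        dt: Optional[float] = None,
    ):
        """Propagate the storage marginal through labeled epochs.

        ``schedule`` is a list of ``(duration, mean_signal, label)``; epochs
        whose label is not None contribute a per-stimulus sample (taken at the
        epoch end).  With ``record=False`` whole epochs are advanced with a
        matrix power and only boundary states are kept.
        """
        dt_cap = self.dt_max if dt is None else dt
        q = np.array(q0, dtype=float)
        t = t0
        times: List[float] = []
        Us: List[float] = []
        Ss: List[float] = []
        stim_samples: List[dict] = []
        snapshots: List[dict] = []

        def obs(abar_vec):
            U = float(q @ (self.muU[0] + (self.muU[1] - self.muU[0]) * abar_vec))
            S = float(q @ self.grid_s)
            return U, S

        for dur, mean, label in schedule:
            if dur <= 0:
                continue
            n = max(1, int(math.ceil(dur / dt_cap - 1e-12)))
            dte = dur / n
            M = self.step_matrix(mean, dte)
            a = self.abar(mean)
            if record:
                U, S = obs(a)
                times.append(t), Us.append(U), Ss.append(S)
                for _ in range(n):
                    q = q @ M
                    t += dte
                    U, S = obs(a)
                    times.append(t), Us.append(U), Ss.append(S)
            else:
                q = q @ np.linalg.matrix_power(M, n)
                t += dur
            U, S = obs(a)
            snapshots.append({"t": t, "q": q.copy(), "mean_signal": mean, "label": label})
            if label is not None:
                stim_samples.append(
                    {"stimulus": label, "t": t, "U": U, "S": S, "q": q.copy(),
                     "mean_signal": mean}
                )
        rec = TrajectoryRecord(
            times=np.array(times),
            U_mean=np.array(Us),
            S_mean=np.array(Ss),
            stim_samples=stim_samples,
            snapshots=snapshots,
        )
        rec.final_q = q
        return rec

    @staticmethod
    def labeled_epochs(protocol: SignalProtocol, sample_phase: float = 1.0):
        """Epoch list for a protocol, splitting stimuli at the sampling phase."""
        if not (0 < sample_phase <= 1):
            raise InvalidParameterError("sample_phase must be in (0, 1]")
        out: List[Tuple[float, float, Optional[int]]] = []
        if protocol.t_start > 0:
            out.append((protocol.t_start, protocol.H_min, None))
        for k in range(1, protocol.n_stimuli + 1):
            if sample_phase < 1.0:
                out.append((protocol.T_s * sample_phase, protocol.H_max, k))
                out.append((protocol.T_s * (1 - sample_phase), protocol.H_max, None))
            else:
                out.append((protocol.T_s, protocol.H_max, k))
            if protocol.Delta_T > 0:
                out.append((protocol.Delta_T, protocol.H_min, None))
        return out

    def initial_state(self, protocol: SignalProtocol) -> np.ndarray:
        """Pre-stimulation state: stationary under the background signal."""
        return self.stationary_q(protocol.H_min)

    def evolve(
        self,
        protocol: SignalProtocol,
        t_end: Optional[float] = None,
        dt: Optional[float] = None,
        sample_phase: float = 1.0,
        q0: Optional[np.ndarray] = None,
        record: bool = True,
    ) -> TrajectoryRecord:
        """Run a square-wave protocol from the background stationary state."""
        sched = self.labeled_epochs(protocol, sample_phase)
        if t_end is not None:
            total = sum(d for d, _, _ in sched)
            if t_end > total:
                sched.append((t_end - total, protocol.H_min, None))
        q0 = self.initial_state(protocol) if q0 is None else q0
        rec = self.run_schedule(q0, sched, record=record, dt=dt)
        rec.protocol = protocol
        return rec
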