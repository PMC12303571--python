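"""Mapping the readout dynamics onto binary-neuron population activity.

Each readout unit stands for a subpopulation of ``N`` neurons dedicated to
one sensing channel.  When a unit responds to a stimulus, each of its
neurons fires independently with probability ``p`` in every time bin of that
stimulus window; units that fail to respond (because their storage has
accumulated and suppressed the readout) contribute silent neurons.  PCA over
the resulting neurons-by-time binary matrix then separates the stimulus
on/off structure (first component) from the habituation trend (second
component), mirroring what the same embedding shows on calcium-imaging
recordings of repeated looming stimulation.

Per-unit stochasticity comes from sampling each unit's storage trajectory
from the solver's one-step transition chain — an exact realization of the
timescale-separation process — and drawing the unit's signal, receptor state
and readout count from the conditional laws at the stimulus sampling phase.
A synthetic fluorescence-like fixture generator with stimulus-locked,
exponentially habituating transients stands in for real recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .params import ModelParams, SignalProtocol, derive_energies
from .tss import TSSSolver

__all__ = [
    "NeuralActivityMatrix",
    "looming_protocol",
    "unit_activations_from_model",
    "sample_neural_activity",
    "pca_embedding",
    "stimulus_scores",
    "generate_fixture",
    "write_activity_csv",
    "read_activity_csv",
]


@dataclass
class NeuralActivityMatrix:
    """Binary neurons-by-time activity with its time grid and provenance."""

    activity: np.ndarray          # (n_units * N, n_bins) in {0, 1}
    time_bins: np.ndarray         # bin centers
    stimulus_onsets: np.ndarray
    stimulus_of_bin: np.ndarray   # stimulus index per bin (0 = none)
    n_units: int
    N: int
    p: float
    seed: int

    @property
    def fraction_active(self) -> np.ndarray:
        """<N>_act per time bin: fraction of neurons firing."""
        return self.activity.mean(axis=0)


def looming_protocol(n_stimuli: int = 10, T_s: float = 30.0,
                     period: float = 150.0, H_max: float = 10.0,
                     H_min: float = 0.1) -> SignalProtocol:
    """Looming-like schedule: brief stimuli repeated at a fixed period."""
    return SignalProtocol(H_min=H_min, H_max=H_max, T_s=T_s,
                          Delta_T=period - T_s, n_stimuli=n_stimuli)


def unit_activations_from_model(
    params: ModelParams,
    protocol: SignalProtocol,
    n_units: int,
    seed: int,
    bin_dt: Optional[float] = None,
    threshold: Optional[float] = None,
    initial_state: str = "naive",
    solver: Optional[TSSSolver] = None,
) -> Tuple[np.ndarray, dict]:
    """Per-unit binary activation table over time bins.

    Each unit carries an independent storage trajectory sampled from the
    solver's one-step chain.  A unit counts as responding to a stimulus when
    its readout, time-averaged over the window given its storage state
    (stimulus windows are long compared to the readout and receptor
    timescales, so the within-window average self-averages over the signal
    ensemble), exceeds ``threshold`` — the midpoint of the passive and
    active means by default.  Units whose storage has climbed past the
    feedback balance therefore stop responding, which is what produces the
    declining activation fraction.  Returns the units-by-bins matrix (1
    inside windows of stimuli the unit responded to) and a metadata dict
    with the per-stimulus activation fraction.
    """
    if not params.is_derived:
        params = derive_energies(params)
    solver = solver or TSSSolver(params)
    thr = 0.5 * (params.U_mean_passive + params.U_mean_active) if threshold is None else threshold
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 911]))

    if initial_state == "naive":
        # an unstimulated subject: no storage accumulated before the first
        # looming presentation (the model's background signal would otherwise
        # pre-load the feedback)
        s_units = np.zeros(n_units, dtype=int)
    elif initial_state == "background":
        q0 = solver.stationary_q(protocol.H_min)
        s_units = rng.choice(solver.grid_s, size=n_units, p=q0)
    else:
        raise ValueError("initial_state must be 'naive' or 'background'")

    bin_dt = protocol.T_s / 6.0 if bin_dt is None else bin_dt
    epochs = solver.labeled_epochs(protocol)
    t = 0.0
    bin_times, bin_stim = [], []
    responded = np.zeros((n_units, protocol.n_stimuli), dtype=bool)
    for dur, mean, label in epochs:
        n_steps = max(1, int(math.ceil(dur / solver.dt_max - 1e-12)))
        dte = dur / n_steps
        cumM = np.cumsum(solver.step_matrix(mean, dte), axis=1)
        for _ in range(n_steps):
            r = rng.random(n_units)
            s_units = (cumM[s_units] < r[:, None]).sum(axis=1)
        nb = max(1, int(round(dur / bin_dt)))
        for b in range(nb):
            bin_times.append(t + (b + 0.5) * dur / nb)
            bin_stim.append(label if label is not None else 0)
        t += dur
        if label is not None:  # window-averaged readout at the sampling phase
            ubar = solver.u_cond_mean(mean)[s_units]
            responded[:, label - 1] = ubar > thr
    bin_stim = np.array(bin_stim)
    table = np.zeros((n_units, len(bin_stim)), dtype=np.int8)
    for k in range(1, protocol.n_stimuli + 1):
        cols = bin_stim == k
        table[:, cols] = responded[:, k - 1][:, None]
    meta = {
        "time_bins": np.array(bin_times),
        "stimulus_of_bin": bin_stim,
        "stimulus_onsets": np.array([protocol.onset(k) for k in range(1, protocol.n_stimuli + 1)]),
        "activation_fraction": responded.mean(axis=0),
        "threshold": thr,
    }
    return table, meta


def sample_neural_activity(
    unit_activations: np.ndarray,
    N: int,
    p: float,
    seed: int,
    meta: Optional[dict] = None,
) -> NeuralActivityMatrix:
    """Expand a units-by-time activation table into binary neuron firing.

    In every time bin, each of the ``N`` neurons of an active unit fires
    independently with probability ``p``; neurons of inactive units stay
    silent.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    units = np.asarray(unit_activations)
    n_units, n_bins = units.shape
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 912]))
    fires = rng.random((n_units * N, n_bins)) < p
    activity = (np.repeat(units, N, axis=0) > 0) & fires
    meta = meta or {}
    return NeuralActivityMatrix(
        activity=activity.astype(np.int8),
        time_bins=meta.get("time_bins", np.arange(n_bins, dtype=float)),
        stimulus_onsets=meta.get("stimulus_onsets", np.array([])),
        stimulus_of_bin=meta.get("stimulus_of_bin", np.zeros(n_bins, dtype=int)),
        n_units=n_units, N=N, p=p, seed=seed,
    )


def pca_embedding(activity: np.ndarray, n_components: int = 2):
    """Mean-centered PCA of a neurons-by-time matrix over time samples.

    Returns ``(scores, explained_variance_ratio)`` with one score row per
    time point.
    """
    X = np.asarray(activity, dtype=float).T  # samples = time points
    if X.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    if np.allclose(X.std(axis=0), 0.0):
        raise ValueError("constant activity matrix: PCA undefined")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


def stimulus_scores(scores: np.ndarray, stimulus_of_bin: np.ndarray,
                    component: int = 1) -> np.ndarray:
    """Per-stimulus mean of one PCA component over that stimulus' bins."""
    ks = np.unique(stimulus_of_bin)
    ks = ks[ks > 0]
    return np.array([scores[stimulus_of_bin == k, component].mean() for k in ks])


def generate_fixture(
    n_neurons: int = 200,
    n_stimuli: int = 10,
    habituation_rate: float = 2.0,
    noise: float = 0.05,
    seed: int = 0,
    habituating_fraction: float = 0.5,
    bins_per_stimulus: int = 10,
    pause_bins: int = 10,
    kernel_tau: float = 3.0,
) -> Tuple[np.ndarray, dict]:
    """Synthetic fluorescence-like neurons-by-time matrix.

    Stimulus-locked transients (a window pulse convolved with an exponential
    decay kernel of ``kernel_tau`` bins).  A ``habituating_fraction`` of the
    neurons decays across stimuli as exp(-k / habituation_rate) while the
    rest respond persistently — the population heterogeneity that rotates the
    activity pattern and puts the habituation trend on the second principal
    component, with the evoked on/off response on the first.  Per-neuron
    lognormal gains plus optional Gaussian noise.  A synthetic stand-in for a
    processed recording; byte-reproducible given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 913]))
    period = bins_per_stimulus + pause_bins
    n_bins = n_stimuli * period + pause_bins
    tb = np.arange(n_bins, dtype=float)
    gains = rng.lognormal(0.0, 0.3, size=n_neurons)
    habituating = rng.random(n_neurons) < habituating_fraction
    kernel = np.exp(-np.arange(4 * int(kernel_tau) + 1) / kernel_tau)
    stim_of_bin = np.zeros(n_bins, dtype=int)
    X = np.zeros((n_neurons, n_bins))
    for k in range(n_stimuli):
        a, b = k * period, k * period + bins_per_stimulus
        stim_of_bin[a:b] = k + 1
        pulse = np.zeros(n_bins)
        pulse[a:b] = 1.0
        resp = np.convolve(pulse, kernel)[:n_bins]
        amp = gains * np.where(habituating, math.exp(-k / habituation_rate), 1.0)
        X += amp[:, None] * resp[None, :]
    if noise > 0:
        X += noise * rng.standard_normal(X.shape)
    meta = {"time_bins": tb, "stimulus_of_bin": stim_of_bin,
            "stimulus_onsets": np.arange(n_stimuli) * float(period),
            "habituating": habituating}
    return X, meta


def write_activity_csv(activity: np.ndarray, time_bins: np.ndarray, path) -> None:
    """One neuron per row; header row carries the time stamps."""
    df = pd.DataFrame(np.asarray(activity), columns=[f"{t:g}" for t in time_bins])
    df.index.name = "neuron"
    df.to_csv(path)


def read_activity_csv(path) -> Tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    times = np.array([float(c) for c in df.columns])
    return df.to_numpy(), times
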