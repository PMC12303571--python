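# habinfo

Habituation — the progressive decline of a response to a repeated, identical
stimulus — appears everywhere from chemotactic signaling to the zebrafish
optic tectum. `habinfo` implements a minimal stochastic model in which
habituation emerges from three ingredients only: a sensing unit, a response
population, and a slow memory that feeds back on the sensor. The package is
aimed at researchers in stochastic thermodynamics and quantitative
neuroscience who want a fully solvable testbed linking habituation dynamics
to information and energy budgets.

## The model

A two-state receptor `R` (passive/active) senses a fluctuating signal `H`
with exponential law p(h) = λ e^{−λh}, λ = 1/⟨H⟩(t), whose mean follows a
square wave (background ⟨H⟩_min, stimulus ⟨H⟩_max). Switching follows
Arrhenius rates along two pathways — a sensing pathway driven by the signal
energy βh and an internal pathway inhibited by the stored energy
κσ s/N_S:

    Γ_P→A^(H) = e^{β(h−ΔE)}/τ_R        Γ_A→P^(H) = 1/τ_R
    Γ_P→A^(I) = e^{−βΔE}/(g τ_R)       Γ_A→P^(I) = e^{β κ σ s/N_S}/(g τ_R)

An active receptor pumps a readout birth–death population `U`
(birth e^{−β(V−cr)} Γ_U⁰, death u Γ_U⁰), whose mean is the observable
response; the readout catalytically produces a storage population `S`
(birth u e^{−βσ} Γ_S⁰ up to capacity N_S, death s Γ_S⁰) that closes the
negative-feedback loop. With τ_U ≪ τ_R ≪ τ_S ≈ τ_H the joint law p(u, s, t)
obeys a Chapman–Kolmogorov recursion in which readout and receptor are
conditionally stationary; the package iterates it exactly on the truncated
grid (the timescale-separation solver, `TSSSolver`) and cross-validates
against an exact Gillespie simulation of all four variables.

On top of the solver sit:

* the five habituation hallmarks (potentiation, spontaneous recovery,
  subliminal accumulation, intensity and frequency sensitivity),
* information observables — the readout–signal mutual information I_{U,H},
  the feedback information ΔI_f = I_{(U,S),H} − I_{U,H} (always ≥ 0), and
  the exact identity I_{S,H} = 0 under timescale separation,
* thermodynamic observables — the internal storage flux J_int and the
  receptor cycle dissipation δQ_R = β(H + κσ⟨S⟩/N_S),
* a stationary Pareto optimization γ I − (1−γ) E_tot over (β, σ), including
  the collapse of fronts when the inhibition adapts as κ = ⟨H⟩_max/(ασ),
* a mapping of readout units onto binary-neuron populations with a PCA
  embedding, for comparison with calcium-imaging recordings of repeated
  looming stimulation.

## Worked example

```python
import numpy as np
from habinfo import ModelParams, SignalProtocol, TSSSolver, derive_energies
from habinfo.hallmarks import habituation_time, peak_responses
from habinfo.info import info_gain

params = derive_energies(ModelParams(beta=3.0, sigma=0.6))
protocol = SignalProtocol(H_min=0.1, H_max=10.0, T_s=100.0, Delta_T=100.0,
                          n_stimuli=12)
solver = TSSSolver(params)
traj = solver.evolve(protocol, record=False)
peaks = peak_responses(traj, protocol)
print("per-stimulus response:", np.round(peaks, 1))
t_hab, n_hab = habituation_time(peaks, protocol)
print("habituates at stimulus", n_hab, "(t =", t_hab, ")")
g = info_gain(solver, protocol)
print("information gain:", round(g.DeltaI_UH, 4), "nats;",
      "flux change:", round(g.DeltaJ_int, 5))
```

prints

```
per-stimulus response: [105.8 100.7  97.8  96.2  95.2  94.6  94.3  94.1  94.   93.9  93.8  93.8]
habituates at stimulus 7 (t = 1200.0 )
information gain: 0.0387 nats; flux change: -0.00629
```

The response declines stimulus after stimulus and settles (habituation, by
the 0.5% decrement criterion, at the 7th stimulus); the habituated state
carries *more* information about the signal than the first response
(ΔI_{U,H} > 0) while dissipating *less* through storage turnover
(ΔJ_int < 0) — the information–energy synergy at the onset of habituation.

A command-line interface exposes the same machinery
(`habinfo evolve | hallmarks | info-scan | pareto | neural | validate`);
every run writes CSV/JSON artifacts plus a `provenance.json` with the fully
resolved configuration and its hash.

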