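# Methods

## Model and solution strategy

The state is (r, u, s, h): a two-state receptor, a readout count, a storage
count with hard capacity N_S, and the instantaneous signal. The master
equation couples four generators, one per unit and one for the environment,
weighted by inverse timescales. All solver results use the
timescale-separation (TSS) limit τ_U ≪ τ_R ≪ τ_S ≈ τ_H:

1. conditioned on the receptor, the readout is stationary — Poisson with
   mean e^{−β(V−cr)}, truncated and renormalized on [0, U_max];
2. conditioned on (s, h), the receptor is stationary — p_A = k_on/(k_on+k_off)
   with both pathway rates summed, evaluated in log-space so arbitrarily
   large signal energies never overflow;
3. the slow pair (U, S) follows a Chapman–Kolmogorov recursion: a storage
   propagator at frozen readout, followed by re-equilibration of the fast
   variables under the signal law of the arrival time.

Every updated joint law has the product form p(u,s) = K(u,s;λ) q(s), where
K is a two-Poisson mixture weighted by the signal-averaged activation
Ābar(s). The recursion therefore closes on the storage marginal q(s): one
step is a stochastic (N_S+1)×(N_S+1) matrix M = mix(Ābar)·P̄, with P̄ the
storage propagator averaged over the conditional readout laws. Long
protocols cost one small matrix–vector product per step; the full-table
step is retained and tested for cross-checks. Stationary states are the
unit-eigenvalue left eigenvector of M (power-polished, residual < 1e-9),
and agree with the closed-form detailed-balance chain built from the
conditional readout means in the small-step limit.

### Storage propagator

The storage generator at frozen readout is tridiagonal: births u e^{−βσ}Γ_S⁰
(forbidden at s = N_S), deaths s Γ_S⁰, diagonal set to minus the column sums
so probability is conserved exactly. The propagator over one step is built
by eigendecomposition of the generator restricted to the n nearest
neighbours of the initial state (default n = 2), with coefficients solving
the δ-initial condition; a dense eigendecomposition of the full generator is
available as a fallback. Truncation error against the dense matrix
exponential is ~2e-7 in total variation at the step sizes used. Steps obey
the jump rule max(rate)·Δt ≤ 0.2; the step size adapts to it per epoch, and
halving it changes ⟨U⟩(t) by < 1e-4 relative.

### Signal quadrature

Signal averages ∫dh λe^{−λh} f(h) use a midpoint rule uniform in the
exponential CDF: y_i = (i+½)/n, h_i = −⟨H⟩ ln(1−y_i), weights 1/n (default
n = 512). At β ≥ 3 the receptor response is nearly a step in h; placing
nodes uniformly in cumulative probability resolves the switch wherever it
falls, and doubling n changes the information functionals by ~1e-11 (a
64-point Gauss–Laguerre rule, by contrast, drifts at the 1e-3 level here).
A further benefit: treating the nodes as a discrete signal variable with
weights 1/n makes every information functional an exact mutual information
of a discrete joint, so the structural identities — I_{S,H} = 0 and
ΔI_f ≥ 0 — hold to machine precision at any quadrature order, not just in
the continuum limit.

## Parameters

| symbol | meaning | default | notes |
|---|---|---|---|
| β | inverse temperature (1/energy) | 3 (scans: 0.5–5) | thermal noise scale |
| σ | storage energy cost (energy) | 0.6 (scans: 0.05–1.5) | per stored unit |
| ΔE | receptor barrier (energy) | 1 | |
| N_S | storage capacity (count) | 30 | hard reflecting cap |
| ⟨U⟩_P, ⟨U⟩_A | readout means, passive/active (count) | 30 / 150 | fix V and c by inversion |
| α | inhibiting storage fraction | 2/3 | sets κ = H_ref/(ασ) |
| H_ref | reference signal (energy) | 10 | |
| g | pathway timescale ratio | 1 | |
| Γ_S⁰ = 1/τ_S | storage rate (1/time) | 1/500 | see below |
| τ_R, τ_U | receptor, readout timescales (time) | 1, 0.01 | ordering enforced |
| τ_H | environment redraw time (time) | τ_S | comparability bound configurable |
| ⟨H⟩_min, ⟨H⟩_max | protocol levels (energy) | 0.1, 10 | square wave |
| T_s, ΔT | stimulus/pause durations (time) | 100, 100 | |

The readout energies are never set directly: V = −ln⟨U⟩_P/β and
c = ln(⟨U⟩_A/⟨U⟩_P)/β, so the conditional means are exact by construction.
The active mean exceeds the passive one (active receptors pump the readout
up); both are overridable for the opposite orientation.

**Storage timescale.** The protocol epochs (100 time units) and the storage
relaxation time must be commensurate for memory to persist across stimuli:
with τ_S ≲ the epoch length, the storage re-equilibrates within every
stimulus and pause, every response is identical, and no habituation across
stimuli can occur. The default τ_S = τ_H = 500 makes the memory span a few
stimulation cycles; it was fixed once, from the qualitative requirement of
a gradual multi-stimulus habituation course (n_hab ≈ 7 at β = 3, σ = 0.6
under the reference protocol), before any quantitative observable was
evaluated. Quantities that depend on this choice — most notably the
subliminal-accumulation magnitude, see Limitations — inherit its
uncertainty.

## Hallmark metrics

The response to stimulus k is ⟨U⟩ sampled at a fixed phase of the k-th
window (end of window by default; results are insensitive to the phase up
to one stimulus in n_hab). Habituation is the first stimulus whose relative
peak decrement falls in [0, 0.005]; recovery is the first pause after which
a probe stimulus evokes a response within 1% of the initial one. Recovery
times are measured by branching a single probe off the post-train state and
bisecting the pause length — the probe response is monotone in the pause —
which resolves recovery to the solver step rather than to the stimulation
period (periodic probing at period T_s+ΔT cannot resolve few-percent
changes of a recovery time of a few hundred time units).

Frequency sensitivity is flagged on rapidity *in time* (t_hab) and depth of
the decrement: denser stimulation habituates earlier and deeper but may
need *more* stimuli to settle below the fixed per-stimulus decrement
threshold, so the stimulus count is reported but not used as the criterion.
Intensity sensitivity is evaluated for stimuli well above background
(H_max ∈ [H_ref/2, 4 H_ref]); for stimuli comparable to the background,
habituation itself fades and the normalized decrement is no longer
monotone.

## Stochastic simulation

The exact simulator implements all reaction channels plus an environment
channel that redraws h from the current epoch's exponential law at
exponential waiting times of mean τ_H and at protocol switches. Rates are
constant between events and boundaries, so advancing to a boundary and
redrawing the waiting time is exact. Each trajectory owns a
counter-derived seed; ensembles are bit-reproducible.

Two feasibility constraints shape where the simulator can be used. First,
with exponential signals, E[e^{βh}] diverges whenever β > 1/⟨H⟩, so the
expected number of receptor events is unbounded at the default exponents —
the cross-validation therefore runs on a reduced model (N_S = 5, readout
means 5/20, β = 1, H_ref = H_max = 3) where all Arrhenius exponents stay
moderate. Second, the TSS recursion implicitly resamples the signal from
its marginal at every step; an environment frozen for τ_H = τ_S builds
(s, h) correlations the TSS ansatz excludes (≈5% bias on ⟨S⟩ in the
reduced model). The validation oracle therefore uses
τ_R ≪ τ_H = 0.02 τ_S ≪ τ_S: fast enough to decorrelate, slow enough for
the receptor to equilibrate to each draw. Under these conditions the
solver and a 1e4-trajectory ensemble agree within 3 standard errors on
⟨U⟩(t) and ⟨S⟩(t) at 20 sample times over a three-stimulus protocol
(~2.5 min of simulation). Validation problem sizes were chosen so the
whole suite runs on a single CPU in a few minutes.

## Pareto optimization

Objectives at the stationary state under a constant signal H_st: the mutual
information I_st (nats) and the total energy per unit energy
E_tot = δQ_R + E_int, with δQ_R = β(H_st + κσ⟨S⟩/N_S) the receptor cycle
affinity and E_int = τ_S J_prod/σ the storage production term. At a 1-D
birth–death stationary state the *net* storage flux vanishes identically,
so the default energy bookkeeping uses the one-way production flux; the net
flux is available as a mode for transient budgets. The functional
γ I − (1−γ) E_tot is maximized by grid search (γ ∈ {0, 0.01, …, 1} by
default). Linear scalarization can only reach the convex part of the trade-
off, so the scalarized maximizers are reported alongside the full
non-dominated set (brute-force dominance filter); the front-collapse
statistic compares non-dominated fronts by mean |ΔI| over overlapping
energy ranges, skipping pairs with disjoint budgets. With the committed
grids, adapting κ = ⟨H⟩_max/(ασ) shrinks the maximum pairwise front
distance for ⟨H⟩_max ∈ {5, 10, 20} to about 0.3 of the fixed-κ spread.

## Neural mapping

Each readout unit stands for N = 20 binary neurons firing independently
with p = 0.5 per time bin while their unit responds. Unit stochasticity
comes from sampling each unit's storage trajectory from the solver's
one-step chain — an exact realization of the TSS process (direct simulation
is infeasible at the comparison point β = 4.5, see above). A unit responds
to a stimulus when its window-averaged readout, given its storage state,
exceeds the midpoint of the passive and active means (windows are long
compared to the readout and receptor timescales, so the within-window
average self-averages over the signal ensemble). Units start from a naive
(s = 0) state, the analogue of an unstimulated subject. Under the
looming-like protocol (30-unit stimuli every 150 time units) at
β = 4.5, σ = 0.15 the activation fraction declines monotonically to near
zero.

The synthetic recording fixture emulates only the post-processed activity
matrix of a stimulus-locked population: window pulses convolved with an
exponential kernel, a habituating and a persistent subpopulation (the
heterogeneity that rotates the activity pattern and places the habituation
trend on the second principal component), lognormal gains and optional
Gaussian noise. It does not emulate evoked-response dynamics, baseline
drift, correlated noise, or segmentation artifacts — passing tests
demonstrate the analysis pipeline's behavior on data with known structure,
not performance on raw recordings. For model-generated *binary* activity,
deep habituation makes the on/off amplitude and the habituation trend
collinear, so the habituation ordering can load on the first component
instead; tests assert the ordering within the two-dimensional embedding.

## Numerical choices and degenerate inputs

* Readout grid: U_max = ceil(max mean + 8√(max mean)); truncated mass must
  stay below 1e-8 or the solver refuses the grid.
* σ = 0 makes the balance-derived κ singular and is rejected unless an
  explicit κ override is supplied (κ = 0 switches the feedback off and is
  the no-habituation control).
* Entropies use 0·log 0 = 0; information is reported in nats.
* Probabilities are clipped at 0 and renormalized only when the defect is
  below the conservation tolerance (1e-8); larger defects raise.
* Stationary solves fail loudly (residual reported) rather than returning
  unconverged states.

## Limitations

* The subliminal-accumulation magnitude (the ~5% class of recovery-time
  increase) is strongly parameter-dependent: with β = 3, σ = 0.6 fixed it
  ranges from ~0.6% to ~8% as the unprinted storage timescale and (β, σ)
  vary within plausible ranges; at the committed defaults it is ~1.1%. The
  package reports the computed value rather than tuning τ_S to a target.
* The TSS solution treats the signal as redrawn every step; for
  environments with persistence times comparable to τ_S it overestimates
  storage growth by a few percent (quantified above). I_{S,H} = 0 is exact
  only in this same limit.
* The hallmark flags are threshold-based (0.5% / 1%); the hallmarks
  themselves are robust to the threshold choice, but n_hab and t_recovery
  values are not threshold-free quantities.
* No spatial structure, single receptor type, single stimulus type;
  dishabituation and other multi-stimulus hallmarks are out of scope.
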