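# Methods

## The representation

A discrete random variable `x(t)` with `N` values is represented by `N`
ensembles of `K` stochastic spiking neurons. Every spike is read as one
sample ("particle") of the variable's current value. Downstream neurons
integrate spikes through EPSPs; with the unit-amplitude rectangular EPSP of
length `τ` used throughout, the EPSP-filtered activity of ensemble `i`,

    A_i(t) = Σ_m Σ_spikes ε(t − t_spike),

is exactly the ensemble's spike count in the half-open window `(t−τ, t]`,
and the represented distribution is the relative portion of spikes,
`p̂_i = A_i / Σ_k A_k`. When ensemble neurons fire as Poisson processes with
rates `f·p_i`, `p̂` is unbiased for the `τ`-averaged probability and has
variance `≈ p(1−p)/S`, where `S = K·f·τ` — the *estimation sample size*,
the expected number of spikes from all ensembles per EPSP length. `S`
controls the fidelity of the code; `K`, `f` and `τ` enter only through `S`
(larger `τ` additionally low-pass filters the represented distribution).

Neurons are stochastic spike-response units: the membrane potential `u` maps
to an instantaneous rate through the rectified linear link `r = f·max(u,0)`,
discretized as one Bernoulli draw per `dt = 0.5 ms` bin (at most one spike
per neuron per bin; bin probabilities saturate at 1). Internally the circuit
expresses all membrane drives in Hz (the link scale is absorbed into the
weights), so every term of the membrane equations is directly comparable to
the filtering equations it approximates.

## The filtering problem and its exact solution

The hidden state evolves as a continuous-time Markov chain with transition
rates `q_{k→i}` (optionally per context `c`) and is observed through `J`
afferent neurons firing Poisson with state-dependent rates `λ_i^(j)`.
Unnormalized posterior masses obey

    dL_i/dt = L_i ( Σ_j w_ij s_j(t) − λ̄_i ) + Σ_{k≠i} q_{k→i} L_k − L_i Σ_{k≠i} q_{i→k},

with `λ̄_i = Σ_j λ_i^(j)` and spike trains `s_j`. The `exact_filter` module
integrates this per bin, entering afferent spikes as exact multiplicative
likelihood factors `λ_i^(j)` (so the evidence-only special case matches the
closed form `L_i(t) = L_i(0)·e^{−λ̄_i t}·Π_j (λ_i^(j))^{N_j(t)}` to machine
precision) and the transition terms by forward Euler; masses are
renormalized every bin. Evidence may equivalently be supplied through
EPSP-filtered traces with weights `w_ij = (log λ_i^(j) + c_j)/τ`: once an
EPSP has been fully integrated its contribution is exactly `log λ_i^(j) +
c_j`, and the per-afferent shift `c_j` (chosen as `−min_i log λ_i^(j)` to
keep weights non-negative) scales all masses alike and cancels in
normalization. Baselines: an input-only decoder (Bayes on the most recent
observation, held between observations, uniform prior) and a context-blind
filter using the arithmetic-mean rate matrix across contexts.

## The spiking particle-filter circuit

Two coupled layers of ensembles implement the filter:

* **Evidence layer E** (`N` ensembles × `K`). Membrane drive of neuron
  `e_i^m`: `Σ_j w_ij y_j(t) + b_i − I(t)`, gated by its dynamics-layer
  partner (below). `y_j` are the EPSP-filtered afferent trains;
  `b_i = 1.1/τ + (max_k λ̄_k − λ̄_i)` carries the recovery term and the
  evidence-decay term shifted to be non-negative; `I(t)` is the shared
  lateral inhibition.
* **Dynamics layer D** (`N` ensembles × `K`, duplicated per context in
  context tasks). Drive of ensemble `i` (context `c`):
  `Σ_k v^c_{k→i} A^E_k(t)` with `v^c_{k→i} = q^c_{k→i}/K` for `k≠i` and the
  self weight `(1/τ − Σ_{k≠i} q^c_{i→k})/K`, so each row's total outflow is
  `1/τ` and a stationary distribution is preserved at sample size `S`. With
  all rates zero this is a pure diagonal copy (evidence integration).

**Multiplication by gating.** The filter requires the product of the
current mass and the evidence factor. Each E neuron `e_i^m` is disinhibited
by its D partner `d_i^m`: it can fire only if the partner spiked within the
last `τ` (gate threshold `θ = 0.5` on the partner's filtered trace; one
spike suffices for rectangular EPSPs). The expected number of released E
neurons equals the D mass, so the ensemble rate is the desired product under
sparse activity (`S ≪ K`; slot collisions shave a few percent when mass
concentrates). Gating is implemented exactly as release/suppress, so the
baseline inhibition magnitude is immaterial. In hard-context tasks every D
ensemble of context `c` is additionally disinhibited by its 10-neuron
context ensemble (50 Hz when active); in graded mode each D neuron is gated
by a single context neuron of an ENS context representation, and the
dynamics weights carry the factor `K_ctx/S_ctx` so the effective transition
rates are the belief-weighted mixture `Σ_c p̂(c)·q^c`.

**Lateral inhibition.** `I = ν·max(A_total − S, 0)/τ`, shared by all E
neurons of a variable, applied with a 0.5 ms delay (one bin), optionally
capped. It only corrects excess activity; the recovery margin in the bias
(`1.1/τ` rather than `1/τ`) keeps the one-sided loop pinned at `S` instead
of drifting below it. The default scaling is the critically damped value
`ν = τ/(2·S·dt)` (0.05 at `S = 400`): the discrete feedback loop has
per-bin gain `g = S·ν·dt/τ`, and `g = 1/2` is the largest non-oscillatory
choice. Larger `ν` (gain 10 at `ν = 1`) produces relaxation oscillations
whose silent phases can extinguish the entire layer. In the 3 ms
delayed-inhibition control the classic delay bound `k·T < π/2` with
`k = S·ν/τ` prescribes `ν ≤ πτ/(2·S·T) ≈ 0.026`; the control uses `ν/2`.

**Readout layers.** A feed-forward layer with weights
`c·P(x=l|z=i)/(K_out·τ)` represents `Σ_i P(x|z=i) p̂_i` with sample size
`c·S_in` (the ambiguous-target action readout uses `K_out = 100` per action
and `S_out = 80`, marginalizing color).

## What the synthetic scenarios emulate

All experiments are synthetic; the generator defaults are the benchmark
conditions (see `scenarios.py`): two-state evidence integration from two
afferent spikes (K=2000, S=400; per-trial priors U(0.1,0.9), rates
U(6,21) Hz), two-state pure dynamics (q ~ U[0,30] Hz), a five-state chain at
1 Hz with 60 ms minimum dwell observed through 35 Gaussian-tuned afferents
(12 s sequences), its two-context variant with interchanged 2→4/3→5
transitions and context switching on every entry to state 1, self-
localization on a 10×10 two-chamber grid with four movement contexts
(3.5 Hz along the movement direction, 0.1 Hz between other adjacent cells,
K=S=250, ambiguous southern landmarks, evidence-free northern corridor,
scripted 3.8 s trajectory), the 16-state ambiguous target task (19 stimulus
ensembles × 20 afferents at 0.1/5 Hz; epochs 100/250/250/250 ms; K=1000,
S=400), and its two-trial sequential variant where a four-state phase
filter provides graded context that resets the belief during fixation
(all-to-all 1 Hz).

Features of real neural data deliberately not emulated: conductance
dynamics, refractoriness, synaptic delays (beyond the delayed-inhibition
control), correlated afferent noise, and learning. Passing tests therefore
show that the circuit mechanism implements the filtering computation under
its own model assumptions, not that cortex does.

## Numerical choices and scale

Time step 0.5 ms everywhere; spike times bin-left-aligned; all windows
half-open `(t−τ, t]`. `τ = 20 ms` for every EPSP; the exponential control
kernel matches the rectangular integral (amplitude 1, decay 20 ms), which
shortens the gate window to `τ·ln 2`. Initialization draws at most one
spike per neuron on `[−τ, 0)` with probability `S·p0_i/K`. Argmax ties in
decoding resolve to the lowest state index; posterior rows with zero total
mass are flagged undefined and count as errors. One master seed spawns
independent child streams per trial, so trial counts can change without
perturbing earlier trials. Benchmarks in the test suite run scaled down
(25 trials for the two-state scatter experiments, 5 sequences for the
generic tasks) as the package's standard verification sizes.

## Known limitations

* **Resampling diffusion.** The E→D→E loop redraws the represented masses
  roughly twice per EPSP length, so the estimate's variance grows about
  linearly in time (≈ `p(1−p)/S` extra per half-cycle) instead of staying at
  the single-snapshot value `p(1−p)/S`; in evidence-free stretches the
  representation is a critical branching process. Time-resolved deviations
  from the exact filter are therefore ~2× the snapshot standard deviation
  at 45 ms.
* **Extinction.** A state whose ensembles hold zero particles cannot be
  revived by evidence (only by transition inflow from other states). In the
  ambiguous target task, rare baseline spikes from inactive stimulus
  ensembles multiply two random states' likelihood by 50; the shared
  inhibition then sheds the added mass through short layer-wide silences in
  which minority states (≈ S/N = 25 particles) can die. The exact filter
  recovers from such spurious kicks; the particle circuit loses roughly a
  quarter of trials this way, which bounds its success rate on that task.
* **Representable likelihood ratios.** Within one EPSP length the circuit
  realizes only part of a large single-spike likelihood jump (the released
  count lags the mass), softening both correct and spurious updates.
* **Mass transients.** Under delayed inhibition, evidence bursts can drive
  the layer mass to several times `S` before the delayed feedback reacts;
  excursions stay bounded and the error is unaffected, but they exceed a
  strict 5·S envelope at the default observation scale.
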