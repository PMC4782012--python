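# Methods

`neuromodal` simulates a closed-loop spiking controller that tunes a fast
periodic movement of a compliant multi-joint plant toward its dominant
oscillation mode. This note documents the model equations, the parameter
choices that matter, the desk-scale protocol design, numerical choices,
and known limitations.

## Controller principle

Joint deflections φ ∈ ℝⁿ are projected onto one controller coordinate
φ_z = wᵀφ; a thresholding unit turns φ_z into a scalar timing/force
signal f_z; the same weights expand the scalar back into joint space,
f = w f_z. If w equals the first principal component of the movement,
the plant is excited along its dominant (resonant) eigenmode, which
maximizes the energy retained per unit of inserted actuation energy.

Two adaptation rules drive w toward that principal component:

* **Oja's rule** dw/dt = γ (wᵀφ)(φ − (wᵀφ) w): Hebbian growth with
  multiplicative normalization; its fixed point is the unit dominant
  eigenvector of E[φφᵀ].
* **Hebb with decay** dw/dt = c_w φ − w/τ_eff: for non-negative, in-phase
  inputs its fixed point c_w τ_eff ⟨φ⟩ points along the same direction.
  This is the abstraction of the serotonergic pathway.

`controller.py` implements both at the rate level; the rest of the
package realizes them with spiking machinery.

## Spiking realization

**Sensory coding.** Each joint's deflection is encoded by a pool of
`n_sens` Poisson neurons with rectified-linear rate m_sens·max(δ, 0).
For the two-mass plant δ is the deviation from the force-free
equilibrium; for the leg δ = φ − φ0 is the stretch of the series-elastic
element relative to its crouch equilibrium — the same physical quantity
(elastic deflection) in both plants. Per step of width dt a Poisson
neuron fires with probability ν·dt (valid for ν·dt ≪ 1; the simulation
grids keep ν·dt ≤ 0.15 everywhere).

**Input pathway (timing unit).** Sensory spikes reach `n_tim`
conductance-based LIF neurons through plastic synapses (random
connectivity p_con, optional conduction delay τ_del,STDP as an exact
integer-step ring buffer). Membrane: τ_m dU/dt = (U_rest − U) +
g_exc(U_exc − U) + g_inh(U_inh − U); each conductance is a fast
exponential stage (τ_ampa = 5 ms, jump = synaptic weight per spike)
low-passed into a slow stage (τ_nmda = 100 ms), effective conductance =
mean of both. A spike resets U to rest and clamps it there for
τ_thr = 5 ms (absolute refractory period, rate ceiling 200 Hz). LIF
constants default to the published conductance-based model values this
neuron is adopted from (τ_m 20 ms, U_rest −60 mV, U_exc 0, U_inh
−80 mV, ϑ −50 mV). An external pool of `n_inh` inhibitory Poisson
neurons (ν_ext = 3 Hz, weight w_ext) sets the resting excitability in
the leg network.

**Plasticity.** Sensory→LIF weights follow the minimal triplet STDP
rule: at a postsynaptic spike, Δw = η A⁺ z⁺_pre z_slow_post(t−ε); at a
presynaptic spike, Δw = −η A⁻ z⁻_post. Traces z⁺ (τ⁺ = 16.8 ms),
z⁻ (τ⁻ = 33.7 ms) and z_slow (τ_slow = 114 ms) decay exponentially and
jump by one at their neuron's spikes; the ε-offset is realized by
excluding the triggering spike from z_slow. The triplet dependence on
z_slow makes potentiation grow with postsynaptic rate (BCM-like).
Homeostatic **synaptic scaling** drifts every weight of a postsynaptic
neuron at rate w·(ν_tar − ν̄²/ν_tar)/(τ_s ν_tar), where ν̄ is the
spike train low-passed with τ_rs. The drift vanishes at ν̄ = ν_tar, is
positive below and negative above.

The scaling term is **multiplicative in w**. This is a deliberate model
decision: an additive uniform drift preserves weight *differences*, so
the ratio w₁/w₂ has no interior fixed point and drifts to
winner-take-all (we measured ratio → 0 over long runs under the additive
variant). With multiplicative scaling the stationarity conditions
a_i·C + w_i·s = 0 give w₁/w₂ = a₁/a₂ exactly — the principal-component
extraction that the controller requires, and the behaviour the
feed-forward experiment shows. The additive variant remains available
(`TripletParams.multiplicative_scaling = False`).

**Output pathway (serotonergic gain).** Per joint, `n_ser` raphe Poisson
neurons fire at b_ser + m_ser·δ (rectified). Each spike releases c_ser
(nM) of 5-HT into that joint's motorpool; clearance follows
Michaelis–Menten kinetics d[5-HT]/dt = −v_max/(k_m/[5-HT] + 1) with
k_m = 170 nM and v_max = 100 nM/s (0.1 µM/s; the printed value of this
constant is dimensionally ambiguous, and 100 nM/s matches the in-vivo
clearance literature and keeps concentrations in the physiological
10–100 nM band). For [5-HT] ≪ k_m the clearance is first order with
τ_eff = k_m/v_max = 1.7 s, making the pathway a leaky integrator of the
sensory rate — the Hebb-with-decay rule. The motor gain of joint i is
w_NM,i = c_NM·[5-HT]_i, multiplicative on the common motor signal.
`n_ser` is not tabulated in the source protocols; we use 290 (= n_sens)
for the two-mass network and 10 for the leg, chosen once so that the
release/clearance balance sits in the stated concentration band given
the tabulated per-spike c_ser.

**Motor signal.** ν̄_post is the pooled (summed) LIF spike train
low-passed with τ_f, and f_z = m_f·ν̄_post. The pooled-sum convention
(rather than pool average) is what makes the enlarged-network protocol
consistent: doubling the LIF pool doubles ν̄_post, and the protocol
compensates by halving c_NM "to keep the motor signal approximately
equal". The applied generalized force is f_i = −w_NM,i·f_z (two-mass)
or a motor set point u_i = −w_NM,i·f_z shifting the series spring,
τ_i = k_i(u_i − φ_i + φ0,i) − d_i φ̇_i (leg).

**Reflex polarity.** The motor output *opposes* the sensed deflection
(a stretch reflex). This sign is load-bearing: the sensing→force path
has a causal lag (filter τ_f, conduction delays), and for a resonant
plant a lagged force proportional to +δ strictly extracts energy
(work per cycle ∝ −sin ωτ_lag) — in simulation the positive-sign loop
either latches into a saturated static state or decays to rest. With
the reflex sign the same lag *pumps* the resonance: the extension
command peaks during the rebound phase. The polarity is configurable
(`ExperimentConfig.motor_sign`).

## Plants

**Two-mass oscillator.** φ̈ = −(d₀/m)φ̇ − Kφ + f/m with the tabulated
m = 0.5 kg, k₀ = 8, k₁ = 15 N/m, d₀ = 0.3 N·s/m. Eigenmodes (1,1) at
√(k₀/m) = 4 rad/s and (−1,1) at √((k₀+2k₁)/m) = √76 rad/s. Initial
deviation (0, 0.1) m excites both modes equally.

**Hopping leg.** Trunk (m₀ = 0.5 kg, vertical rail) + thigh and shank
(uniform rods, m₁ = 0.1 kg each, length l) with revolute hip and knee.
Angles are measured from full extension, positive in flexion; the shank
absolute angle is φ₁ − φ₂, so the crouch equilibrium φ0 = (π/6, π/3)
puts the foot directly under the trunk. The equations of motion
M(φ)v̇ + p(φ,v) = Q + JᵀF were derived symbolically (Lagrangian) and
are cross-checked in the test suite against an independent sympy
evaluation. Ground contact at the foot point: linear spring–damper
normal force clamped at zero (no adhesion) plus viscous tangential
friction saturated at μ·F_n.

Free mechanical parameters, chosen once on physical grounds:

| parameter | value | why |
|---|---|---|
| segment length l | 0.106 m | with the printed 0.75 N·m/rad springs, longer segments (e.g. 0.3 m) collapse statically — gravity torque about the knee exceeds any available spring+motor torque; ~0.1 m yields centimeter hops with joint excursions of a few tenths of rad |
| ground stiffness | 1e5 N/m | landing penetration < 5 mm |
| ground damping | 300 N·s/m | near-critical for the ~0.1–0.3 kg unsprung mass |
| friction μ | 1.0 | foot essentially pinned during stance |
| joint stops | 25 N·m/rad at φ < −0.11 rad | the reflex otherwise drives hip/knee backwards through the straight configuration into unphysical trapped states; the 0.11 rad margin keeps the stop out of the regular gait so the leg cannot lean on it statically |

The converged weight ratios and trajectory principal component are
sensitive to these at the few-percent level (documented sensitivity:
l ± 5 % moves the converged ratio by roughly ∓0.05).

## Desk-scale protocols

The full-length protocols (60,000 s open loop, 10,000 s closed loop)
exist because the STDP amplitudes A⁺ = 6.5e-5 / A⁻ = 1.1e-5 are reduced
by two orders of magnitude from the original triplet-model values to
match in-vivo learning time scales of hours. The package's default
protocols compress the synaptic time scale and divide durations
accordingly; *converged ratios*, not time constants, are the quantities
of interest. Serotonergic dynamics converge in seconds and are never
scaled. Per experiment:

* **Feed-forward**: A± × 10, duration 6,000 s (dt = 1 ms). A factor of
  100 destabilizes this protocol: the postsynaptic unit is a rate-coupled
  Poisson neuron with no saturation, and at ×100 the correlational LTP
  outruns the (amplitude-independent) scaling.
* **Two-mass**: A± × 100, duration 400 s (neural dt = 0.1 ms, serotonin
  1 ms). The LIF pool's refractory ceiling bounds the loop, so ×100 is
  stable. 400 s ≈ 8 scaling time constants, enough to forget the
  asymmetric initial-deflection imprint on the weight ratio.
* **Leg**: A± × 100 together with τ_s 15,000 → 150 s and τ_rs 300 → 3 s,
  duration 150 s. The leg's scaling is two orders of magnitude weaker
  than the other protocols' (τ_s = 15,000 s vs 50 s), so compressing
  amplitudes alone would shift the LTP/scaling weight fixed point by the
  same factor (weights grew ~50× and the pool saturated). Compressing
  both sides preserves the fixed point and the homeostatic loop's
  damping ratio; the compressed rate estimator (3 s) stays long against
  the ~0.4 s hop cycle.
* **Jump-height/ratio sweep**: unchanged from the source protocol
  (20 s per ratio, plasticity and neuromodulation frozen at the
  converged norms, ratio 0.05–1.5 in steps of 0.03, mean of the last
  20 apexes).
* **Network-size fluctuation comparison**: full-scale amplitudes, 50 s,
  apex SD over the 30–50 s window. Synaptic weights are held at their
  initial values here: at compressed amplitudes the learning transient
  sweeps the weight ratio through the window and the apex series
  acquires a trend — exactly what the F-test's own preconditions
  exclude. With frozen weights the measure isolates what it is meant to
  measure, the pool-size dependence of the Poisson noise. Serotonin
  stays dynamic.

Convergence-ratio averages use the final 50 s of each run; repeated-trial
protocols run 10 trials, trial 0 from the tabulated initial conditions
and trials 1–9 with initial weights uniform in [0.8, 1.2] and initial
concentrations uniform in [6, 60] nM.

## Numerics

* Explicit Euler for all neural state (traces, conductances, membranes,
  filters, concentrations) at dt = 1 ms (open loop) or 0.1 ms (closed
  loop); serotonin on a 1 ms subgrid (accumulated release, verified
  within 1 % of a uniform fine-grid reference).
* Two-mass plant: semi-implicit (symplectic) Euler at the neural dt.
  Explicit Euler at dt = 0.1 ms gains ~0.8 %/s energy at the anti-phase
  frequency; the symplectic variant keeps the drift bounded below
  0.1 %/s, which the mode-decay analysis requires.
* Leg plant: classical fixed-step RK4 at the neural dt with the motor
  set point held constant across the step (zero-order hold); springs,
  dampers, stops, gravity and contact are evaluated continuously inside
  the step. An adaptive embedded scheme (scipy RK45) is provided for
  offline mechanics runs and agrees with RK4 on drop/first-apex tests
  to < 1 mm.
* Delays are exact integer-step ring buffers (construction fails for
  non-multiple delays).
* All stochasticity flows from one `numpy.random.Generator` per run,
  seeded from the experiment config; recordings are bit-identical for
  identical seed+config. The compiled (numba) inner loops consume the
  same generator.
* Weights are clipped at zero; concentrations are floored at zero;
  Poisson steps reject ν·dt ≥ 1.
* Trace/plasticity update order per step: decay all traces; increment
  presynaptic traces (same-step pre spikes visible to LTP); apply LTD at
  pre spikes, LTP at post spikes (z_slow read before its increment —
  the ε offset); increment postsynaptic traces; apply scaling and clip.
  Verified against an exact event-driven implementation of the rule.

## What the synthetic protocols do and do not show

The generators emulate the study conditions: sinusoidal rate programs
with a minor-mode perturbation and Gaussian rate noise (open loop), and
fully self-generated proprioceptive input in the closed loops. They do
not emulate: muscle-level actuation (joint-level torques only),
receptor-level 5-HT dynamics, spike-transmission jitter beyond Poisson
statistics, or sensory adaptation. Passing tests therefore support the
controller-level claims (principal-component extraction, mode-aligned
excitation, energy-efficiency plateau, noise scaling with pool size) but
say nothing about muscle or receptor physiology.

Known limitations:

* The converged leg ratios depend at the few-percent level on the
  contact/geometry choices above; the acceptance bands (2× the printed
  spreads) absorb this.
* With the neuromodulatory gains frozen at asymmetric values the output
  weighting never converges (the implemented negative control), but the
  two-mass *trajectories* still align near ratio 1, because the
  common-mode force pumps the in-phase mode regardless of the gain
  asymmetry. The stronger narrative claim that unequal output gains
  prevent trajectory alignment is not reproduced by this implementation.
* At compressed amplitudes the closed-loop LIF pools run above their
  homeostatic target during stance (the scaling equilibrium shifts with
  A·τ_s); rates, unlike ratios, should not be read quantitatively from
  the desk-scale runs.
* The feed-forward fits' intercepts are slightly positive (rectified
  noise floor), as in the source data.
* At the strongest noise level (σ = 1) the synaptic-pathway fit keeps a
  high adjusted R², but the neuromodulatory ratios compress toward 1
  under the rectified noise floor and their fit quality drops; the
  acceptance script reports both.
* The compressed two-mass protocol has roughly twice the trial-to-trial
  ratio spread of the full-length protocol, so the ten-trial mean of the
  synaptic ratio carries a sampling error of the same order as the
  tightest comparison band; repeats with different seed sets can land on
  either side of that band.
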