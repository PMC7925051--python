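# Methods

## Model

`qifmf` studies a two-population network of quadratic integrate-and-fire
(QIF) neurons — one excitatory, one inhibitory population, all-to-all coupled
through conductance synapses with an instantaneous threshold gate — and its
exact mean-field reduction.

Each neuron obeys

    dV/dt = V² + η + I_ext − J_e (V − E_e) S_e(t) − J_i (V − E_i) S_i(t),

where η is a quenched per-neuron background current drawn from a Lorentzian
density g(η) with center η̄ and half-width Δ, I_ext is a common external
drive applied to the excitatory population, and the population gates

    S_k(t) = (1/N_k) Σ_l H(V_l − V_th)

are the instantaneous fractions of each population above the gating
threshold V_th. A neuron reaching V_peak emits a spike and restarts at
V_reset = −V_peak. The idealized model sends both cutoffs to infinity; the
simulator uses V_peak = 100, which biases single-neuron inter-spike
intervals by ≈ 2/V_peak (≈ 2%, see "Numerical choices").

### Exact reduction

Because the single-neuron flow is quadratic in V (a Riccati flow), the
Lorentzian family of voltage densities is invariant: a density with pole
V₀ = y − ix evolves by the analytically continued vector field,
dV₀/dt = V₀² + B V₀ + C with

    B = −(J_e S_e + J_i S_i),
    C = η + I_ext + J_e E_e S_e + J_i E_i S_i.

Integrating over the Lorentzian g(η) by residues (pole η = η̄ − iΔ) and
identifying the half-width with x = πr and the center with the mean voltage
y = v gives the closed four-dimensional system for
(r_e, v_e, r_i, v_i):

    dr_k/dt = Δ/π + 2 r_k v_k − r_k (J_e S_e + J_i S_i)
    dv_e/dt = η̄ + v_e² − π² r_e² − J_e (v_e−E_e) S_e − J_i (v_e−E_i) S_i + I_ext
    dv_i/dt = η̄ + v_i² − π² r_i² − J_e (v_i−E_e) S_e − J_i (v_i−E_i) S_i

with the gate evaluated at the pole,

    S_k = (1/π) · arg((V_th − v_k) + iπ r_k)
        = 1/2 − (1/π) arctan((V_th − v_k)/(π r_k)).

Two truncated variants are selectable on `ModelParams` for sensitivity
checks and comparison with other published forms of these equations:
`gate_convention="narrow"` gates on half-width r instead of πr, and
`rate_coupling="self"` keeps only the population's own conductance term in
its rate equation. The defaults are the exact reduction; the truncated
variants demonstrably lose central features of the dynamics (the `"narrow"`
gate destroys the bistability at (I_ext, J_e) = (−3, 32) entirely), so every
analysis and test in this package runs the exact form.

At r = 0 the gate is defined by its one-sided limit (0 below threshold, 1
above, ½ at threshold), making the vector field well defined on the closed
half-space r ≥ 0; since dr/dt = Δ/π > 0 on r = 0, rates remain positive.

### Default constants

J_e = 15, J_i = 8, E_e = 75, E_i = −75, η̄ = −5, Δ = 1, V_th = 50 (all
dimensionless). The model has a single time unit; we follow the habit of
labeling rates "Hz" and times "s" in plots, treating one model time unit as
one second. Only J_e and I_ext are varied in the analyses.

## Dynamical repertoire

On the (I_ext, J_e) plane the model exhibits, and the test suite pins:

* **Quiescence** — a low-rate stable equilibrium (e.g. (0, 15),
  r_e ≈ 0.077).
* **Synchronization** — limit cycles with pronounced rate spikes (e.g.
  (8, 15), the step-protocol experiment).
* **Steady high-rate focus** — e.g. reached at (−3, 32) after a transient
  pulse; settles to r_e ≈ 3.38.
* **Bistability** — the quiescent state coexists with the focus (region
  around (−3, 32)) or with limit cycles (larger J_e at negative I_ext); a
  brief pulse to I_ext = +3 switches between basins. For the focus case
  the landing basin depends on the pulse release phase (the focus rotates
  at ≈ 21.6 rad/unit and is weakly damped): a 1-unit pulse at (−3, 32)
  switches, while a 2-unit pulse happens to fall back.
* **Period-doubling cascade to chaos** along I_ext = −3: period-1 up to
  J_e ≈ 54.8 (PD1, located by a Floquet multiplier crossing −1), period-2 up
  to ≈ 62.3 (PD2), then period-4/8 and chaos (positive largest Lyapunov
  exponent by J_e ≈ 64).

The corresponding two-parameter skeleton is traced by `analysis`:
a fold curve f entering at the left edge near J_e ≈ 24, running to a cusp
near (3.9, 6), and leaving through the top edge near I_ext ≈ −4.1; a Hopf
curve h1 bounding the low-coupling oscillatory tongue, from the bottom edge
near I_ext ≈ 7 to a Bogdanov–Takens point on f near (2.7, 8.9); a second
Hopf curve h2 crossing the whole window near J_e ≈ 41–44 (loss of stability
of the high-rate focus); and the two period-doubling curves PD1, PD2 rising
from the left edge across the window to the top edge near I_ext ≈ −0.7.

## Algorithms

* **Mean-field integration**: classical fixed-step RK4, dt = 0.01 by
  default. Analyses that resolve the cascade (attractor classification,
  period-doubling location, Lyapunov exponents) use dt = 10⁻³: the rate
  spikes reach r_e ≈ 20–60 and a 0.01 step under-resolves them.
* **Network integration**: explicit Euler with dt = 10⁻³ (a Runge–Kutta
  stage has no meaning across the discontinuous reset), gates from the
  pre-step state, immediate reset without refractoriness. Heterogeneity is
  assigned by deterministic Lorentzian quantiles by default (i.i.d.
  sampling behind `het_mode="sample"`), which removes sampling noise from
  the finite-size comparison against the mean-field limit.
* **Equilibria**: multistart quasi-Newton (Powell hybrid, analytic
  Jacobian available) from a scrambled Sobol grid over
  r ∈ [0, 20]², v ∈ [−80, 80]²; roots deduplicated at 10⁻⁶ in a metric
  with rates scaled ×10; every root re-verified to residual < 10⁻⁹ and
  classified from Jacobian eigenvalues with hyperbolicity tolerance 10⁻⁶.
* **Branch continuation**: pseudo-arclength predictor–corrector; fold test
  function det J, Hopf test the product of pairwise eigenvalue sums,
  candidates screened for a genuine complex pair; special points localized
  by bisection along the branch.
* **Codim-2 curves**: folds by the Moore–Spence augmented system (state +
  null vector + normalization), Hopf curves by the augmented system with
  the real/imaginary eigenvector parts and frequency ω as unknowns; both
  continued by pseudo-arclength with finite-difference tangents. Hopf
  tracing stops when |ω| < 0.05 and the endpoint is snapped onto the fold
  curve: at a Bogdanov–Takens point ω → 0 and the augmented system
  degenerates toward the fold system, so continuing further duplicates
  the fold curve with noisy tangential crossings.
* **Limit cycles**: single shooting on (initial state, period) with the
  monodromy matrix integrated from the variational equations (RK4); phase
  anchored in the slow inter-spike segment of the orbit — anchoring on the
  spike makes the Newton matrix wildly ill-conditioned. Damped Newton with
  a period guard (0.4–2.5× the guess) avoids the degenerate T → 0 root;
  non-convergence raises instead of returning a pseudo-solution. The
  trivial multiplier's deviation from 1 is reported as an accuracy check
  (typically < 10⁻⁸).
* **PD1** is located per I_ext slice by walking the period-1 cycle in J_e
  (bounded steps, re-shooting) and bisecting the real Floquet multiplier
  through −1 to 10⁻³.
* **PD2** is located by bisection on the attractor's period class
  (2 vs > 2), to 0.05 in J_e, with the on-branch state carried between
  neighbouring slices. Rationale: past PD2 the period-2 orbit is deeply
  unstable with coexisting nearby orbits, and shooting from slice seeds
  intermittently converges onto neighbouring branches; the classification
  boundary is robust and coincides with the multiplier crossing where the
  doubling is supercritical. At the most negative drives the stable
  period-2 window ends in a crisis (no stable period-4 follows); there the
  traced "PD2" point is the upper boundary of the period-2 regime, the
  natural continuation of the curve at the resolution of the diagram.
* **Period classification**: r_e peaks (quadratic sub-grid refinement)
  after discarding a transient; smallest n ≤ 16 for which peak amplitudes
  and inter-peak intervals are n-periodic within 2% (0.5% in cascade
  bisections, where the early splitting is small); otherwise "chaotic",
  corroborated by a positive Benettin exponent where both are computed.
* **Lyapunov exponent**: two-trajectory Benettin method, renormalization
  every 1 time unit, offset 10⁻⁷, seeded perturbation direction. For the
  weakly contracting focus (leading Re λ ≈ −0.024 at (5, 30)) the
  trajectory must start in the focus basin — a stable limit cycle coexists
  there, and a quiescent start lands on it.
* **Region counting**: the curve polylines plus the window boundary are
  noded and polygonized exactly; faces with area below 0.01 parameter
  units² are discarded (polyline-noise slivers where curves meet
  tangentially, an order of magnitude below the smallest genuine region,
  which has area ≈ 0.11). The count is verified robust with the area
  floor varied 4× in both directions. A rasterized companion (n×n cell
  barriers, 4-connected flood fill) provides the labeled mask and a
  cross-check at the scales the grid resolves; pure raster counting is
  not used for the final count because the small region at the fold cusp
  fragments against the thickened barriers as the grid is refined.

## What the synthetic protocols emulate

There is no external data; the `protocols` module plays the role of the
data generator. `figure1_protocol` is the quiescence-to-synchronization
step (I_ext 0 → 8 at t = 2); `bistability_protocol` holds the base drive,
pulses I_ext = +3 higher on t ∈ [10, 12), and observes to t = 25;
`fixture_signal` generates sinusoids, alternating-amplitude and 4-motif
peak trains, and Poisson rasters with known ground truth for the
classifier and rate-estimator tests. The catalogue in `paper_points`
pins the study's named parameter points with the regime the model
exhibits there, verified by tests — a mismatch is a test failure, not a
relabel.

What passing tests do *not* show about real neural data: the network is
all-to-all, noiseless apart from quenched heterogeneity, with
instantaneous synapses; finite-size fluctuations, synaptic kinetics,
sparse topology and measurement noise are all outside the model class.

## Numerical choices and known limitations

* Finite cutoffs V_peak = −V_reset = 500. The cutoff must sit far above
  the gating threshold: the gate counts neurons during the spike flight
  through (V_th, V_peak) and loses a fraction ≈ V_th/V_peak of the ideal
  above-threshold time, which at V_peak = 100 lengthens collective
  oscillation periods by ~15% (at 500 the residual bias is below 1%). The
  closed-form ISI (arctan(V_peak/√I) − arctan(V_reset/√I))/√I is the
  oracle for the uncoupled neuron (1% tolerance at dt = 10⁻³).
* Network/mean-field agreement is tested at N = 1000–2000 per population
  (quiescent mean rates within 15%, synchronized oscillation periods
  within 10%, stationary voltage density Lorentzian with center v and
  half-width πr to sup-distance < 0.1 after trimming the spike flight);
  N = 20000 runs are supported but not exercised by the test suite.
* The mean-field rate equations printed in some accounts of this model
  omit the cross-population conductance damping and the π on the gate
  half-width; those truncations are implemented as the `"self"` /
  `"narrow"` variants. They are not used for analysis: the truncated
  system is monostable where the network is bistable.
* Near-degenerate points (Bogdanov–Takens, cycle folds, the cascade
  accumulation) are handled by truncation and robust fallbacks as
  described, not by normal-form computation; sub/supercritical character
  is inferred from nearby attractor simulation.
* Region counts are reported for the window I_ext ∈ [−6, 10],
  J_e ∈ [5, 80] at the stated raster resolution; regions thinner than a
  raster cell (slivers between near-tangent curves) are below the
  diagram's resolution by construction.
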