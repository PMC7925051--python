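# qifmf

Exact mean-field reduction and bifurcation analysis of a two-population
spiking network of quadratic integrate-and-fire (QIF) neurons.

## The problem

Large networks of spiking neurons are hard to analyze directly: the state
space has one voltage per neuron. For QIF neurons with Lorentzian-distributed
background currents and instantaneous conductance synapses, the
population density closes exactly — in the infinite-size limit each
population is described by just its firing rate r and mean membrane
potential v. This package implements both levels:

* the **spiking network**: N excitatory + N inhibitory QIF neurons,

      dV/dt = V² + η + I_ext − J_e (V−E_e) S_e − J_i (V−E_i) S_i,

  with gates S_k = (1/N) Σ H(V_l − V_th), quenched Lorentzian heterogeneity
  η ~ g(η; η̄, Δ), spike at V_peak, reset at −V_peak;

* the **exact mean-field reduction**, a 4-D ODE system for
  (r_e, v_e, r_i, v_i):

      dr_k/dt = Δ/π + 2 r_k v_k − r_k (J_e S_e + J_i S_i)
      dv_e/dt = η̄ + v_e² − π²r_e² − J_e(v_e−E_e)S_e − J_i(v_e−E_i)S_i + I_ext
      dv_i/dt = η̄ + v_i² − π²r_i² − J_e(v_i−E_e)S_e − J_i(v_i−E_i)S_i

  with S_k = ½ − arctan((V_th − v_k)/(π r_k))/π;

* the **analysis layers**: equilibrium location and classification,
  pseudo-arclength continuation with fold/Hopf detection, codim-2 curve
  tracing in the (I_ext, J_e) plane, limit-cycle shooting with Floquet
  multipliers, period-doubling detection, inter-spike-interval bifurcation
  sweeps, and largest-Lyapunov-exponent chaos diagnostics.

The interesting biology lives in the dynamical repertoire: quiescence,
synchronized oscillations (period-1/2/4), a steady high-rate state,
bistability that a transient stimulus can switch (a working-memory motif),
and a period-doubling route to chaos. See `docs/methods.md` for the
derivation, algorithms, and numerical conventions.

## Worked example: bistability and switching

```python
import numpy as np
from qifmf import ModelParams, StimulusProtocol, integrate
from qifmf.equilibria import find_equilibria

params = ModelParams(J_e=32.0)           # other constants at defaults

# 1. all equilibria at I_ext = -3
eqs = find_equilibria(params, I_ext=-3.0, n_starts=1024, seed=0)
for e in eqs:
    print(f"{e.classification:13s} r_e={e.state.r_e:7.4f} v_e={e.state.v_e:7.3f}")

# 2. start quiescent, pulse I_ext: -3 -> +3 on t in [10, 11) -> -3
proto = StimulusProtocol.from_steps([-3.0, 3.0, -3.0], [10.0, 11.0], 30.0)
traj = integrate(eqs[0].state, proto, 0.002, params)
tail = traj.window(25.0, 30.0)
print(f"pre-pulse rate  r_e = {eqs[0].state.r_e:.4f}")
print(f"post-pulse rate r_e = {tail.r_e.mean():.4f}")
```

prints

```
stable focus   r_e= 0.0642 v_e= -2.451
saddle         r_e= 0.3504 v_e= -0.292
stable focus   r_e= 3.3769 v_e=  1.322
pre-pulse rate  r_e = 0.0642
post-pulse rate r_e = 3.3716
```

Two stable states coexist at (I_ext, J_e) = (−3, 32): a quiescent state at
r_e ≈ 0.06 (a weakly oscillatory near-node) and a high-rate focus at
r_e ≈ 3.38, separated by a saddle. The brief pulse switches the population
from the quiescent basin onto the focus, where it stays after the stimulus
is gone — transient input, persistent activity. (The focus rotates fast
and is weakly damped, so whether a given pulse lands in its basin depends
on the release phase; a 1-unit pulse does, see `docs/methods.md`.)

The same repertoire from the shell:

```
qifmf equilibria --Iext -3 --Je 32 --out out/eq
qifmf simulate-network --Ne 1000 --Ni 1000 --protocol fig1 --out out/net
qifmf sweep --Iext -3 --Je-min 48 --Je-max 66 --Je-steps 37 --out out/cascade
qifmf codim2 --out out/scenario        # traces f, h1, h2, PD1, PD2; counts regions
```

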