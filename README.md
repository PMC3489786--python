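# actonet

Brownian-dynamics simulation of active, cross-linked actin networks
coupled to an elastic substrate — a computational testbed for actomyosin
rigidity sensing.

Cells adapt their contractile behaviour to the stiffness of what they are
attached to.  `actonet` models the minimal machinery behind one proposed
mechanism: a 3-D network of semiflexible actin filaments, passive
cross-linkers (ACPs) and myosin-minifilament motors, clamped inside a
cubical domain whose walls yield like an elastic substrate of Young's
modulus *E*.  Motors walk toward filament barbed ends at a load-dependent
rate and stall either by reaching their stall force (~4 pN), by finding
the next binding site occupied (blocking), or by arriving at a barbed
end.  Which of these dominates depends on *E*, and the wall stress the
network can build inherits that dependence.

The model, in brief:

* overdamped Langevin dynamics, explicit Euler, thermal forces obeying
  the fluctuation–dissipation theorem (`x += (F + F^B) dt / zeta`);
* quadratic potentials: extension on every bond, bending at filament and
  linker hinges, excluded volume between actin segments closer than their
  diameter;
* stochastic kinetics: motor stepping at
  `k_w(F) = 1/(d1 e^{l1 F} + d2 e^{l2 F})` for resisting loads,
  Bell-law unbinding `k_u = k0 e^{lambda F/kBT}`, and second-order
  (re)binding from implicit monomer pools;
* elastic boundary: each face is displaced by a strain `sigma/E`, where
  `sigma` is the normal stress its clamped filaments exert on it.

See `docs/methods.md` for the full model description, parameter table
rationale and numerical choices.

## Worked example

```python
from actonet import (reference_parameters, make_mini_network,
                     run_contraction, summarize, stall_census, stall_force)

p = reference_parameters()
print(f"stall force of the walking law: {stall_force(p):.2f} pN")

# a desk-scale network: 30 filaments (<L_f> = 2 um) in a 1.5-um box
net = make_mini_network(30, 1.5, R_ACP=0.01, R_M=0.02, seed=1)
for E in (100.0, 10000.0):
    pp = p.replace(E=E)
    st = net.copy()
    st.domain.E = E
    series = run_contraction(st, pp, horizon_s=20.0, seed=7)
    m = summarize(series, pp)
    c = stall_census(series.final_state, pp)
    print(f"E = {E:>7.0f} Pa   sigma_p = {m.sigma_p_Pa:6.2f} Pa   "
          f"eps_p = {m.eps_p:7.4f}   blocked = {c.blocked:.2f}")
```

prints (a few minutes of runtime):

```
stall force of the walking law: 3.99 pN
E =     100 Pa   sigma_p =   0.50 Pa   eps_p =  0.0050   blocked = 0.08
E =   10000 Pa   sigma_p =   2.68 Pa   eps_p =  0.0003   blocked = 0.09
```

The stall force is the load at which the motor stepping rate drops below
1 % of its unloaded value.  `sigma_p` is the "plateau" wall stress at the
run horizon and `eps_p` the domain contraction strain: on the soft
substrate the network contracts (strain 0.5 %, exactly `sigma/E`) and
builds little stress; on the 100x stiffer substrate it barely moves and
builds ~5x more stress — the rigidity-sensing signature at reduced
scale.  `blocked` is the fraction of motors stalled because their next
binding site is occupied.

## Command line

```bash
actonet assemble config.yaml -o network.snap     # periodic steady-state net
actonet run config.yaml -o out/                  # sever, clamp, contract
actonet probe out/final.snap                     # oscillatory stiffness E_n
actonet sweep sweep.yaml -o sweep_out/           # grid over E, R_M, ...
actonet analyze out/series.csv                   # summary metrics table
```

Configs are YAML mappings of `ParameterSet` fields plus `seed`,
`horizon_s`, `n_filaments`, `grid`, `seeds`.  Every run directory gets a
manifest with the fully resolved parameters; identical config + seed
reproduces a run bit-exactly.  Snapshots are a documented columnar text
format (plus VTK polydata export); time series are CSV, metrics JSON.

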