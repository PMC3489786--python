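# Model and methods

`actonet` simulates an active, cross-linked actin network inside a cubical
domain whose walls behave as an elastic substrate, to study how actomyosin
contractility senses substrate rigidity.  This note documents the model,
its parameters, the numerical choices, and what the reduced-scale test
conditions do and do not establish.

## The model

**Components.**  Actin filaments are bead–rod chains of cylindrical
segments (rest length `r0_A` = 140 nm, diameter `r_c` = 7 nm) with distinct
barbed and pointed ends.  Passive actin cross-linking proteins (ACPs) and
myosin-minifilament motors are two-armed linkers: each arm is a Hookean
spring from a backbone point to a filament node, the two backbone points
being joined by a stiff backbone bond.  Binding sites are filament nodes
(one arm per node).  Linkers are monomeric (free, kept as implicit
per-voxel concentration pools), inactive (one arm bound) or active (both
arms bound, to two distinct filaments).

**Mechanics.**  The potential is quadratic throughout: extension
`U_s = 1/2 kappa_s (r - r0)^2` on every bond; bending
`U_b = 1/2 kappa_b (theta - theta0)^2` at filament hinges (`theta0 = pi`),
between the two arms of a linker (`theta0 = 0`, parallel arms) and between
an arm and the local filament axis (`theta0 = pi/2`); and an
excluded-volume term `U_r = 1/2 kappa_r (r12 - r_c)^2` whenever the minimum
distance `r12` between two actin segments falls below `r_c`, distributed to
the four segment endpoints by the lever rule.  Forces are the exact
analytic gradients (verified against central-difference gradients to 1e-6
relative in the test suite).

**Dynamics.**  Motion is overdamped Langevin dynamics integrated with the
explicit Euler scheme, `x += (F + F^B) dt / zeta`, with isotropic per-node
drag `zeta = 3 pi mu r0_A` and a thermal force `F^B` satisfying the
fluctuation–dissipation theorem (per-component variance
`2 kBT zeta / dt`).  Inertia is dropped.  The API-level thermal force is
Gaussian; the fused integration kernel uses uniform variates with matched
variance (the variance is the physical contract).

**Motor stepping.**  An arm of an active motor steps one node toward the
barbed end at the load-dependent rate

    k_w(F_par) = 1 / (d_w1 exp(lambda_w1 F_par) + d_w2 exp(lambda_w2 F_par))

for resisting loads `F_par > 0` (arm tension projected on the filament
tangent toward the pointed end) and `k_w(0)` otherwise.  With the reference
parameters (`d_w1` = 0.04 s, `d_w2` = 0.005 s, `lambda_w1` = 0.1 /pN,
`lambda_w2` = 1.7 /pN) the unloaded rate is ~22 steps/s and the rate falls
below 1 % of it at ~4.0 pN — the stall force.  A step onto an occupied
node is refused (blocking); an arm on the barbed-end node stays until it
unbinds.  Both arms of a motor step independently, so two antiparallel
filaments bridged by one unloaded motor slide at `2 r0_A k_w(0)`.

**Unbinding and binding.**  All attached arms unbind by Bell's law
`k_u = k0_u exp(lambda_u F / kBT)` on the arm tension.  Free linkers bind
by a second-order reaction `k_bind [free][available sites]` per voxel
(3x3x3 pools, fully redistributed each chemistry step — the
fast-diffusion limit).  An inactive linker attaches its second arm to an
unoccupied node of a different filament within reach
`max(2 r0 (1 + tol), r0_A)` at the local second-order rate
`k_bind x (candidates in reach) / V_reach`; the reach floor of one
segment length reflects that the nearest *nodes* of two crossing filaments
straddle the crossing by up to a segment.  Arms are placed at rest and the
backbone bond is born at its binding span, so binding injects no force.

**Boundaries.**  Assembly uses periodic boundaries.  Before a measurement
run, filaments crossing a face are severed at the plane and the cut ends
permanently clamped there (severed sliver bonds are born unstressed at
their cut length); periodicity is then off.  During a run the faces are
sticky (any free filament end within 30 nm is irreversibly clamped, with
the terminal bond re-rested so capture injects no tension) and elastic:
the normal stress on a face (sum of inward normal anchor forces / area,
contractile positive) displaces it by a strain `sigma/E` referenced to
`W0/2`, so the domain axis strain tracks `sigma/E` exactly at steady
state.  Both faces of an axis move symmetrically.

**Stiffness probe.**  With all binding/unbinding/walking frozen, the two
faces of one axis are driven sinusoidally (differential displacement
amplitude 280 nm at full scale; 0.5 Hz, 3 cycles, fit on the last 2) and
`E_n` = stress amplitude / strain amplitude; the phase delay is reported
and small (elastic response).

## Parameters

Printed reference values: `C_A` = 12 uM, `R_ACP` = 0.01, `R_M` = 0.02
(molar ratios to actin monomers; entity counts are `R x N_monomers` with
~52 monomers per 140-nm segment), `<L_f>` = 2 um, `W0` = 5 um, arm spans
2x35 nm (ACP) and 2x70 nm (motor), T = 300 K, stall force ~4 pN.

The remaining constants are this package's own reconstructions, set from
physical arguments and frozen (each is tagged in `params.py`):

* `kappa_s_A` = 2.5e-3 N/m and `kappa_r` = 2e-3 N/m.  Filament stretch at
  the multi-motor force scale stays ~1 % of a segment, while the softer
  springs quadruple the admissible time step (the source framework applies
  the same reasoning).
* `kappa_s_M` = 1e-4 N/m.  The arm compliance sets the tension gained per
  140-nm step: ~7 pN against a stiff anchor, so an anchored motor reaches
  stall within 1–2 steps.  With much softer arms a motor in a reduced
  network can never reach stall within one filament length; with much
  stiffer arms a single step overshoots by tens of pN.  The linker
  backbone bond is rigid relative to the arms (minifilament body).
* `kappa_b_A` = 2.66e-19 N m (persistence length 9 um at 300 K);
  linker hinge stiffnesses ~10–25 kBT/rad^2.
* Unbinding/binding: `k0_u_ACP` = 0.06 1/s, `k0_u_M` = 0.25 1/s,
  `lambda_u_ACP` = 0.17 nm, `lambda_u_M` = 0.4 nm,
  `k_bind` = 2 /(uM s), capture tolerance 0.5.  Linkers outnumber binding
  sites ~1.6-fold at the reference composition, so these equilibria set
  the site occupancy (~50–70 %): high enough that blocking is the dominant
  stall cause (as in the source study), low enough that motors can still
  walk and load, and strong enough that the ACP scaffold percolates.
* `mu` = 3.44 Pa s (an effective cytoplasmic viscosity ~4000x water) and
  `dt` = 1.5e-4 s, safety factor ~0.08 against the overdamped stability
  bound `zeta/kappa_max`.  Raising `mu` rescales time only; the motor
  stepping and chemistry are quasi-static with respect to the mechanics.

Kinetic events are evaluated every `n_kinetic` = 10 integration steps
(event probability per window < 0.04); slow chemistry (binding, zero-force
unbinding of inactive linkers) every 10 ms; within a window unbinding is
evaluated before walking, and firing events are processed in a seeded
random permutation to avoid site-contention bias.

## Numerical choices

* **Instability detection.**  The deterministic per-step displacement is
  monitored; the single-step API flags `> 0.1 r_c`, production runs flag
  `> 2 r_c = 0.1 r0_A`.  A steady multi-motor tension chain (>100 pN) is
  overdamped drift, not instability — stability depends on
  `kappa dt / zeta` (margin ~12x), not on force magnitude.
* **Wall-stress smoothing.**  Instantaneous anchor forces carry
  `sqrt(kBT kappa)`-scale thermal noise; the face targets use an
  exponentially smoothed stress (time constant 0.2 s, much shorter than
  the contraction timescale), with per-window face motion capped at
  1 % of `W0`.  Raw and smoothed stresses are both recorded.
* **Hinges on sliver bonds** (severing remnants < 30 nm) carry no torque:
  a quadratic angle term over a nm-scale lever arm produces unphysical
  forces.
* **Inactive linkers have no mechanical beads.**  A singly-bound linker
  transmits no force; it is occupancy bookkeeping plus stored resting
  geometry until its second arm binds.  This halves the integrated degrees
  of freedom.
* **Excluded-volume pair list**: cell-list candidate search with a Verlet
  skin of 3 `r_c`, refreshed when any bead has moved half a skin.
* **Degenerate geometry tie-breaks**: coincident closest points of two
  segments repel along +x; hinge angles at exactly 0/pi use a clamped
  sine.  Zero-length bonds with finite rest length are an error.
* The Hill fit uses the product form `(sigma0 + a)(eps_dot0 + b) = c`
  (the only form consistent with the constants' units Pa, 1/s, Pa/s),
  fitted by Levenberg–Marquardt in log-parameters from a deterministic
  linearized initialization.

## Synthetic data and reduced-scale conditions

The assembly module is a geometric/kinetic-Monte-Carlo constructor, not a
polymerization simulation: filament segment counts are geometric
(nucleation–elongation steady state) with mean `L_f_mean / r0_A`; chains
grow as discrete worm-like chains; linkers bind/unbind on the frozen
geometry until their active fractions are steady (< 2 % change between
sliding windows); residual G-actin is deleted.  The constructor
reproduces composition and large-scale geometry, not the kinetics of
polymerization; it also leaves excluded-volume contacts (random
placement), so a passive zero-motor network carries a Pa-scale *static*
prestress.

The desk-scale study conditions are a mini network: 30 filaments of mean
length 2 um in a 1.5-um box (reproducing `C_A` ~ 11 uM), 20-s horizon,
5 seeds, substrate moduli {10, 100, 1000, 10000} Pa.  The E grid is
shifted ~100x below the full-scale study's because the mini wall stress is
~100x smaller, preserving the dimensionless regimes `sigma_p/E` from
soft (strain ~10 %) to rigid (strain -> 0).  Full-scale, 200-s runs of the
5-um reference network are outside the desk budget and are treated as
cluster-scale work.

What the reduced scale shows: the monotone rise of plateau stress and the
fall of contraction strain with substrate stiffness, the stall-force
physics, and the filament-length dependence of the stall census.  What it
cannot show: (i) the *saturation* of plateau stress at high `E` — mini
wall stress is a few motors' worth, far below the stall-force-limited
ceiling that makes the full-scale curve level off, so sigma_p keeps
creeping upward across the whole reduced grid; (ii) the tracking of
network stiffness `E_n` with plateau stress — in a 1.5-um box with a 9-um
persistence length, box-spanning filaments are nearly straight, so `E_n`
is dominated by their passive axial stiffness (~kPa) while prestress
contributes ~Pa; the full-scale tracking requires thermal slack in long
wavy paths; and (iii) a clean census shift from blocking to force stall
with `E` — at reference composition the baseline site occupancy makes
blocking dominate walk attempts at every `E`, and the additional
densification-driven blocking at soft substrates is small at 20-s,
1.5-um scale.  The corresponding acceptance tests assert the full-scale
directions as stated and are left failing where the reduced scale cannot
express them.

## Known limitations

* One binding site per node and one myosin head per motor arm (the source
  model shares both; refining them changes the blocking statistics).
* No hydrodynamic interactions, no slender-body (anisotropic) drag, no
  viscoelastic substrate, no filament turnover during measurement.
* The stall census classifies a motor by its most advanced arm with
  precedence barbed > force > blocked; inactive motors count as not
  stalled; fractions are over bound motors.
* At very soft substrates (E below ~10 Pa at mini scale) the wall-stress
  noise corresponds to strain excursions that the quasi-static face update
  cannot meaningfully follow.
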