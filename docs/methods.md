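# Methods

## Model

### Reaction network

The homogeneous clock tracks nine concentrations: free cyclin B `B`; the
four phospho-forms of the cyclin B–Cdk1 complex (`C00` unphosphorylated,
`CY` Tyr-15-phosphorylated, `CT` Thr-phosphorylated = active Cdk1, `CYT`
doubly phosphorylated, inactive); and the active fractions of the four
regulators Cdc25, Wee1, Plx1 and APC.  Rate laws:

* cyclin synthesis at `ks` (nM/min); pseudo-first-order Cdk1 binding
  `k_bind` (free Cdk1 treated as in excess) with slow dissociation;
* Tyr-15 phosphorylation at `k_wee1_basal + k_wee1_act · wee1_active` and
  dephosphorylation at `k_cdc25_basal + k_cdc25_act · cdc25_active`,
  acting identically on the Thr-unphosphorylated and Thr-phosphorylated
  complexes;
* Thr phosphorylation by CAK at `k_cak`, reversal at `k_pp`;
* destruction of every cyclin-containing species at
  `kdest · apc_active`;
* regulator activation driven by active Cdk1 (Cdc25, Plx1) or by active
  Plx1 (APC) through Hill functions `x^n / (K^n + x^n)`, and first-order
  reversion to the resting form.  The resting form of Cdc25, Plx1 and APC
  is inactive; the resting form of Wee1 is **active** (interphase Tyr-15
  kinase activity requires it), so Cdk1 *inactivates* Wee1 and Wee1
  relaxes back to its active pool.

Units are nM and minutes; regulator pools are normalized fractions.
Because every threshold used by the triggers and diagnostics is defined
relative to the model's own limit-cycle extrema, absolute concentration
units never enter any result.

### Parameter provenance and calibration

The published source for the full equation set of this oscillator family
is not recoverable at numeric precision, so the constants shipped in
`data/xenopus_calibrated.yaml` are a calibrated set, fixed once against
the well-established observables of the system and then frozen:

1. free-running period `T = 39.2 min` (sets `ks = 4.153 nM/min`);
2. `T ∝ 1/ks`: doubling `ks` halves `T` within ~7%, and `T(ks)` is
   monotone over at least a 4-fold range (this requires fast relaxation
   of the negative-feedback arm after each spike; `kapc_off = 0.8/min`,
   `kc25_off = 0.3/min`, `kwee_on = 0.4/min`, `kplx_off = 0.3/min`);
3. relaxation character: active Cdk1 spends < 5% of the cycle above half
   its range;
4. a CSF-arrested steady state whose active-Cdk1 level lies far below a
   quarter of the mitotic peak, so the 4× spreading trigger is meaningful
   (peak/arrest ≈ 170 with the shipped set);
5. sustained oscillation down to `T ≈ 10 min` by raising `ks` alone
   (the short-period, fly-like regime; `tune_ks_for_period` finds
   `ks ≈ 20.4`).

Hill midpoints and coefficients (sharp Cdc25 response `n = 11`, softer
Wee1 response `n = 3.5`) are in the range reported for this oscillator;
midpoints were scaled to the calibrated cyclin scale.  The YAML file is
the single source of truth; nothing in the code hard-codes a constant.

### CSF arrest and the calcium-wave gate

CSF blocks the negative feedback at the APC.  We implement the wave /
CSF modification by multiplying the **entire** rate equation of
`apc_active` by the gate indicator: ahead of the front (gate 0) APC is
frozen at its current value, behind it (gate 1) the full kinetics apply.
The pre-fertilization state is obtained by integrating the gated system
from the metaphase point of the limit cycle (peak of active Cdk1, where
APC is still at its small lagging value ≈ 0.16) to steady state
(residual < 1e-8).  Destruction at the frozen APC level then balances
synthesis, yielding a genuine low-Cdk1 arrested state.

The alternative — zeroing only the APC *activation* flux while letting
APC decay — is provably inconsistent with the rest of the model: APC and
hence destruction vanish, cyclin accumulation is unbounded unless an
ad-hoc basal turnover is added, and any steady state reachable from
metaphase then lies on the high-Cdk1 branch, from which the documented
4× active-Cdk1 trigger could never be exceeded by an oscillation whose
single-cycle cyclin accumulation is necessarily smaller than the
arrested asymptote.  Freezing the APC equation is the minimal reading
that makes the arrested state, the wave gate and the spreading trigger
mutually consistent.

One consequence: the arrested state depends on the phase at which the
freeze is applied (freezing well before metaphase freezes a near-zero
APC, and no steady state exists).  The package therefore defines the
arrest by the documented procedure — freeze exactly at the metaphase
point — and tests reproducibility of that procedure rather than
phase-independence.

### Triggers

* **Calcium wave**: planar front through the fertilization point,
  `gate = 1` iff the projected axial distance satisfies `x ≤ v·t`
  (inclusive).  The gate is sampled at the start of each time step; at
  default numerics the front moves less than one grid cell per step.
* **Diffusive spread**: a monotone per-node latch set where active Cdk1
  reaches `threshold_factor` (default 4) times its arrested value, or
  inside the initially active region (default: the terminal 10% of the
  domain).  Latched nodes run full kinetics; unlatched nodes stay gated.
* `instantaneous` is the fast-wave limit; with a whole-domain initial
  region the two triggers are bitwise identical (tested).

## Numerics

* **Homogeneous runs**: adaptive Dormand–Prince 4(5) (`solve_ivp`),
  default `rtol 1e-8`, `atol 1e-10`; burn-in 10 cycles; the period is
  the mean interval between upward half-maximum crossings of `CYT` over
  ≥ 5 cycles (linear interpolation between samples).  Damped dynamics
  are reported as "no limit cycle", not raised.
* **1D solver**: uniform grid (default `dx = 10 µm`), no-flux
  (finite-volume half-cells at the ends) or periodic.  Crank–Nicolson
  diffusion is coupled to the reaction by Strang splitting (half
  diffusion, full fixed-step RK4 reaction, half diffusion); FTCS is the
  classical simultaneous explicit update and refuses to start if
  `dt > dx²/2D`.  The trapezoid-weighted total of each species is
  conserved to round-off under pure diffusion (tested at 1e-10/1000
  steps).  Default `dt = 0.1 s`; the scaled protocols use 1–2.5 s,
  guarded by the refinement-convergence tests (halving `dt` or `dx`
  moves division times < 1%).
* **3D solver**: P1 finite elements with row-sum (lumped) mass, one
  region per cell compartment, so exterior and internal division
  boundaries are no-flux by construction.  Axisymmetric meshes
  triangulate the half-section and weight elements by `2π r̄`
  (stiffness exact for P1; lumped mass uses the exact
  `2πA(2rᵢ+rⱼ+rₖ)/12` row sums); the discretization reproduces the
  slowest Neumann eigenvalue of the unit ball to 0.01%.  Tetrahedral
  balls combine a symmetric interior lattice with a latitude/longitude
  surface shell (Delaunay, three rounds of neighbor-mean smoothing of
  interior points; negligible-volume surface slivers dropped).  The CN
  half-step systems are solved by sparse LU, factorized once per
  compartment topology — a direct solve trivially satisfies the
  iterative-residual contract the interface specifies.
* **Cellularization**: when a cell's volume-averaged `CYT` crosses the
  homogeneous half-maximum upward (and the cell is armed — it must first
  have been below threshold, and at least half a period old, so one
  cleavage is scored per cycle per lineage), a flat plane is inserted
  through the cell: normal from the orientation policy (default:
  alternating orthogonal axes, first perpendicular to the fertilization
  axis), offset chosen along the normal for equal daughter volumes
  (≤ 1% imbalance or an error advising a finer mesh).  Daughters inherit
  the concentration field as-is; no redistribution.

## Synchrony classification and the critical speed

A run is synchronous iff, over the analysis window, the left- and
right-half mean division counts agree (rounded) and every corresponding
division event lies within 10% of the period across all positions.  The
window is the *settled* part of the run — from
`max(transit time, t_end/2)` (capped at `0.75 t_end`) to `t_end` —
because including the transit phase would make the criterion an artifact
of the 10%-of-T bound rather than a statement about chaos: any entraining
medium would then return a critical transit time of exactly `0.1 T`.

Asynchrony in this model occupies a **band** of wave speeds (very slow
waves can re-synchronize, and there are isolated synchronous "holes"
inside the band), so the critical-speed search first scans a small grid
of slow anchor speeds for an asynchronous probe and then bisects the
upper edge of the band.  If no anchor is asynchronous the domain is
reported as below the minimum chaotic size.

## Canonical protocols (problem sizes)

`cyclewave.protocols` freezes the study conditions used by both the
acceptance script and the acceptance tests: 6-hour classification runs at
`dx = 20 µm`, `dt = 2 s` for the critical-speed searches (1D and
axisymmetric prolate); the 8-hour fast-wave synchrony run; the 6 mm
periodic chaotic run (600 min, `dx = 10 µm`, analysis window 200–600 min,
1/e correlation-length convention); and the cellularized tetrahedral
embryo (70 µm spacing, `dt = 2.5 s`, 320 min).  The slow wave for the
cellularization protocol is 0.02 mm/min — slow relative to *this model's*
critical speed (≈ 0.07 mm/min for the 1 mm embryo) in roughly the same
proportion as the classic slow-wave protocol is to its own critical
speed.  All protocol sizes sit inside the refinement-convergence guards.

## Synthetic fixtures

The diagnostics are validated independently of the solver on generated
fields with closed-form structure: a traveling plane wave (correlation
surface exactly `cos(kδx − ωδt)`), a spectrally synthesized Gaussian
field with exponential spatial correlation (recovers its ξ), a uniform
oscillation (no decay within range), and strictly alternating short/long
event trains (frequency-doubling ratio exactly 2).  These fixtures
emulate period, wavelength and correlation structure only; they carry
none of the model's nonlinearity, so passing diagnostics on them
validates the measurement machinery, not the physics.

## What the calibrated model does and does not reproduce

All structural and property-level behavior is reproduced and tested:
sustained 39.2-min relaxation oscillations with `T ∝ 1/ks`; a consistent
CSF arrest with large trigger headroom; fast-wave synchrony (exactly 12
uniform divisions in 8 h); Fig-1-style diffusive spread at a constant
front speed with a chaotic wake; a finite critical wave speed with
genuine slow-wave spatio-temporal irregularity (division-count
heterogeneity, short correlation length, strong transient amplification
of 1e-6 perturbations); monotonicity of the critical speed in embryo
length and in APC activity; 3D geometries tolerating slower waves than
1D; and the slow-wave cellularization ordering in which the hemisphere
distal to the fertilization point divides minutes before the proximal
one at the second cleavage round.

The calibrated constants are, however, measurably more
synchronization-prone than the (unrecoverable) original set, and several
quantitative literature targets are therefore *not* met; the acceptance
suite asserts them anyway and they fail honestly:

* critical transit time ≈ 0.32 T for the 1 mm embryo (literature: 0.1 T),
  and ≈ 1.6 T in the 10-min-period regime (literature: 0.5 T) — the
  ordering (faster clocks tolerate relatively slower waves) is
  reproduced, the ratios are not;
* minimum chaotic size ≈ 0.66 mm (literature: ≈ 0.4 mm);
* prolate critical transit ≈ 60 min (literature: 6 min);
* chaotic correlation length ≈ 0.21–0.23 mm (literature: ≈ 0.1 mm);
* the chaotic interval distribution is not cleanly bimodal at ratio 2:
  deep chaos here suppresses the division amplitude (few threshold
  crossings at all — itself a form of the division-arrest phenotype),
  while edge-of-band chaos shows only weak alternans (ratio ≈ 1.1);
* no cellularized lineage arrests outright: daughter compartments
  (≥ 0.25 mm) fall below this model's minimum chaotic size and
  re-synchronize internally;
* perturbation growth is strongly transient (1e3–1e6-fold amplification)
  but does not reach order one within 8–12 h, and the critical speed
  shows no interior maximum versus the diffusion constant (v_c decreases
  monotonically with D here).

These gaps share a single cause — the diffusive phase-repair of the
calibrated oscillator is stronger than in the original network — and are
the expected failure mode when the exact kinetic constants cannot be
transcribed.  An extensive re-tuning scan (≈ 40 variants of the reset,
destruction and switch constants, each re-calibrated to T = 39.2 min)
did not find a Hill-regulator parameterization that is simultaneously
period-faithful and as chaos-prone as the original, so the shipped set
prioritizes the homogeneous and structural contracts.

## Known limitations

* The spreading trigger is a 1D protocol; in 3D only the wave and
  instantaneous triggers are exposed.
* Division planes are restricted to the alternating-orthogonal-axes
  policy by default (pluggable), and the tetrahedral mesh conforms to at
  most the three coordinate planes through the center; deeper cleavage
  rounds re-use lattice-conforming offsets and rely on the equal-volume
  search.
* No mechanics, no nuclear compartments, no stochastic kinetics — the
  model is deterministic throughout, so "sensitivity" statements refer
  to deterministic chaos, not molecular noise.
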