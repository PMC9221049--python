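# Methods

`cardionet` simulates networks of rat ventricular myocytes in which every
cell's calcium release machinery gates stochastically, and asks the
source–sink question: how many cells must activate together — by current
injection or by spontaneous sarcoplasmic-reticulum (SR) calcium release —
for a sustained action potential (AP) to propagate into the surrounding
tissue?

## Model

### Calcium release units

Each myocyte contains 20,000 physical calcium release units (CRUs, dyads).
A dyad couples a junctional-SR (JSR) compartment, carrying a cluster of 49
RyR2 channels, to a cluster of 7 L-type Ca²⁺ channels (LCCs) across a
femtolitre dyadic subspace.

* **RyR2 gating.** Two states per channel. The opening rate is a
  saturating power law in the *effective activating Ca²⁺*
  `ca_eff = ca_ss · (ca_jsr / 1000 µM) · s`, where `ca_ss` is cleft Ca²⁺,
  the linear lumen factor carries the JSR-load dependence, and `s` is the
  phenotype sensitivity (1.0 control, 1.5 heart failure — the sensitivity
  multiplies the ligand, not the rate):
  `k_open = k_max·x/(k_max+x)` with `x = k₊·ca_eff^η`, η = 3,
  k₊ = 3×10⁻⁵ ms⁻¹µM⁻³, k_max = 30 ms⁻¹. An Ising-type mean-field
  coupling multiplies opening by `exp(+a·f_open)` and closing
  (`k₋ = 0.4 ms⁻¹`) by `exp(−a·f_open)`, a = 1. There is no
  Ca²⁺-dependent inactivation: release terminates by JSR depletion, which
  collapses the lumen factor and with it re-opening.
* **LCC gating.** Four states: closed, open, voltage-inactivated,
  Ca²⁺-calmodulin-inactivated. Voltage activation is a Boltzmann
  (V½ = −10 mV, slope 6.24 mV, τ = 2 ms); voltage inactivation
  (V½ = −23 mV, τ = 30 ms); Ca-CaM inactivation of the open state at
  0.01 ms⁻¹µM⁻¹ of cleft Ca²⁺ (capped at 5 ms⁻¹), recovery 0.01 ms⁻¹.
* **Dyad fluxes.** Release `∝ n_open·(ca_jsr − ca_ss)` (1.5×10⁻³
  µm³/ms per open channel), subspace→myoplasm efflux (0.1 µm³/ms, so the
  cleft relaxes with τ ≈ 10 µs), NSR→JSR refill (10⁻³ µm³/ms), all in
  amount form so that every flux appears with opposite sign in exactly two
  compartments. The subspace buffer (47 µM, Kd 10 µM) integrates with
  explicit mass-action kinetics. The JSR buffer (calsequestrin class,
  13.5 mM sites, Kd 630 µM) is held in rapid equilibrium on the conserved
  total JSR Ca²⁺ via the exact quadratic root: explicit kinetics for this
  buffer are stiffer than the desk-scale timestep and oscillated under
  explicit Euler, while the equilibrium form is exactly conservative and
  unconditionally stable. This is the one buffer not integrated
  kinetically.

### Coarse graining

Simulations track 200 coarse units per cell by default (tests and tissue
runs use 50×400 or smaller), each representing `multiplicity` identical
physical CRUs: one stochastic representative cluster is simulated and its
fluxes into the bulk compartments are multiplied by the multiplicity. This
preserves the all-or-none character of sparks at the cost of lumpier
whole-cell release noise (variance scales with multiplicity). The
alternative of aggregating the replicated channels into one binomial count
sharing the subspace was rejected because it averages away spark
discreteness — the feature local-control models exist to keep.

### Whole-cell membrane

Charge balance over: fast Na⁺ current (classic cardiac m³hj scheme),
inward-rectifier K⁺, fast and slow transient-outward K⁺ and a
non-inactivating steady-state K⁺ current (rodent-like kinetics, giving a
short AP), Na⁺/K⁺ pump, electrogenic 3:1 NCX, plasma-membrane Ca²⁺ pump,
three linear background currents (Ca²⁺/Na⁺/K⁺), the stochastic LCC trigger
flux, applied current, and gap-junction coupling
`+Σ G_gap(V_k − V_m)/(C_sc·A_m)`. The NCX senses
`0.2·⟨sat(ca_ss)⟩ + 0.8·sat(ca_myo)` — 20% of exchangers live in the
dyadic space — with an internal-Ca saturation `sat(c) = c/(1 + c/150 µM)`;
without saturation the exchanger current grows unphysically with cleft
Ca²⁺ (hundreds of µM).

Bulk compartments: myoplasmic Ca²⁺ buffered by calmodulin (24 µM, Kd
2.38 µM), troponin (70 µM, Kd 0.6 µM) and a low-affinity pool (400 µM, Kd
20 µM) representing ATP, sarcolemmal and myofilament sites — the pool is
required for the free transient to stay in the µM range against an SR
content of order 150 µmol per litre cytosol; network-SR Ca²⁺ refilled by a
thermodynamically reversible SERCA2a (reversal at `ca_nsr/ca_myo` =
Kmr/Kmf = 10⁴, Hill 1.787, Vmax 0.9 µM/ms); intracellular Na⁺ and K⁺
integrate their current balances.

### Heart-failure phenotype

Multiplicative transforms applied per cell: transient-outward and
inward-rectifier K⁺ conductances ×0.8, NCX ×2.0, SERCA2a ×0.7, RyR2 Ca²⁺
sensitivity ×1.5, and orphaning of exactly 25% of the CRUs (seed-reproducible
subset) through a 30-fold dyadic subspace volume increase, which dilutes
and slows the LCC trigger signal in those dyads (loss of T-tubule
coupling).

A note on the failing phenotype's diastolic RyR2 open probability: the
sensitized cluster is leakier at any *matched* Ca²⁺ state (×1.5³ ≈ 3.4 in
opening rate), but after pacing to steady state the doubled NCX depresses
diastolic myoplasmic — hence cleft — Ca²⁺ and the SR load enough that the
*operating-point* open probability lands at roughly half the control value.
Reports of this quantity in failing myocytes differ in direction depending
on whether the comparison is state-matched or at the remodeled operating
point; the test suite records both readings.

## Numerics

Explicit Euler with an adaptive timestep and no-flux boundaries. Each step
satisfies, simultaneously: the expected fraction of CRUs with at least one
channel transition ≤ 10% (via the linear bound Σ rates·dt), per-channel
transition probability ≤ 0.2, resolution of the fastest continuous rate
(subspace relaxation, Na⁺ gates, gap coupling; safety factor 0.5), and a
≤ 2 mV membrane-potential move. Desk-scale bounds are dt ∈ [10⁻⁵, 5×10⁻³]
ms; the fine-grained native bounds (10–100 ns) remain selectable. The
realized transition fraction is instrumented and asserted in the tests.
Channel transitions are tau-leaped with exact per-channel probabilities
`1 − e^(−k·dt)` and binomially sampled counts (exact inversion for every
single-cluster case; a continuity-corrected normal approximation only above
mean 50 with more than 128 aggregated channels). Concentrations are clipped
at zero only with a logged diagnostic; in a healthy run the clip count is
zero, and with sarcolemmal Ca²⁺ fluxes disabled total Ca²⁺ is conserved to
machine precision (the test bound is 10⁻⁶ relative over 100 ms).

Every stochastic site draws from its own counter-based stream
(splitmix64-style mixing of seed, site identity and a per-site counter), so
results are bit-reproducible under any update order, runs can be split at
checkpoints without changing the trajectory, and a logged seed replays a
threshold trial exactly.

## Calibration

The ionic-current equations above are standard forms; the free maximal
parameters are pinned by a small physiological contract rather than by any
single published rate constant (`cardionet calibrate` re-runs the pass):

1. resting potential ≈ −80 mV with zero net current *and* zero net Na⁺/K⁺/
   Ca²⁺ species flux — solved in closed form for the two background
   conductances and the Na/K-pump ceiling;
2. a rapid-upstroke, short (rodent-like) AP — APD₉₀ ≈ 50 ms at the
   defaults;
3. longitudinal conduction velocity 0.36 m/s on a cable at 2500 nS gap
   conductance and 100 µm cell length;
4. the cable excitation facts: seven end cells suffice for the slow
   equal-charge stimulus (−6.52 µA/cm² × 5 ms) while five do not, and five
   suffice for the fast one (−16.30 µA/cm² × 2 ms);
5. in the failing phenotype, spontaneous release (10 RyR2s opened in 50% of
   CRUs) needs seven cells, and 80% of CRUs needs four.

Items 3–5 fix the parameters with real leverage: the effective membrane
capacitance `C_sc·A_m` = 500 pF (t-tubule-folded area; at 150 pF the
slowest stable velocity on the 2500 nS cable was ≈ 0.5 m/s, so the
velocity target itself dictates the larger capacitive load), g_Na = 8
mS/cm² (velocity fine-tuning), g_K1 = 0.7 mS/cm² (the resting sink that
separates the slow from the fast stimulus), v_NCX = 250 with the 150 µM
internal saturation (sets the delayed-afterdepolarization drive and keeps
it growing with the released fraction), and k₊ = 3×10⁻⁵ (bulk-Ca CICR
recruitment slow enough that the forced CRU fraction, not recruitment,
controls release magnitude). The calibrated values ship as the package
defaults; every one is an explicit config field.

## What the simulations do and do not emulate

The generator-side defaults *are* the study conditions: 100-cell cables
(the published 1-D percentages imply 100 cells), 100×100 sheets and
100×100×12 blocks with anisotropic coupling (2500 nS longitudinal, 800 nS
transverse), the 8368-cell trabecula-on-wall geometry, the equal-charge
stimulus pair, and the 50%/80% spontaneous-release protocols with 10 of 49
channels forced open. Desk-scale runs reduce the coarse-unit count per cell
(50×400 for tissue, preserving 20,000 physical CRUs per cell) and the
test geometries (30-cell cables, 20×20 sheets); the methods above and the
recorded diagnostics apply unchanged at full scale.

Not represented: spatially resolved sub-cell Ca²⁺ gradients and
intracellular wave propagation (the myoplasm is one compartment, so
cell-level synchronization of release is imposed by the protocol rather
than emergent), β-adrenergic signalling and phospholamban regulation,
transmural cell-type heterogeneity, bidomain/extracellular potentials, and
fibre-angle rotation. Because release inside a coarse unit is replicated
rather than independent, whole-cell release noise is amplified relative to
20,000 independent dyads; threshold counts are therefore defined by a
majority rule (≥ 3 of 5 trials with logged seeds) rather than single
realizations.

## Degenerate inputs and tie-breaks

Zero-duration runs return the initial snapshot only. A lattice of one cell
has no edges (pure single-cell integration). Forced openings never clamp:
`n_open := max(n_open, n)` and the channels close through normal gating.
Stimulus/event times are integration boundaries, so the step never
straddles a protocol edge. The threshold search scans N upward from 1
(success need not be monotone trial-by-trial near threshold; bisection is
unsafe), decides each N early once the majority verdict is fixed, and
reports the failing outcomes at n_min − 1 alongside the success at n_min.
Activation is an exact, interpolated upward crossing of 0 mV recorded by
the integrator (a −20 mV alternative is a parameter), and conduction
velocity uses the median consecutive-cell delay over the central half of
the longitudinal path, excluding stimulus and boundary zones.
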