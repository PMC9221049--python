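# cardionet

How many ventricular myocytes must activate together to start an ectopic
heartbeat?  `cardionet` is a stochastic, local-control simulator of rat
ventricular myocyte networks built to answer that source–sink question.
Each cell carries thousands of calcium release units (CRUs) whose RyR2 and
L-type channel clusters gate by Monte Carlo sampling; cells couple through
gap junctions in 1-D cables, 2-D anisotropic sheets, 3-D blocks, and
trabecula-on-wall geometries.  Protocols inject current at fixed charge
mass or force spontaneous RyR2 openings (the calcium-wave/DAD route to
ectopy), in control or heart-failure phenotypes, and a threshold search
reports the minimal activated-cell count for a sustained propagating
action potential.

## Model in brief

Membrane potential of cell *i* obeys

    C dV_i/dt = -(I_Na + I_K1 + I_Ktof + I_Ktos + I_Kss + I_NaK + I_NCX
                  + I_pmca + I_bg + I_dhpr + I_app)
                + sum_k G_gap (V_k - V_i) / A_m

with stochastic L-type trigger flux I_dhpr summed over open channels.
Each coarse CRU holds a 49-channel RyR2 cluster (two-state channels,
saturating power-law activation by cleft Ca²⁺ scaled by a linear
junctional-SR lumen factor, Ising-type mean-field coupling, no
Ca²⁺-dependent inactivation — release terminates by lumen depletion) and a
7-channel L-type cluster (closed / open / voltage-inactivated /
Ca²⁺-calmodulin-inactivated) facing a femtolitre subspace.  20% of the NCX
senses subspace Ca²⁺, which is what turns spontaneous release into a
depolarizing inward current.  Heart failure is modeled as I_to and I_K1
×0.8, NCX ×2, SERCA2a ×0.7, RyR2 Ca²⁺ sensitivity ×1.5, and 25% of CRUs
orphaned via a 30-fold subspace volume increase.  Integration is explicit
Euler with an adaptive timestep that caps the expected fraction of CRUs
with channel transitions at 10% per step; every stochastic site owns a
counter-based random stream, so runs are bit-reproducible and resumable.
See `docs/methods.md` for the full account, including how the free
conductances were calibrated (resting balance, rat-like AP, 0.36 m/s
conduction at 2500 nS).

## Worked example

Find the minimal number of end cells whose fast equal-charge stimulus
(−16.30 µA/cm² for 2 ms) launches a propagating AP along a 100-cell cable
at 2500 nS coupling:

```python
from cardionet import ModelParams, build_lattice
from cardionet.protocols import (ThresholdSetup, build_trial_runner,
                                 find_min_cells)

geom = build_lattice((100,), g_long=2500.0)
setup = ThresholdSetup(geometry=geom, params=ModelParams(),
                       stimulus_kind="instantaneous",
                       n_cru=50, multiplicity=400, settle_ms=800.0)
runner = build_trial_runner(setup)
res = find_min_cells(runner, n_max=12, trials=5, seed=1)
print("n_min =", res.n_min)
print("outcomes:", {n: [ok for _, ok in v] for n, v in res.outcomes.items()})
```

which prints

```
n_min = 5
outcomes: {1: [False, False, False], 2: [False, False, False],
           3: [False, False, False], 4: [False, False, False],
           5: [True, True, True]}
```

i.e. four stimulated cells never recruit the cable (the injected charge
drains into the resting sink), while five succeed on every trial — the
cable's ectopic threshold for this stimulus.  Because gating is
stochastic, `n_min` is defined by a majority rule (here ≥3 of 5 trials,
decided early once fixed) and every trial's seed is logged in
`res.seeds` for exact replay.

The same machinery runs spontaneous-release protocols
(`SpontaneousReleaseProtocol(cru_fraction=0.8, channels_opened=10)` on
heart-failure cells), 2-D/3-D lattices, trabeculae
(`build_trabecula()`, 8368 cells), and non-contiguous stimulation
patterns (`make_noncontiguous_pattern`).  A YAML-configured CLI wraps it:

```bash
cardionet simulate -c config.yaml -o out.h5
cardionet threshold -c config.yaml --protocol instantaneous
cardionet sweep -c config.yaml -o thresholds.csv
cardionet calibrate
```

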