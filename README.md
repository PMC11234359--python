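# prebound

Analysis toolkit for the unbinding pathway of a tightly bound
protein–protein complex — the serine protease trypsin with BPTI (bovine
pancreatic trypsin inhibitor) and its P1-truncated/fluorinated variants —
centred on the metastable **prebound state**: an intermediate in which the
inhibitor has slid ~0.2 nm out of the fully bound pose (centre-of-mass
distance 2.75–3.00 nm vs. ~2.65 nm bound) but has not yet dissociated.

The package is aimed at simulators who want to detect and characterise
such intermediates in dissociation trajectories, and provides:

* **Collective variables.** Six internal coordinates built from
  mass-weighted backbone reference points (T1–T3 on the enzyme, B1–B3 on
  the inhibitor): the centre-of-mass distance *r* = |T1−B1|, the positional
  angle Θp = ∠(T2,T1,B1) and dihedral Φp = ∠(T3,T2,T1,B1), and the
  orientational coordinates θo, φo, ψo. All are invariant under global
  rigid-body motion.
* **Random-acceleration dissociation protocol** on a reduced Langevin
  model: a constant-magnitude force (default 3500 kJ/(mol nm)) of random
  direction acts on the ligand and is redrawn whenever the centre of mass
  moves ≤ 0.0025 nm per 100 fs, on a calibrated two-basin radial free-energy
  landscape with bound (2.65 nm) and prebound (2.85 nm) wells.
* **State analysis.** 200 ps moving-average smoothing of r(t), frame
  classification, detection of prebound visits (≥ 1 ns contiguous dwell in
  the 2.75–3.00 nm band), per-state statistics and distribution overlaps.
* **Interface interactions.** Heavy-atom contacts (< 0.35 nm), hydrogen
  bonds by the Wernet–Nilsson cone criterion
  r_DA < 3.3 Å − 0.00044 Å/deg² · δ²_HDA, arginine-guanidine minimum
  distances, aromatic ring-centroid distances (cation–π readout), and
  Shrake–Rupley solvent-accessible surface area.
* **Umbrella sampling / binless WHAM.** Free-energy profiles over the
  Phe41-O–Arg17-N distance ξ from 13 harmonic windows
  (k = 6276 kJ/(mol nm²)), with the 5-segment leave-one-out bootstrap and
  barrier/minimum extraction.
* **Synthetic data with ground truth** for all of the above, including a
  programmatically built two-chain mini-complex (a labelled synthetic
  stand-in, not experimental coordinates).

## Worked example

Generate a two-state trajectory whose bound/prebound distributions follow
the study system (r = 2.65 ± 0.04 nm and 2.85 ± 0.05 nm, with a +0.2 rad
shift of Θp and Φp in the prebound state), then recover the states:

```python
from prebound import synthetic_data as sd, state_analysis as sa
from prebound.collective_variables import compute_cv_series

plan = sd.TwoStateTrajectoryPlan.defaults(n_frames_per_state=200, seed=1)
traj, truth = sd.generate_two_state_trajectory(plan)
series = compute_cv_series(traj, sd.template_reference_spec())
stats = sa.state_statistics(series, truth.labels)
print(stats.table[["r_mean", "r_sd", "theta_p_mean", "count"]].round(3))
```

```
          r_mean   r_sd  theta_p_mean  count
state
bound      2.647  0.039         1.801    200
prebound   2.853  0.048         2.003    200
```

The recovered means and spreads match the planted distributions within
sampling error, and the Θp shift between states is the planted 0.2 rad.

Run one biased dissociation at the default force and look for the
intermediate:

```python
from prebound.toy_ramd import ToyLandscape, RAMDParams, run_ramd
from prebound.state_analysis import SmoothingParams, moving_average, detect_prebound_visit

run = run_ramd(ToyLandscape(), RAMDParams(seed=3))
smoothed = moving_average(run.times_ps, run.r_nm, SmoothingParams(200.0))
report = detect_prebound_visit(run.times_ps, smoothed)
print("dissociated at", run.dissociation_time_ns, "ns;",
      "visited prebound:", report.visited_prebound)
```

```
dissociated at 9.282494 ns; visited prebound: True
```

This run leaves the bound basin, dwells for several nanoseconds in the
2.75–3.00 nm band (the prebound state) and then dissociates — the
signature the dwell detector is built to find.

A command-line pipeline ties the stages together:

```sh
prebound synth dwell --seed 2 --out run/
prebound detect --series run/dwell_series.csv --out run/
prebound pmf --seed 2 --out run/
```

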