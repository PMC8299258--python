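# mtforce

Single-molecule AFM force spectroscopy of metalloprotein unfolding:
a Monte-Carlo polyprotein pulling simulator with per-curve ground truth,
and the full analysis pipeline that turns sawtooth force-extension curves
into unfolding pathways and rupture kinetics.

## The scientific problem

Human metallothionein (MT) binds its metals in two polynuclear
metal-thiolate clusters — M₄S₁₁ in the α domain, M₃S₉ in the β domain.
When one MT molecule is stretched between an AFM tip and a surface inside
a (GB1)₃-MT-(GB1)₃ polyprotein, each unfolding event releases a
characteristic contour length ΔLc and appears as one sawtooth peak.  The
α-domain cluster can rupture in one step (ΔLc ≈ 11 nm, the whole
Cys34–Cys67 segment) or in two steps whose increments always sum to
~11 nm: an intermediate survives with one anchoring cysteine (Cys37/38,
Cys42, Cys45 or Cys49/51) still bound, defining four pathways P1–P4.
Because the cysteine-free Cys51–Cys64 stretch sits on the C-terminal
side, the larger member of a two-step pair always comes from the
C-terminus, so the order of the two increments reveals the unfolding
direction.  Rupture is stochastic and force-accelerated
(Bell–Evans: k(F) = k_off·exp(FΔx/k_BT)), so pulling at several speeds
and reading the most probable rupture force against the logarithm of the
loading rate yields the zero-force dissociation rate k_off and the
distance to the transition state Δx.

`mtforce` is for people who build or test such analyses: every stage
(peak detection, worm-like-chain fitting, ΔLc computation, marker
fingerprint selection, pathway/direction classification, Bell–Evans
fitting) can be run against simulated curves whose true events, pathways
and kinetics are known exactly.

## Core models

* **Worm-like chain** (Marko–Siggia interpolation), persistence length
  0.4 nm, k_BT = 4.114 pN·nm:
  `F = (k_BT/p)·[1/(4(1−x/Lc)²) − 1/4 + x/Lc]`
* **Contour increments**: `ΔLc = 0.36 nm/aa · n_aa − d_folded`
  (e.g. 0.36·34 − 1.3 = 10.9 nm for the full α segment).
* **Bell–Evans kinetics** with exact inverse-CDF rupture-force sampling
  and the modal-force relation `F* = (k_BT/Δx)·ln(rΔx/(k_off·k_BT))`.
* **Kinetic Monte-Carlo pulling**: WLC in series with a Hookean
  cantilever, per-step rupture hazards for every intact domain, scenario
  mixture (one-step 51%, P1–P4, 55% C-terminus-first) for the cluster.

## Worked example

Simulate 300 marker-flanked Zn-αMT molecules, analyze them blind, and
tabulate the pathway statistics:

```python
import numpy as np
from mtforce import (
    SegmentTable, build_construct, simulate_curve, analyze_curve,
    build_default_pathways, classify_event, tabulate,
)

config = build_construct("Zn-aMT")          # (GB1)3 - Zn-alphaMT - (GB1)3
pathways = build_default_pathways(SegmentTable.default())

assignments = []
for seed in np.random.SeedSequence(1).generate_state(300):
    curve, truth = simulate_curve(config, int(seed))
    result = analyze_curve(curve)
    if result.accepted and result.target_event is not None:
        assignments.append(classify_event(result.target_event.dlc_list, pathways))

stats = tabulate(assignments)
print(f"molecules accepted: {stats.n_total}, assigned: {stats.n_assigned}")
print(f"one-step fraction:  {stats.frequencies['one-step']:.2f}")
print(f"C-terminus-first:   {stats.c_terminal_fraction:.2f}")
```

prints

```
molecules accepted: 271, assigned: 241
one-step fraction:  0.55
C-terminus-first:   0.54
```

271 of 300 curves pass the GB1 fingerprint selection (≥3 marker peaks of
ΔLc 16–20 nm above 100 pN); among classified molecules the one-step
fraction and the C-terminal direction bias recover the generating mixture
(0.51 and 0.55) within sampling error.  Kinetics are recovered the same
way from rupture forces across five loading-rate decades:

```python
from mtforce import KineticParameters, sample_rupture_force
from mtforce.dfs_kinetics import bin_by_loading_rate, dfs_from_bins

params = KineticParameters(k_off=25.0, delta_x=0.20)   # Zn-alphaMT cluster
edges = np.geomspace(1e3, 3e5, 6)
rng = np.random.default_rng(1)
forces, rates = [], []
for r in np.sqrt(edges[:-1] * edges[1:]):
    forces.append(sample_rupture_force(r, params, rng=rng, size=300))
    rates.append(np.full(300, r))
bins, _ = bin_by_loading_rate(np.concatenate(forces), np.concatenate(rates))
fit = dfs_from_bins(bins)
print(f"k_off = {fit.k_off:.1f} 1/s (*/ {fit.k_off_geom_se:.2f}), "
      f"delta_x = {fit.delta_x:.3f} nm +/- {fit.delta_x_se:.3f}")
```

prints

```
k_off = 25.6 1/s (*/ 1.09), delta_x = 0.203 nm +/- 0.006
```

i.e. the Bell–Evans fit recovers the generating k_off = 25 s⁻¹ and
Δx = 0.20 nm; the k_off uncertainty is a multiplicative (geometric)
factor.

## Command line

Each pipeline stage is a subcommand of `mtforce`
(`simulate`, `analyze`, `classify`, `dfs`, `report`), and `pipeline`
chains them:

```
mtforce pipeline --construct Zn-aMT --n-curves 200 --seed 1 --out run/
```

writes the simulated dataset (TSV curves + JSON ground truth + manifest),
the events table, the pathway-statistics and histogram tables, a
Bell–Evans fit from a multi-speed sweep, and `report.json`.  All outputs
are plain text, stamped with the package version, a config hash and the
master seed, and byte-identical across reruns with the same seed.

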