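# Methods

This note documents the models behind `mtforce`, the default parameter
choices and why they were made, what the simulator does and does not
emulate, and the numerical decisions that matter when reading its output.

## Polymer elasticity

Unfolded polypeptide is modelled by the Marko–Siggia interpolation of the
worm-like chain,

    F(x; Lc) = (kBT/p) · [ 1/(4(1 − x/Lc)²) − 1/4 + x/Lc ],

with persistence length `p = 0.4 nm` and `kBT = 4.114 pN·nm` (298 K) —
typical values for polyprotein AFM work.  Both are plain parameters
(`WlcParameters`), never hard-coded in analysis logic, so an exact
numerical WLC could be substituted.  The inverse (extension at a given
force) is solved by bracketed root finding to machine precision; the
round trip reproduces forces to well below 1e-6 pN.

Contour increments follow the segment arithmetic
`ΔLc = 0.36 nm/aa · n_aa − d_folded`.  The shipped `SegmentTable` stores
residue counts verbatim as published rather than deriving them from
residue indices, because the published counts do not follow a single
inclusive/exclusive endpoint convention (34 aa for Cys34–Cys67 is
endpoint-inclusive; 22 aa for Cys45–Cys67 is not).  Folded end-to-end
distances of the two α sub-segments (0.72 and 0.42 nm) are
back-calculated so the table reproduces the tabulated theoretical
increments (3.6 and 7.5 nm).

## Rupture kinetics

Bond rupture under force follows Bell–Evans,
`k(F) = k_off · exp(F·Δx/kBT)`.  Under a constant loading rate `r` the
rupture-force distribution has the closed-form survival function
`S(F) = exp[−(k_off·kBT/(rΔx))·(exp(FΔx/kBT) − 1)]`; sampling uses the
exact inverse CDF via an exponential deviate, and the sampler is tested
against `S(F)` at a Kolmogorov–Smirnov distance below 0.01 (n = 1e5).
The modal force is `F* = (kBT/Δx)·ln(rΔx/(k_off·kBT))`, clipped at zero:
physical rupture forces are non-negative and the dynamic-force-
spectroscopy fit never operates in the clipped regime.

Cluster kinetics defaults: Zn-α `k_off = 25 s⁻¹`, Cd-α `10 s⁻¹`,
Zn-rubredoxin control `0.5 s⁻¹`, Cd-rubredoxin `1.6 s⁻¹`.  The barrier
distances are not printed in the available record and default to
`Δx = 0.20 nm` (α-cluster-like) and `0.15 nm` (rubredoxin-like); they are
declared constants, configurable everywhere.  β-domain kinetics are not
published either and default to the α values.

## The pulling simulator

`simulate_curve` advances the piezo at constant speed in steps of
0.05 nm.  At each step the polymer (WLC of the current total contour
length) and the Hookean cantilever (40 pN/nm) are in mechanical series;
the balance is solved by vectorised Newton iteration and the recorded
"extension" is the tip–sample separation, as in a corrected AFM retract
trace.  Every intact unit carries a Bell–Evans hazard; a rupture is drawn
by inverse-CDF over the per-step survival products, the rupturing unit by
its hazard share, and the released increment is added to the contour
length.  Metal-cluster domains draw a scenario first: one-step
(probability 0.51, ΔLc 11.3 nm) or two-step via pathways P1–P4
(conditional probabilities 16/12/10/11 normalised, measured pairs
5.2+6.1, 4.1+7.2, 3.2+8.1, 2.4+9.3 nm) with the larger member released
first in 55% of events (C-terminus-first).  Two-step intermediates keep
the first-rupture kinetics by default, reflecting the similar
metal–thiolate bond strengths across pathways.  The β domain ships with
an explicitly illustrative "unresolved" mode (uniform split of 7.8 nm),
since its anchoring pattern cannot be resolved experimentally.  After the
last unfolding the tether detaches at a fixed 400 pN; a 10 nm zero-force
approach segment precedes engagement and a short zero-force tail follows
detachment.  Gaussian force noise (SD 8 pN) is added to the whole trace.
Every curve carries a ground-truth sidecar listing each rupture's domain,
increment, force, pathway, anchor and direction.

### Instrument defaults and their calibration

Instrument settings are not part of the published record; the defaults
are package calibration choices, made from the force-distribution
arithmetic and then fixed:

* **Pulling speed 5000 nm/s.**  With `k_off = 25 s⁻¹` the α cluster
  ruptures spontaneously on millisecond timescales, so slow pulling loses
  a large fraction of events at near-zero force and makes the smallest
  intermediate force drops (2.4 nm release) sink below any noise-safe
  detection threshold.  5000 nm/s puts the one-step modal force near
  85 pN — inside the experimentally reported 75 ± 34 pN band — while
  still leaving ~10% of cluster ruptures below the 20 pN detection floor.
  That residual loss is a property of the physics, not of the analyzer.
* **Tether (handle) contour 10 nm.**  A short tether maximises the
  relative contour release per rupture and hence the force drops.
* **Marker model.**  GB1 markers have a fixed 18 nm increment and a
  target modal rupture force of 180 pN.  Their rate constant is solved
  from the modal-force relation at the construct's own mid-pulling
  effective loading rate, divided by the geometric-mean hazard
  multiplicity `(n!)^(1/n)` of the n identical markers (six markers share
  the hazard, which otherwise lowers the observed force series by
  ~25–40 pN).  The marker `Δx = 0.3 nm` is an effective fingerprint
  value: it keeps the marker force distribution narrow enough that
  left-tail marker ruptures below the 100 pN marker criterion stay rare.
  The marker's true microscopic rate parameters are not part of the
  published record; only the 18 nm / ~180 pN signature is.
* The rubredoxin-like control uses a nominal fixed 13 nm increment — a
  synthetic choice, as only its kinetics matter for the control.

## Curve analysis

Each trace is baseline-corrected by the median force of its first 5% of
samples (the approach region), smoothed by an 11-sample moving average
*for detection only*, and peaks are local maxima with ≥ 10 pN prominence
and ≥ 20 pN height whose drop appears within three smoothing windows (a
genuine rupture drops immediately; noise bumps recover).  Branch
boundaries are set at the raw-force minimum just after each peak, so no
pre-rupture samples leak into the next branch.  Each rising branch's
contiguous terminal segment above 15 pN is fitted for its contour length
(persistence length fixed for identifiability on short branches; a
global-fit switch exists); increments are consecutive contour-length
differences.

Two refinement passes recover ruptures that leave no separate smoothed
maximum — with `k_off = 25 s⁻¹` a second rupture frequently follows the
first within the smoothing scale:

* **Valley rescue**: samples between a peak and the next branch start are
  converted to implied contour lengths (extension over relative extension
  at each sample's force); a tight cluster strictly between the flanking
  branches (≥ 1.5 nm from both) is refitted and inserted as a peak.
* **Change-point split**: a branch whose single-contour fit residual
  exceeds 1.1× the curve's median branch residual is scanned for the best
  two-part fit; the split is kept only if it reduces the summed squared
  residual by at least 25× the post-split residual variance and implies a
  step ≥ 0.8 nm.

Both are guarded by a re-merge rule: any increment below 0.8 nm —
beneath the ~1 nm (~3 aa) length resolution of the measurement — is
treated as a spurious branch split and healed by refitting the merged
branch.  Negative or > 25 nm increments (outside any construct segment)
mark mis-fits and exclude the event.  Rupture forces are reported as the
fitted WLC evaluated at the drop point, which removes the ~10 pN
downward bias of reading the smoothed maximum on a rising branch.

Molecule selection follows the marker-fingerprint logic: accept a curve
iff ≥ 3 events fall in the 16–20 nm marker window at ≥ 100 pN.  A
marker-window increment *below* the force criterion is attributed to a
low-force marker rupture and excluded rather than passed to the target
list: no target segment in these constructs can release ~18 nm, and
without this rule genuine left-tail GB1 events contaminate the
metallothionein increment lists.  The final detachment peak is excluded
from increment statistics.

## Pathway and direction classification

A single increment inside the one-step window (10–13 nm for α) is
one-step.  A pair is first checked for conservation (sum within 1 nm of
11.3 nm), then matched as a sorted (small, large) pair to the nearest
pathway by Euclidean distance, accepted within 0.7 nm — half the ~1 nm
stated length resolution.  Distance ties break deterministically toward
the lower pathway id and are flagged; at the default tolerance a tie
cannot actually occur (adjacent pathway pairs are ≥ 1.56 nm apart, so
the equidistant midpoint lies outside tolerance), but the rule is kept
for custom tolerances.  Direction comes from the observed order: the
first increment matching the pair's larger member means C-terminus-first;
pairs whose members differ by less than 0.5 nm are direction-undecidable.
Events with more than two increments (below 1% of molecules) are counted
as multi-step and excluded from P1–P4 statistics, as are unassigned
events.  Sorted-pair matching deliberately decouples pathway from
direction: (a+b) and (b+a) are one pathway observed in two directions.

## Dynamic force spectroscopy

Per-event loading rates are the endpoint derivative of a quadratic
fitted to force versus time over the terminal 30% of the branch, with
time reconstructed from piezo travel (extension plus cantilever
deflection over speed).  The quadratic endpoint matters: the series
stiffness rises along the branch, so a plain average slope over the
window understates the rate at rupture by ~20%; the endpoint estimate
agrees with the analytic series-spring oracle `k_eff·v` to ~4%.  Events
are pooled into five log-spaced bins spanning 1e3–3e5 pN/s (bin centres
at the geometric mean of the edges, matching the log-linear model); each
bin's most probable force is the mode of a Gaussian kernel density
(Silverman bandwidth) above 20 events, a histogram mode between 5 and 19,
and the bin is dropped below 5.  The Bell–Evans line is fitted by
weighted least squares of modal force on ln r; `Δx = kBT/slope` and
`k_off = exp(−intercept/slope)/slope`, with delta-method standard errors
(multiplicative/geometric for k_off, additive for Δx).  A diagnostic
envelope refits with k_off scaled ×3 and ÷3 for the plot.

The pipeline's DFS stage simulates a dedicated sweep over five pulling
speeds and uses only one-step cluster events: a single-speed dataset
spans less than a decade of loading rate and cannot constrain the line,
and two-step intermediates rupture from a different starting state.

## Problem sizes and what the tests show

The test suite and the acceptance script run the pipeline at desk scale:
200 single-marker curves for marker fidelity (mean fitted increment
18.0 ± 0.2 nm), 400 two-step curves for direction recovery, 800
mixed-scenario curves for the one-step fraction (each within three
binomial standard errors of the generating mixture), and 300 rupture
forces per bin for kinetics recovery (k_off within a factor 1.5, Δx
within 10%).  The noiseless round trip demands exact recovery (ΔLc error
< 0.1 nm, zero false peaks) of every *resolvable* event; events below
the 20 pN force floor, events whose force drop is under the 10 pN
detection threshold, and ruptures closer than the smoothing scale
(~0.5 nm of piezo travel, tens of microseconds) are invisible to any
analysis of the trace, and the fast α-cluster kinetics guarantee such
events occur.  An invisible rupture silently merges its increment into a
neighbouring event — on real data as on simulated data — which is why
recovered one-step fractions run one to three points above the generating
value and why multi-step statistics need the unassigned bucket.

## What the simulator does not emulate

No refolding during a ramp (pulling is monotonic), no more-than-two-step
cluster ruptures (below 1% experimentally), no drift, no hydrodynamic
drag or cantilever ringing, no correlated thermal position noise, and no
heterogeneity in the per-pathway increments (the broad experimental ΔLc
distribution reflects more intermediates than the four-pathway model
resolves).  Passing tests therefore certify the analysis logic against
the stated generative model, not against every artefact of real AFM
data; the reader interface accepts any two-column TSV, so real corrected
traces can be analyzed, but vendor formats and calibration are out of
scope.
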