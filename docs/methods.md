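# Methods

This note documents the models, estimators and numerical choices behind
pocketdyn, in the order the pipeline applies them, together with what the
synthetic validation does and does not demonstrate.

## Scope and conventions

The package analyses short equilibrium trajectories of a protein active
site — the motivating system is the GFP chromophore pocket with its
Tyr66–water–Ser205–Glu222 proton wire — sampled densely in time
(femtosecond steps, picosecond spans).  Coordinates are Å, time is fs,
angles are degrees; there is no unit auto-detection.  Distances are plain
Euclidean with no periodic-boundary handling: the intended systems are
single solvated proteins treated as clusters.  Atom identity comes from a
PDB topology whose coordinates are ignored; PDB residue numbering is kept
verbatim so selections read like the literature (Tyr66, Ser205, ...).
The timestep is never parsed from XYZ comment lines — there is no
standard dialect, and silent misreads are worse than one explicit config
key.

## Geometric descriptors

Hydrogen-bond dynamics is followed through *raw heavy-atom distances*
(donor–acceptor O–O / N–O), not binary H-bond states: existence criteria
with angular cutoffs would discard exactly the fluctuation amplitude the
correlation analysis needs.  Bond angles come from the clamped-arccos
form (the cosine is clipped to [−1, 1] to absorb floating-point drift at
straight configurations; no tolerance is exposed).  Torsions use the
two-normal atan2 formulation with the IUPAC right-handed sign convention
on (−180°, 180°]; the convention was fixed against an independent
implementation (MDAnalysis) and is exercised in the tests over random
geometry.  The "plane–plane" dihedral of the proton wire is implemented
as the ordinary 4-atom torsion over the wire oxygens, since the two
planes of interest share an edge.  Which Glu222 carboxylate oxygen is
"the accepting oxygen" is a per-topology fact; the config must name it
explicitly.

## Cavity volume

The pocket cavity is modelled as the union of atom-centered spheres over
a configured selection, with radii from the packaged UFF table (Rappé et
al. 1992 nonbond radii, the table continuum-solvation cavity builders
use).  A multiplicative `radius_scale` (default 1.0) is exposed because
cavity conventions often scale van-der-Waals radii (e.g., ×1.1); whether
hydrogens belong in the selection is likewise left to the config.  This
is deliberately a volume, not a surface model: no solvent probe, no
tessellation, no solvent-excluded surface.

Two estimators:

* **grid** (default spacing 0.1 Å): a voxel counts if its *center* lies
  inside any sphere, over the tight bounding box; volume = count × h³.
  No partial-voxel weighting — the rule is deterministic, converges as
  O(h), and is trivial to oracle against closed forms.
* **monte_carlo**: uniform samples in the bounding box; volume = hit
  fraction × box volume; the reported `stochastic_error` is the binomial
  standard error scaled by the box volume.  Deterministic given the seed;
  per-frame seeds are spawned from the master seed and the frame index,
  so results do not depend on evaluation order.

Spheres wholly contained in another are pruned before the point test as
an optimization; pruning cannot change any point's in/out status, so
results are bit-identical with pruning off (asserted in tests).

Analytic bounds (largest single sphere ≤ union ≤ sum of spheres) are
asserted per frame with an estimator-aware slack — 3·h/r_min relative for
the grid, 5 standard errors for MC — because voxelization can legitimately
overshoot the continuum bounds by O(h).

Accuracy at the defaults: a single r = 2 Å sphere at 0.05 Å spacing is
within 0.5% of 4πr³/3; two overlapping spheres match the exact
sphere–sphere lens formula within 1%; grid and MC agree within combined
uncertainties on random five-sphere sets (the grid uncertainty is taken
as the h → h/2 refinement difference).

## Distributions

"Normalized" means unit area (probability density), not unit maximum, so
curves at different resolutions are comparable.  Default resolutions are
0.02 Å for distances, 2.00° for angles/torsions, 1 Å³ for volumes.  Bin
edges sit on the lattice anchor + k·resolution with anchor 0.0 by
default, so reported bin centers do not depend on the sampled range.
Smoothing is a centered moving average over bins (default window 15) with
truncated windows at the edges — a window average, chosen over block
averaging for shape preservation; both peak reports (raw and smoothed)
are written because the two can legitimately differ by a bin.  Peaks are
strict local maxima filtered to ≥ 10% of the global maximum and ≥ 5 bins
apart (the higher of a conflicting pair wins): at 0.02 Å resolution this
separates bimodal arrangements ~0.5 Å apart while suppressing
single-bin sampling noise.

## Time-lagged cross-correlation

For mean-subtracted series x, y at common dt,

    r_xy(τ) = ⟨x(t+τ) y(t)⟩ / √(⟨x²⟩⟨y²⟩),  τ = k·dt, k ∈ [−K, K].

Estimator decisions, in decreasing order of consequence:

* **Boundary handling.**  At lag k the numerator is summed over the
  overlap region only and divided by the overlap count N − |k| (lag-wise
  unbiased), while the denominator keeps the τ-independent full-series
  mean squares.  Consequence: |r| can marginally exceed 1 at extreme
  lags; values are clipped to [−1, 1] and the per-lag overlap count is
  reported.  A warning is emitted when the overlap drops below 30
  samples.
* **Lag sign.**  x is the first-named series; a peak at negative τ means
  y lags behind x.  For H-bond/volume reports, x is the distance and y
  the volume.
* **Exact antisymmetry.**  Each directed lag runs the identical BLAS dot
  product under both argument orders, so r_xy(τ) = r_yx(−τ) holds
  bit-exactly, not just to rounding.
* **Mean subtraction** uses the full-series mean; no detrending — the
  intended inputs are stationary equilibrium fluctuations.
* **Lag range.**  The hard cap is 70% of the duration (delays up to
  ~two-thirds of a trajectory appear in practice in this literature).
  The *recommended* analysis window, used by the synthetic-study preset,
  is **half the duration**: beyond 50% overlap loss, the estimator
  variance for fluctuations with ~25 fs memory grows enough that the
  |r| > 0.45 retention rule loses its meaning (measured on independent
  OU pairs at the study conditions: over the 70% window the null crosses
  0.45 in ~20% of runs; over the 50% window, in none of 50 runs).

Extrema of r(τ) are interior strict local maxima/minima.  The global |r|
extremum is always reported first — every analysed pair gets a headline
"r (delay)" value — and further extrema are reported when they exceed
the retention threshold, pruned to a minimum lag separation (default
50 fs) keeping the larger |r|.  Endpoints are never extrema, so a
monotone r(τ) yields an empty list.  Retention is strict:
max |r| > 0.45; both a positive and a negative extremum are listed when
each qualifies.  No significance testing beyond the threshold rule is
attempted (no block bootstrap, no effective-sample-size correction) —
the threshold is part of the analysis definition.

## Synthetic data and what it validates

The fluctuation model is the exact-discretization Ornstein–Uhlenbeck
process: stationary, Gaussian, exponentially correlated — the minimal
model with a tunable correlation time.  Defaults emulate the study
sampling: 10,000 steps at 0.25 fs (2.5 ps) with a 100-step (25 fs)
correlation time.  Coupling is imposed on *standardized* series,
y_k = ρ·x̃_{k−lag} + √(1−ρ²)·z̃_k, so ρ is directly the expected peak
correlation, attained exactly at τ = −lag·dt; neighbouring lags decay as
the OU autocorrelation.  (No attenuation applies at the peak itself
because the coupling is written at the lag.)  One master seed fans out to
per-stream seeds by a stable hash of the stream name, so adding a stream
never perturbs existing ones.

The toy pocket realizes prescribed series as exact geometry: each moving
atom slides along a dedicated axis from a static partner (distance
readback is exact to formatting precision), and two "breathing" spheres
whose gap follows the coupled partner series drive the union volume
monotonically while they overlap.  The gap series is clipped to keep the
spheres overlapping; clipping is rare (<1% of frames at the defaults)
and, together with the smooth nonlinearity of volume-versus-gap, slightly
attenuates the realized distance/volume correlation below ρ — observed
peaks at ρ = 0.6 typically land in 0.48–0.70 across seeds, comfortably
above the 0.45 retention threshold.

What passing the synthetic study shows: the estimator chain (file I/O →
selection → descriptors → volume → correlation → retention) recovers
known couplings at the right lag and does not fabricate couplings between
independent series, at the study's sampling conditions.  What it does not
show: physical realism.  OU statistics are Gaussian and unimodal (no
bimodal H-bond switching), the toy geometry has no vibrational structure,
rotations or anharmonicity, and real AIMD descriptors are neither exactly
stationary nor exactly Markovian.  Quantitative agreement with any
specific simulation's peak positions or correlation values is out of
scope.

## Problem sizes in the shipped studies

The validation studies run at: 1,000-step pairs for oracle equivalence
(all ±500 lags against an explicit double loop, agreement ≤ 1e-10);
10,000-step pairs for recovery (20 seeds) and null retention (50 pairs);
10⁷ Monte-Carlo samples against 0.05 Å grids on ten random five-sphere
sets; and a full 10,000-frame, 46-atom toy-pocket pipeline with the grid
estimator at 0.2 Å (coarser than the 0.1 Å default — the toy's volume
signal is large against discretization error, and the run stays
comfortably within a few minutes).  The 2,000-frame pipeline fixture uses
a 20-step OU memory and a 125 fs lag window: on a 500 fs trajectory the
default 100-step memory leaves too few independent fluctuations for the
retention rule to separate a ρ = 0.6 coupling from null.

## Known limitations

* The union-of-spheres cavity is not a solvent-excluded surface; absolute
  volumes depend on the radii table, the scale factor and the selection,
  so only *fluctuations and correlations* of the volume series should be
  interpreted, not magnitudes.
* The retention rule |r| > 0.45 is a convention, not a calibrated
  significance level; with long-memory series and long lag windows the
  null can cross it (see the lag-window discussion above).
* The grid estimator's O(h) convergence means very small volume changes
  (≪ h × surface area) per frame are quantized; use the MC estimator or
  a finer grid when differentiating near-constant series.
* XYZ/PDB are the only trajectory/topology formats; binary formats
  (DCD/XTC/TRR) are out of scope.
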