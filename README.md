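# pocketdyn

Structural-dynamics analysis of a fluorescent-protein chromophore pocket
from molecular-dynamics trajectories: hydrogen-bond geometric descriptors,
pocket cavity volume, equilibrium distributions, and normalized
time-lagged cross-correlation analysis with significance filtering —
plus a synthetic-trajectory generator with known correlation structure so
every stage is testable without external simulation data.

## Who this is for

Computational chemists and structural bioinformaticians who have short
(picosecond-scale, femtosecond-step) trajectories of a protein active
site — e.g., the GFP chromophore pocket with its Tyr66–water–Ser205–Glu222
proton wire — and want to quantify how hydrogen-bond fluctuations couple
to each other and to the size of the cavity embedding the chromophore.

## The analysis

**Descriptors.** From a multi-frame XYZ trajectory (Å, fixed timestep in
fs) and a PDB topology (labels only), the package extracts heavy-atom
distance, bond-angle and signed-torsion time series for named selections
such as `O(Tyr66)-O(Wat)`.

**Cavity volume.** The pocket volume is the volume of the union of
atom-centered spheres over a configured selection, with UFF atomic radii
(optionally scaled).  Two estimators: deterministic voxel counting
(volume = voxel-centers-inside × h³) and seeded Monte Carlo with a
binomial error bar.

**Distributions.** Unit-area histograms at fixed resolution — 0.02 Å for
O–O distances, 2.00° for angles/torsions, 1 Å³ for the volume — with
moving-average smoothing and peak location.

**Cross-correlation.** For mean-subtracted series x(t), y(t) at common
timestep, the normalized time-lagged cross-correlation is

    r_xy(τ) = ⟨x(t+τ) y(t)⟩ / √(⟨x²⟩⟨y²⟩)  ∈ [−1, 1]

estimated lag-wise over the overlap region.  A peak at negative τ means
y lags behind x.  Local extrema are reported as "r (delay)" pairs and a
correlation function is *retained* as significant only if some extremum
satisfies |r_xy| > 0.45.

**Synthetic ground truth.**  Ornstein–Uhlenbeck (OU) processes with
tunable correlation time stand in for fs-scale structural fluctuations;
coupled pairs are built so the expected peak correlation and its lag are
known exactly, and a toy-pocket builder emits a full labelled trajectory
in which chosen interatomic distances equal the prescribed series exactly
and the cavity volume is driven by a prescribed breathing mode.

## Worked example

```bash
python examples/04_cross_correlation.py
```

prints (abridged):

```
ground truth : r = 0.6 at -12.5 fs
recovered    : r = 0.55 at -12.5 fs (max)

pair                                                r (lag fs)
O(Tyr66)-O(Wat) / cavity_volume                     0.55 (-12.5)
O(Ser205)-O(Glu222) / cavity_volume                 0.27 (287.75)   [not retained]
```

A pair generated with target correlation 0.6 at a 50-step (12.5 fs)
delay is recovered at the right lag with r within sampling error of the
target; the estimator's negative delay reads "the volume lags the
H-bond distance".  An independent control pair never crosses the 0.45
retention threshold.  The other examples cover descriptor extraction,
analytic volume checks (`56.5487 Å³` exact vs `56.5500` grid for two
overlapping r = 2 Å spheres), distribution peaks, and the full
config-driven pipeline.

## Command line

```bash
pocketdyn synth --preset gfp-toy --seed 7 -o study/   # trajectory + config
pocketdyn run -c study/config.yaml                    # full analysis
pocketdyn xcorr -c study/config.yaml --threshold 0.6  # one stage, override
```

Each run writes descriptor/volume/histogram/correlation TSVs, a
formatted `r (lag)` table, and a `manifest.json` sufficient to re-execute
the run; reruns with the same config and seed are bit-identical for the
grid volume estimator.

## Layout

- `src/pocketdyn/` — library (`trajectory`, `descriptors`, `cavity`,
  `distributions`, `crosscorr`, `synthetic`, `pipeline`, `cli`)
- `examples/` — one short narrative script per capability
- `docs/methods.md` — model assumptions, estimator choices, limitations
- `tests/` — unit, property and acceptance suites
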