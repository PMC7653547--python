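"""Synthetic trajectories and descriptor series with known correlation structure.

Sub-picosecond trajectories from ab-initio MD are expensive and rarely
redistributable, so every pipeline stage here is validated against
synthetic data whose ground truth is known exactly.  The fluctuation model
is the Ornstein–Uhlenbeck (OU) process: stationary, Gaussian, with a
tunable exponential correlation time — the minimal model reproducing
fs-scale correlated bond-distance dynamics without claiming physical
fidelity.

Coupled pairs are built on *standardized* series,

    y_k = rho * x~_{k-lag} + sqrt(1 - rho^2) * z~_k,

with x~, z~ independently standardized OU series, so ``rho`` is directly
the expected peak cross-correlation, attained at tau = -lag·dt (y lags x).
Away from the peak, r(tau) decays as the OU autocorrelation
exp(-theta·|tau - (-lag·dt)|).

The toy-pocket builder emits a full labelled trajectory in which chosen
interatomic distances *equal* prescribed coupled series exactly (each
moving atom slides along a dedicated axis from a static partner) and the
pocket's union-of-spheres volume is driven monotonically by a prescribed
breathing series — geometry chosen for exactness and invertibility, not
realism.  Defaults emulate a 2.5 ps trajectory at 0.25 fs steps
(10,000 frames).

One master seed fans out to per-stream seeds by stable hashing of stream
names, so adding a stream never perturbs existing streams.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .trajectory import AtomLabels, TimeSeries, Trajectory

__all__ = [
    "OUParams",
    "CouplingSpec",
    "GroundTruth",
    "ToyPocketConfig",
    "SyntheticError",
    "derive_seed",
    "simulate_ou",
    "standardize",
    "simulate_coupled_pair",
    "build_toy_pocket_trajectory",
    "write_xyz_trajectory",
    "write_pdb_labels",
]


class SyntheticError(ValueError):
    """Invalid generator parameters or infeasible geometry."""


def derive_seed(master_seed: int, stream: str) -> np.random.SeedSequence:
    """Per-stream seed from a master seed and a stable hash of the stream name."""
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.SeedSequence(master_seed, spawn_key=(key,))


@dataclass(frozen=True)
class OUParams:
    """Ornstein–Uhlenbeck parameters.

    Attributes
    ----------
    mean : float
        Stationary mean, series units.
    theta : float
        Relaxation rate, 1/fs (correlation time = 1/theta fs).
    sigma : float
        Noise scale, units/sqrt(fs); stationary sd = sigma/sqrt(2 theta).
    dt : float
        Timestep, fs.
    n_steps : int
    seed : int
    """

    mean: float
    theta: float
    sigma: float
    dt: float
    n_steps: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise SyntheticError(f"theta must be positive, got {self.theta}")
        if self.sigma < 0:
            raise SyntheticError(f"sigma must be nonnegative, got {self.sigma}")
        if not self.dt > 0:
            raise SyntheticError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 2:
            raise SyntheticError(f"n_steps must be >= 2, got {self.n_steps}")

    @property
    def stationary_sd(self) -> float:
        return self.sigma / np.sqrt(2.0 * self.theta)


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth coupling: target peak correlation and lag in steps.

    Positive ``lag_steps`` means y lags x, so the cross-correlation peak
    of r_xy sits at tau = -lag_steps·dt.
    """

    rho: float
    lag_steps: int
    noise_seed: int = 1

    def __post_init__(self) -> None:
        if abs(self.rho) > 1:
            raise SyntheticError(f"|rho| must be <= 1, got {self.rho}")
        if self.lag_steps < 0:
            raise SyntheticError("lag_steps must be >= 0 (y lags x)")


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to regenerate a dataset bit-identically and to
    state the expected estimator outcome."""

    base: OUParams
    coupling: CouplingSpec
    master_seed: int
    pair: tuple = ("x", "y")
    control_pair: tuple | None = None

    @property
    def expected_peak_r(self) -> float:
        """Expected peak correlation at the imposed lag (equals rho: the
        coupling is written at the lag, so no autocorrelation attenuation
        applies at the peak itself)."""
        return self.coupling.rho

    @property
    def expected_peak_lag_fs(self) -> float:
        return -self.coupling.lag_steps * self.base.dt

    def to_json(self) -> str:
        payload = {
            "base": asdict(self.base),
            "coupling": asdict(self.coupling),
            "master_seed": self.master_seed,
            "pair": list(self.pair),
            "control_pair": list(self.control_pair) if self.control_pair else None,
            "expected_peak_r": self.expected_peak_r,
            "expected_peak_lag_fs": self.expected_peak_lag_fs,
        }
        return json.dumps(payload, indent=2)


def simulate_ou(params: OUParams, x0: float | None = None,
                name: str = "ou", units: str = "") -> TimeSeries:
    """Exact-discretization OU series.

    x_{k+1} = mu + (x_k - mu) e^{-theta dt} + sigma sqrt((1 - e^{-2 theta dt})
    / (2 theta)) xi_k with xi_k standard normal; x_0 is drawn from the
    stationary law unless given explicitly.
    """
    rng = np.random.default_rng(params.seed)
    a = np.exp(-params.theta * params.dt)
    noise_sd = params.sigma * np.sqrt((1.0 - a * a) / (2.0 * params.theta))
    x = np.empty(params.n_steps)
    if x0 is None:
        x[0] = params.mean + params.stationary_sd * rng.standard_normal()
    else:
        x[0] = x0
    xi = rng.standard_normal(params.n_steps - 1)
    for k in range(params.n_steps - 1):
        x[k + 1] = params.mean + (x[k] - params.mean) * a + noise_sd * xi[k]
    return TimeSeries(name=name, values=x, dt=params.dt, units=units)


def standardize(values: np.ndarray) -> np.ndarray:
    """Sample-standardize to mean 0, variance 1 (population normalization)."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        raise SyntheticError("cannot standardize a constant series")
    return (values - values.mean()) / sd


def simulate_coupled_pair(base: OUParams, coupling: CouplingSpec,
                          x_name: str = "x", y_name: str = "y",
                          units: str = "",
                          ) -> tuple[TimeSeries, TimeSeries, GroundTruth]:
    """A pair (x, y) with peak correlation ``rho`` at lag -lag_steps·dt.

    x is an OU series; y is built from the standardized, lag-shifted x
    plus independent standardized OU noise (seed ``coupling.noise_seed``),
    then rescaled to x's mean and stationary sd so both series share units.
    """
    lag = coupling.lag_steps
    if lag >= base.n_steps // 2:
        raise SyntheticError(
            f"lag_steps {lag} must be < n_steps/2 = {base.n_steps // 2}")
    n = base.n_steps
    ext = OUParams(mean=base.mean, theta=base.theta, sigma=base.sigma,
                   dt=base.dt, n_steps=n + lag, seed=base.seed)
    x_ext = simulate_ou(ext).values
    noise = OUParams(mean=0.0, theta=base.theta, sigma=base.sigma,
                     dt=base.dt, n_steps=n, seed=coupling.noise_seed)
    z_std = standardize(simulate_ou(noise).values)
    x_std_ext = standardize(x_ext)
    y_std = coupling.rho * x_std_ext[:n] + np.sqrt(1.0 - coupling.rho ** 2) * z_std
    sd = base.stationary_sd if base.sigma > 0 else 1.0
    y_vals = base.mean + sd * y_std
    x = TimeSeries(name=x_name, values=x_ext[lag:], dt=base.dt, units=units)
    y = TimeSeries(name=y_name, values=y_vals, dt=base.dt, units=units)
    truth = GroundTruth(base=base, coupling=coupling, master_seed=base.seed,
                        pair=(x_name, y_name))
    return x, y, truth


# ---------------------------------------------------------------------------
# toy pocket trajectory


@dataclass(frozen=True)
class ToyPocketConfig:
    """Layout and coupling of the synthetic chromophore-pocket trajectory.

    Defaults emulate the study sampling (2.5 ps at 0.25 fs = 10,000
    frames) with a proton-wire-like coupled distance/volume pair
    (rho = 0.6, lag 50 steps) and an uncoupled control distance.  The OU
    correlation time is 100 steps (25 fs), a realistic fs-scale H-bond
    fluctuation memory.
    """

    n_frames: int = 10_000
    dt: float = 0.25                # fs
    seed: int = 2020
    rho: float = 0.6                # coupled-pair target peak correlation
    lag_steps: int = 50             # volume lags the driving distance
    corr_time_steps: float = 100.0  # OU correlation time, steps
    distance_mean: float = 6.0      # Å, mean of the moving-pair distances
    distance_sd: float = 0.15       # Å
    breathing_gap_mean: float = 2.0  # Å, mean center distance of breathing spheres
    breathing_gap_sd: float = 0.45   # Å
    n_filler: int = 40              # static pocket-filler atoms

    @property
    def theta(self) -> float:
        return 1.0 / (self.corr_time_steps * self.dt)


#: Series names emitted by the toy pocket.
COUPLED_DISTANCE = "O(TYR66)-O(HOH)"
CONTROL_DISTANCE = "O(SER205)-O(GLU222)"
VOLUME_NAME = "cavity_volume"


def build_toy_pocket_trajectory(config: ToyPocketConfig = ToyPocketConfig(),
                                ) -> tuple[Trajectory, GroundTruth]:
    """Labelled pseudo-pocket whose descriptors have known correlations.

    Geometry (all atoms far apart so sphere groups never interact):

    * TYR66 OH fixed at the origin; HOH O on the +x axis at distance d1(t),
      the *coupled* series (drives the volume with lag ``lag_steps``).
    * SER205 OG fixed; GLU222 OE1 on a dedicated axis at distance d2(t),
      an independent OU series — the uncoupled control pair.
    * Two "breathing" carbon spheres whose center distance follows the
      coupled partner series, so the union volume is strictly monotone in
      it while the spheres overlap.
    * ``n_filler`` static carbons well separated from everything, padding
      the pocket to study size (~50 atoms) with constant volume.

    Returns the trajectory and the ground truth of the coupled pair.
    """
    cfg = config
    n = cfg.n_frames
    base = OUParams(mean=0.0, theta=cfg.theta, sigma=np.sqrt(2.0 * cfg.theta),
                    dt=cfg.dt, n_steps=n,
                    seed=int(derive_seed(cfg.seed, "driver").generate_state(1)[0]
                             % (2 ** 31)))
    coupling = CouplingSpec(
        rho=cfg.rho, lag_steps=cfg.lag_steps,
        noise_seed=int(derive_seed(cfg.seed, "breathing-noise")
                       .generate_state(1)[0] % (2 ** 31)))
    xs, ys, truth = simulate_coupled_pair(base, coupling,
                                          x_name=COUPLED_DISTANCE,
                                          y_name=VOLUME_NAME)
    d1 = cfg.distance_mean + cfg.distance_sd * standardize(xs.values)
    breathing = standardize(ys.values)

    ctrl_params = OUParams(
        mean=cfg.distance_mean, theta=cfg.theta,
        sigma=cfg.distance_sd * np.sqrt(2.0 * cfg.theta), dt=cfg.dt,
        n_steps=n,
        seed=int(derive_seed(cfg.seed, "control").generate_state(1)[0]
                 % (2 ** 31)))
    d2 = simulate_ou(ctrl_params).values

    # breathing sphere separation, clipped to keep the spheres overlapping
    # (carbon UFF radius 1.9255 Å => strict monotonicity for s < 3.851 Å)
    s = cfg.breathing_gap_mean + cfg.breathing_gap_sd * breathing
    s = np.clip(s, 0.4, 3.4)

    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise SyntheticError("prescribed distance series reaches a "
                             "non-positive value; increase the mean or "
                             "decrease the spread")

    records = [
        ("OH", "TYR", 66, "O"),    # 0: static partner of the coupled pair
        ("O", "HOH", 301, "O"),    # 1: moving, d1(t) on +x
        ("OG", "SER", 205, "O"),   # 2: static partner of the control pair
        ("OE1", "GLU", 222, "O"),  # 3: moving, d2(t) on +y from SER
        ("C1", "POC", 900, "C"),   # 4: breathing sphere (static)
        ("C2", "POC", 900, "C"),   # 5: breathing sphere, gap s(t) on +x
    ]
    # static filler carbons on a compact 3-D grid far from the moving parts
    # (5 Å spacing keeps them pairwise disjoint: 2 x r_C = 3.851 Å)
    for m in range(cfg.n_filler):
        records.append((f"CF{m + 1}", "FIL", 950 + m, "C"))
    labels = AtomLabels.from_records(records)

    n_atoms = len(records)
    coords = np.zeros((n, n_atoms, 3))
    coords[:, 0] = (0.0, 0.0, 0.0)
    coords[:, 1, 0] = d1
    coords[:, 2] = (20.0, 0.0, 0.0)
    coords[:, 3, 0] = 20.0
    coords[:, 3, 1] = d2
    coords[:, 4] = (40.0, 0.0, 0.0)
    coords[:, 5, 0] = 40.0 + s
    for m in range(cfg.n_filler):
        gz, rem = divmod(m, 16)
        gx, gy = divmod(rem, 4)
        coords[:, 6 + m] = (60.0 + 5.0 * gx, 5.0 * gy, 5.0 * gz)

    traj = Trajectory(coordinates=coords, labels=labels, dt=cfg.dt)
    truth = GroundTruth(base=base, coupling=coupling, master_seed=cfg.seed,
                        pair=(COUPLED_DISTANCE, VOLUME_NAME),
                        control_pair=(CONTROL_DISTANCE, VOLUME_NAME))
    return traj, truth


#: The pocket selection for the toy trajectory: everything except the
#: far-field filler atoms beyond the first few (to mimic a ~44-atom pocket,
#: include the six active atoms plus 38 fillers).
def toy_pocket_selection(traj: Trajectory, n_pocket: int = 44) -> list[tuple]:
    labels = traj.labels
    sel = []
    for i in range(min(n_pocket, len(labels))):
        sel.append((str(labels.residue_name[i]), int(labels.residue_id[i]),
                    str(labels.atom_name[i])))
    return sel


# ---------------------------------------------------------------------------
# text writers (multi-frame XYZ + PDB labels + ground-truth sidecar)


def write_xyz_trajectory(traj: Trajectory, path,
                         comment: str = "synthetic pocket") -> None:
    """Write a multi-frame XYZ file (Å; 10 decimal places, so a round trip
    through the reader reproduces coordinates to 1e-10 Å)."""
    path = Path(path)
    elements = [str(e) for e in traj.labels.element]
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n{comment} frame {f}\n")
            frame = traj.coordinates[f]
            for el, (x, y, z) in zip(elements, frame):
                fh.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")


def write_pdb_labels(traj: Trajectory, path) -> None:
    """Write the topology labels (with first-frame coordinates) as PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = traj.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = traj.coordinates[0].astype(np.float32)
    arr.atom_name = np.asarray([str(a) for a in traj.labels.atom_name])
    arr.res_name = np.asarray([str(r) for r in traj.labels.residue_name])
    arr.res_id = np.asarray(traj.labels.residue_id, dtype=int)
    arr.element = np.asarray([str(e) for e in traj.labels.element])
    arr.hetero = np.asarray([rn in ("HOH", "WAT", "POC", "FIL")
                             for rn in traj.labels.residue_name])
    arr.chain_id = np.full(n, "A")
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(truth.to_json() + "\n")
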