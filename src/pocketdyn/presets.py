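"""Ready-made analysis configs for the synthetic toy pocket."""

from __future__ import annotations

from pathlib import Path

import yaml

from .synthetic import (CONTROL_DISTANCE, COUPLED_DISTANCE, ToyPocketConfig,
                        toy_pocket_selection)
from .trajectory import Trajectory

__all__ = ["toy_config_dict", "write_toy_config"]


def toy_config_dict(traj: Trajectory, cfg: ToyPocketConfig,
                    trajectory: str = "traj.xyz",
                    topology: str = "labels.pdb",
                    output_dir: str = "out",
                    grid_spacing: float = 0.2) -> dict:
    """Analysis config matching :func:`build_toy_pocket_trajectory` output.

    The descriptor roster is the coupled distance, the uncoupled control
    distance; the pocket selection covers the active atoms plus fillers up
    to 44 atoms; correlations are every descriptor against the volume.

    The lag window is capped at half the trajectory duration so every
    correlation estimate keeps at least 50% sample overlap (long-memory
    fluctuations make the extreme-lag estimates too noisy for the
    |r| > 0.45 retention rule to be meaningful there).
    """
    max_lag_fs = 0.5 * (cfg.n_frames - 1) * cfg.dt
    return {
        "trajectory": trajectory,
        "topology": topology,
        "dt": cfg.dt,
        "output_dir": output_dir,
        "descriptors": [
            {"name": COUPLED_DISTANCE, "kind": "distance",
             "atoms": [["TYR", 66, "OH"], ["HOH", 301, "O"]]},
            {"name": CONTROL_DISTANCE, "kind": "distance",
             "atoms": [["SER", 205, "OG"], ["GLU", 222, "OE1"]]},
        ],
        "selection": [list(s) for s in toy_pocket_selection(traj)],
        "volume_method": "grid",
        "grid_spacing": grid_spacing,
        "pairs": "descriptors_vs_volume",
        "threshold": 0.45,
        "max_lag_fs": max_lag_fs,
        "seed": cfg.seed,
    }


def write_toy_config(traj: Trajectory, cfg: ToyPocketConfig, path,
                     **kwargs) -> None:
    Path(path).write_text(yaml.safe_dump(
        toy_config_dict(traj, cfg, **kwargs), sort_keys=False))
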