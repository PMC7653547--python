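"""Trajectory and time-series containers plus text-format I/O.

Coordinates are Cartesian and in angstroms (Å) throughout; time is in
femtoseconds (fs) throughout.  There is no unit auto-detection and no
periodic-boundary handling: the systems of interest are single solvated
proteins treated as clusters, so distances are plain Euclidean.

The trajectory interchange format is multi-frame XYZ (an atom-count line,
a comment line, and N coordinate lines per frame).  XYZ carries no residue
information, so atom identities come from a separate PDB topology whose
coordinates are ignored — only the label columns (atom name, residue name,
residue number, element) are used.  The timestep is never parsed from XYZ
comment lines (there is no standard dialect); it is supplied explicitly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AtomLabels",
    "Trajectory",
    "TimeSeries",
    "TrajectoryError",
    "XYZParseError",
    "TopologyError",
    "read_xyz_trajectory",
    "read_topology_labels",
    "write_timeseries",
    "read_timeseries",
]


class TrajectoryError(ValueError):
    """Base error for trajectory/topology handling."""


class XYZParseError(TrajectoryError):
    """Malformed multi-frame XYZ input."""


class TopologyError(TrajectoryError):
    """Malformed or empty topology input."""


@dataclass(frozen=True)
class AtomLabels:
    """Per-atom identity labels, indexed 0-based in record order.

    PDB residue numbering is preserved verbatim so selections can use the
    crystallographic numbering (Tyr66, Ser205, Glu222, ...).
    """

    atom_name: np.ndarray      # str array, e.g. "OH"
    residue_name: np.ndarray   # str array, e.g. "TYR"
    residue_id: np.ndarray     # int array, PDB residue sequence number
    element: np.ndarray        # str array, e.g. "O"

    def __post_init__(self) -> None:
        n = len(self.atom_name)
        for name in ("residue_name", "residue_id", "element"):
            if len(getattr(self, name)) != n:
                raise TopologyError(f"label column {name!r} has length "
                                    f"{len(getattr(self, name))}, expected {n}")
        if any(e == "" for e in self.element):
            raise TopologyError("every atom must carry a non-empty element symbol")

    def __len__(self) -> int:
        return len(self.atom_name)

    @classmethod
    def from_records(cls, records) -> "AtomLabels":
        """Build from an iterable of (atom_name, residue_name, residue_id, element)."""
        an, rn, ri, el = zip(*records)
        return cls(
            atom_name=np.asarray(an, dtype=object),
            residue_name=np.asarray(rn, dtype=object),
            residue_id=np.asarray(ri, dtype=int),
            element=np.asarray(el, dtype=object),
        )


@dataclass(frozen=True)
class Trajectory:
    """Ordered frames of Cartesian coordinates with shared atom labels.

    Attributes
    ----------
    coordinates : ndarray, shape (n_frames, n_atoms, 3), Å
    labels : AtomLabels
    dt : float
        Timestep between stored frames, fs.
    t0 : float
        Time of the first frame, fs.
    """

    coordinates: np.ndarray
    labels: AtomLabels
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise TrajectoryError(f"coordinates must have shape (frames, atoms, 3), "
                                  f"got {coords.shape}")
        if coords.shape[1] != len(self.labels):
            raise TrajectoryError(f"frame atom count {coords.shape[1]} does not match "
                                  f"topology atom count {len(self.labels)}")
        if not np.all(np.isfinite(coords)):
            raise TrajectoryError("coordinates contain non-finite values")
        if not self.dt > 0:
            raise TrajectoryError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in fs."""
        return self.t0 + self.dt * np.arange(self.n_frames)

    @property
    def duration(self) -> float:
        """Time span (N-1)·dt in fs."""
        return (self.n_frames - 1) * self.dt


@dataclass(frozen=True)
class TimeSeries:
    """A named scalar series sampled at a fixed timestep.

    ``units`` is one of "A" (Å, distances), "deg" (angles), "A^3" (volumes),
    or "" for dimensionless synthetic series.
    """

    name: str
    values: np.ndarray
    dt: float
    units: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise TrajectoryError(f"series {self.name!r} must be a non-empty 1-D array")
        if not np.all(np.isfinite(vals)):
            raise TrajectoryError(f"series {self.name!r} contains non-finite values")
        if not self.dt > 0:
            raise TrajectoryError(f"series {self.name!r}: dt must be positive")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(len(self))


# ---------------------------------------------------------------------------
# multi-frame XYZ reader

def read_xyz_trajectory(path, dt: float, labels: AtomLabels | None = None,
                        t0: float = 0.0) -> Trajectory:
    """Read a multi-frame XYZ file into a :class:`Trajectory`.

    Parameters
    ----------
    path : path-like
    dt : float
        Timestep between frames in fs (not read from the file).
    labels : AtomLabels, optional
        Topology labels for the atoms, in file order.  The XYZ element
        column is cross-checked against ``labels.element``; if omitted,
        minimal labels (residue UNK 1) are synthesised from the element
        column of the first frame.
    t0 : float
        Time of the first frame, fs.

    Raises
    ------
    XYZParseError
        On atom-count mismatches (naming the frame) or non-numeric
        coordinates (naming the line).
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()

    frames: list[np.ndarray] = []
    symbols_first: list[str] = []
    pos = 0
    n_lines = len(lines)
    frame_idx = 0
    n_atoms_expected: int | None = None
    while pos < n_lines:
        if lines[pos].strip() == "" and all(l.strip() == "" for l in lines[pos:]):
            break  # trailing blank lines
        frame_idx += 1
        try:
            n_at = int(lines[pos].split()[0])
        except (ValueError, IndexError):
            raise XYZParseError(
                f"{path.name}, frame {frame_idx}: expected an atom-count line at "
                f"line {pos + 1}, got {lines[pos]!r}") from None
        if n_atoms_expected is None:
            n_atoms_expected = n_at
        elif n_at != n_atoms_expected:
            raise XYZParseError(
                f"{path.name}, frame {frame_idx}: declares {n_at} atoms, "
                f"previous frames had {n_atoms_expected}")
        if pos + 2 + n_at > n_lines:
            raise XYZParseError(
                f"{path.name}, frame {frame_idx}: declares {n_at} atoms but the "
                f"file ends after {n_lines - pos - 2} coordinate lines")
        coords = np.empty((n_at, 3))
        for a in range(n_at):
            lineno = pos + 2 + a
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"{path.name}, frame {frame_idx}, line {lineno + 1}: expected "
                    f"'element x y z', got {lines[lineno]!r}")
            try:
                coords[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise XYZParseError(
                    f"{path.name}, frame {frame_idx}, line {lineno + 1}: "
                    f"non-numeric coordinate in {lines[lineno]!r}") from None
            if frame_idx == 1:
                symbols_first.append(parts[0])
        frames.append(coords)
        pos += 2 + n_at

    if not frames:
        raise XYZParseError(f"{path.name}: no frames found")

    if labels is None:
        labels = AtomLabels.from_records(
            [(s, "UNK", 1, s) for s in symbols_first])
    else:
        if len(labels) != n_atoms_expected:
            raise XYZParseError(
                f"{path.name}: topology has {len(labels)} atoms, "
                f"file frames have {n_atoms_expected}")
        for a, (s, e) in enumerate(zip(symbols_first, labels.element)):
            if s.upper() != str(e).upper():
                raise XYZParseError(
                    f"{path.name}: atom {a} element {s!r} does not match "
                    f"topology element {e!r}")

    return Trajectory(coordinates=np.stack(frames), labels=labels, dt=dt, t0=t0)


# ---------------------------------------------------------------------------
# PDB topology labels (coordinates ignored)

def read_topology_labels(path) -> AtomLabels:
    """Read atom labels from a PDB file's ATOM/HETATM records, in record order.

    Water records (HOH/WAT) are retained; duplicate atom serials are accepted
    (indices are assigned by record order).  PDB coordinates are never used.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        structure = pdb_file.get_structure(model=1)
    except Exception as exc:
        raise TopologyError(f"{path.name}: could not parse PDB: {exc}") from exc
    if structure.array_length() == 0:
        raise TopologyError(f"{path.name}: no ATOM/HETATM records found")
    element = np.asarray([str(e) for e in structure.element], dtype=object)
    if any(e.strip() == "" for e in element):
        # fall back to the first letter of the atom name (common for minimal PDBs)
        element = np.asarray(
            [e if e.strip() else str(n)[0] for e, n in
             zip(element, structure.atom_name)], dtype=object)
    return AtomLabels(
        atom_name=np.asarray([str(a) for a in structure.atom_name], dtype=object),
        residue_name=np.asarray([str(r) for r in structure.res_name], dtype=object),
        residue_id=np.asarray(structure.res_id, dtype=int),
        element=element,
    )


# ---------------------------------------------------------------------------
# TSV time-series writer / reader

def _column_header(ts: TimeSeries) -> str:
    return f"{ts.name} [{ts.units}]" if ts.units else ts.name


def write_timeseries(series: list[TimeSeries], path) -> None:
    """Write aligned time series to a TSV with a time column in fs.

    All series must share dt and length.  Values are written with 17
    significant digits so a round-trip read reproduces them exactly
    (well within the 1e-12 contract).
    """
    if not series:
        raise TrajectoryError("no series to write")
    n = len(series[0])
    dt = series[0].dt
    bad = [ts.name for ts in series if len(ts) != n or ts.dt != dt]
    if bad:
        raise TrajectoryError(
            f"series must share length and dt; offending series: {bad}")
    frame = pd.DataFrame({"time [fs]": series[0].times})
    for ts in series:
        frame[_column_header(ts)] = ts.values
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timeseries(path) -> list[TimeSeries]:
    """Read back a TSV written by :func:`write_timeseries`."""
    frame = pd.read_csv(path, sep="\t")
    time_col = frame.columns[0]
    t = frame[time_col].to_numpy()
    if len(t) > 1:
        dt = float(t[1] - t[0])
    else:
        dt = 1.0
    out = []
    for col in frame.columns[1:]:
        if col.endswith("]") and "[" in col:
            name, _, units = col.rpartition(" [")
            units = units[:-1]
        else:
            name, units = col, ""
        out.append(TimeSeries(name=name, values=frame[col].to_numpy(),
                              dt=dt, units=units))
    return out
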