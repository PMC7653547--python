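"""Geometric descriptor time series: distances, bond angles, torsions.

These are the structural order parameters used to follow hydrogen-bond
dynamics in a chromophore pocket: heavy-atom (typically O–O or N–O)
distances along the proton wire, the bond angle of the methine bridge, and
the torsion spanned by the proton-wire oxygens.  Hydrogen-bond existence
criteria (donor–H–acceptor cutoffs) are deliberately out of scope — the
analysis operates on the raw heavy-atom distances themselves.

Angles are returned in degrees.  Torsions follow the IUPAC right-handed
sign convention in (-180°, 180°], computed with the two-normal atan2 form
for stability near 0°/180°.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trajectory import AtomLabels, TimeSeries, Trajectory

__all__ = [
    "Selector",
    "DescriptorDefinition",
    "SelectionError",
    "DescriptorError",
    "select_atom",
    "distance_series",
    "angle_series",
    "dihedral_series",
    "evaluate_descriptor",
    "evaluate_descriptors",
]

#: (residue_name, residue_id, atom_name)
Selector = tuple


class SelectionError(ValueError):
    """Atom selector resolved to zero or multiple atoms."""


class DescriptorError(ValueError):
    """Degenerate geometry or invalid descriptor definition."""


_KIND_ARITY = {"distance": 2, "angle": 3, "dihedral": 4}
_KIND_UNITS = {"distance": "A", "angle": "deg", "dihedral": "deg"}


@dataclass(frozen=True)
class DescriptorDefinition:
    """A named geometric descriptor over selected atoms.

    ``atoms`` is an ordered tuple of (residue_name, residue_id, atom_name)
    selectors: 2 for a distance, 3 for an angle (vertex is the middle
    selector), 4 for a torsion.
    """

    name: str
    kind: str  # distance | angle | dihedral
    atoms: tuple

    def __post_init__(self) -> None:
        if self.kind not in _KIND_ARITY:
            raise DescriptorError(
                f"{self.name!r}: unknown descriptor kind {self.kind!r}")
        if len(self.atoms) != _KIND_ARITY[self.kind]:
            raise DescriptorError(
                f"{self.name!r}: kind {self.kind!r} needs "
                f"{_KIND_ARITY[self.kind]} atom selectors, got {len(self.atoms)}")

    @property
    def units(self) -> str:
        return _KIND_UNITS[self.kind]


def select_atom(labels: AtomLabels, selector: Selector) -> int:
    """Resolve (residue_name, residue_id, atom_name) to a unique atom index.

    Raises :class:`SelectionError` on zero matches (naming the selector) or
    on multiple matches (listing the candidates).
    """
    if len(labels) == 0:
        raise SelectionError("empty topology")
    res_name, res_id, atom_name = selector
    hits = [
        i for i in range(len(labels))
        if str(labels.residue_name[i]).upper() == str(res_name).upper()
        and int(labels.residue_id[i]) == int(res_id)
        and str(labels.atom_name[i]).upper() == str(atom_name).upper()
    ]
    if not hits:
        raise SelectionError(f"no atom matches ({res_name}, {res_id}, {atom_name})")
    if len(hits) > 1:
        raise SelectionError(
            f"selector ({res_name}, {res_id}, {atom_name}) is ambiguous: "
            f"matches atom indices {hits}")
    return hits[0]


def _resolve(labels: AtomLabels, selectors: Sequence[Selector]) -> list[int]:
    idx = [select_atom(labels, s) for s in selectors]
    if len(set(idx)) != len(idx):
        raise SelectionError(f"selectors resolve to non-distinct atoms: {idx}")
    return idx


def distance_series(traj: Trajectory, i: int, j: int,
                    name: str | None = None) -> TimeSeries:
    """Per-frame Euclidean distance between atoms i and j, in Å."""
    if i == j:
        raise DescriptorError("distance requires two distinct atoms")
    d = np.linalg.norm(traj.coordinates[:, i] - traj.coordinates[:, j], axis=1)
    return TimeSeries(name=name or f"d({i},{j})", values=d, dt=traj.dt, units="A")


def angle_series(traj: Trajectory, i: int, j: int, k: int,
                 name: str | None = None) -> TimeSeries:
    """Per-frame bond angle i–j–k (vertex j) in degrees, range [0°, 180°].

    The cosine is clamped to [-1, 1] before arccos to absorb floating-point
    drift at exactly straight or closed configurations.
    """
    if len({i, j, k}) != 3:
        raise DescriptorError("angle requires three distinct atoms")
    a = traj.coordinates[:, i] - traj.coordinates[:, j]
    b = traj.coordinates[:, k] - traj.coordinates[:, j]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    bad = np.nonzero((na == 0) | (nb == 0))[0]
    if bad.size:
        raise DescriptorError(
            f"zero-length angle arm (coincident atoms) at frame {bad[0]}")
    cosang = np.einsum("fi,fi->f", a, b) / (na * nb)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return TimeSeries(name=name or f"angle({i},{j},{k})", values=ang,
                      dt=traj.dt, units="deg")


def dihedral_series(traj: Trajectory, i: int, j: int, k: int, l: int,
                    name: str | None = None) -> TimeSeries:
    """Per-frame signed torsion i–j–k–l in degrees, range (-180°, 180°].

    IUPAC right-handed convention: with n1 = b1×b2 and n2 = b2×b3 the plane
    normals (b1 = rj-ri etc.), the torsion is
    atan2((n1×n2)·b2_hat, n1·n2).  Satisfies the reversal symmetry
    dihedral(i,j,k,l) == dihedral(l,k,j,i).
    """
    if len({i, j, k, l}) != 4:
        raise DescriptorError("dihedral requires four distinct atoms")
    c = traj.coordinates
    b1 = c[:, j] - c[:, i]
    b2 = c[:, k] - c[:, j]
    b3 = c[:, l] - c[:, k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    bad = np.nonzero(nb2 == 0)[0]
    if bad.size:
        raise DescriptorError(f"degenerate central bond at frame {bad[0]}")
    degenerate = np.nonzero(
        (np.linalg.norm(n1, axis=1) < 1e-10) | (np.linalg.norm(n2, axis=1) < 1e-10)
    )[0]
    if degenerate.size:
        raise DescriptorError(
            f"undefined torsion (collinear arm) at frame {degenerate[0]}")
    y = np.einsum("fi,fi->f", np.cross(n1, n2), b2) / nb2
    x = np.einsum("fi,fi->f", n1, n2)
    phi = np.degrees(np.arctan2(y, x))
    # map -180 exactly to +180 so the range is (-180, 180]
    phi = np.where(phi == -180.0, 180.0, phi)
    return TimeSeries(name=name or f"dihedral({i},{j},{k},{l})", values=phi,
                      dt=traj.dt, units="deg")


def evaluate_descriptor(traj: Trajectory,
                        definition: DescriptorDefinition) -> TimeSeries:
    """Resolve a definition's selectors and compute its time series."""
    idx = _resolve(traj.labels, definition.atoms)
    if definition.kind == "distance":
        return distance_series(traj, *idx, name=definition.name)
    if definition.kind == "angle":
        return angle_series(traj, *idx, name=definition.name)
    return dihedral_series(traj, *idx, name=definition.name)


def evaluate_descriptors(traj: Trajectory,
                         definitions: Sequence[DescriptorDefinition]
                         ) -> list[TimeSeries]:
    return [evaluate_descriptor(traj, d) for d in definitions]
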