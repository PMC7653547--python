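import numpy as np
import pytest

from pocketdyn.trajectory import AtomLabels, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20201027)


def make_labels(n, element="C"):
    return AtomLabels.from_records(
        [(f"C{i}", "UNK", 1, element) for i in range(n)])


def make_trajectory(coords, dt=0.25, elements=None):
    """Trajectory from a (frames, atoms, 3) array with generic labels."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    if elements is None:
        elements = ["C"] * n_atoms
    labels = AtomLabels.from_records(
        [(f"A{i}", "UNK", 1, el) for i, el in enumerate(elements)])
    return Trajectory(coordinates=coords, labels=labels, dt=dt)


@pytest.fixture
def single_frame():
    """One frame, four atoms placed for hand-checkable geometry."""
    def _build(points):
        return make_trajectory(np.asarray(points, dtype=float)[None, :, :])
    return _build


def write_xyz(path, frames, elements):
    """Hand-rolled XYZ writer independent of the package's writer."""
    with open(path, "w") as fh:
        for f, frame in enumerate(frames):
            fh.write(f"{len(frame)}\nframe {f}\n")
            for el, (x, y, z) in zip(elements, frame):
                fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")
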