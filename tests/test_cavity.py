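"""Union-of-spheres volume: analytic oracles, estimator agreement, bounds."""

import numpy as np
import pytest

from pocketdyn.cavity import (CavityError, RadiiTable, SphereSet,
                              build_sphere_set, load_uff_radii, union_volume,
                              volume_series)
from pocketdyn.trajectory import AtomLabels, Trajectory

from conftest import make_trajectory


def sphere_ball_volume(r):
    return 4.0 / 3.0 * np.pi * r ** 3


def two_sphere_union_analytic(r, d):
    """Independent closed-form oracle: union of two equal spheres at center
    distance d via the lens formula V_lens = pi (2r-d)^2 (4r+d) / 12."""
    if d >= 2 * r:
        return 2 * sphere_ball_volume(r)
    lens = np.pi * (2 * r - d) ** 2 * (4 * r + d) / 12.0
    return 2 * sphere_ball_volume(r) - lens


def random_sphere_set(rng, m=5):
    centers = rng.uniform(-2.0, 2.0, size=(m, 3))
    radii = rng.uniform(0.8, 2.0, size=m)
    return SphereSet(centers=centers, radii=radii)


class TestRadiiTable:
    def test_packaged_uff_table_has_biomolecular_elements(self):
        table = load_uff_radii()
        for el, expected in [("H", 1.4430), ("C", 1.9255), ("N", 1.8300),
                             ("O", 1.7500), ("S", 2.0175)]:
            assert table.lookup(el) == pytest.approx(expected)

    def test_missing_element_raises(self):
        table = RadiiTable(radii={"C": 1.9})
        with pytest.raises(CavityError, match="Xx"):
            table.lookup("Xx")

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(CavityError):
            RadiiTable(radii={"C": 0.0})


class TestBuildSphereSet:
    def test_one_sphere_per_selected_atom(self):
        labels = AtomLabels.from_records(
            [("C1", "POC", 1, "C"), ("O1", "POC", 1, "O"),
             ("N1", "OTH", 2, "N")])
        traj = Trajectory(coordinates=np.arange(9.0).reshape(1, 3, 3),
                          labels=labels, dt=1.0)
        spheres = build_sphere_set(
            traj, [("POC", 1, "C1"), ("POC", 1, "O1")], load_uff_radii(),
            frame=0)
        assert len(spheres) == 2
        np.testing.assert_allclose(spheres.radii, [1.9255, 1.75])

    def test_radius_scale_applies(self):
        labels = AtomLabels.from_records([("O1", "POC", 1, "O")])
        traj = Trajectory(coordinates=np.zeros((1, 1, 3)), labels=labels,
                          dt=1.0)
        spheres = build_sphere_set(traj, [("POC", 1, "O1")], load_uff_radii(),
                                   frame=0, radius_scale=1.1)
        assert spheres.radii[0] == pytest.approx(1.75 * 1.1)

    def test_missing_radius_and_empty_selection(self):
        labels = AtomLabels.from_records([("X1", "POC", 1, "Xx")])
        traj = Trajectory(coordinates=np.zeros((1, 1, 3)), labels=labels,
                          dt=1.0)
        with pytest.raises(CavityError, match="Xx"):
            build_sphere_set(traj, [("POC", 1, "X1")], load_uff_radii(), 0)
        with pytest.raises(CavityError):
            build_sphere_set(traj, [], load_uff_radii(), 0)


class TestUnionVolume:
    def test_single_sphere_grid(self):
        s = SphereSet(centers=[[0.0, 0.0, 0.0]], radii=[2.0])
        est = union_volume(s, method="grid", grid_spacing=0.05)
        assert est.volume == pytest.approx(sphere_ball_volume(2.0), rel=0.005)

    def test_disjoint_spheres_add(self):
        s = SphereSet(centers=[[0.0, 0, 0], [10.0, 0, 0]], radii=[1.0, 1.0])
        est = union_volume(s, method="grid", grid_spacing=0.05)
        assert est.volume == pytest.approx(2 * sphere_ball_volume(1.0),
                                           rel=0.005)

    @pytest.mark.parametrize("d", [0.5, 1.0, 2.0, 3.0])
    def test_overlapping_pair_matches_lens_oracle(self, d):
        s = SphereSet(centers=[[0.0, 0, 0], [d, 0, 0]], radii=[2.0, 2.0])
        est = union_volume(s, method="grid", grid_spacing=0.05)
        assert est.volume == pytest.approx(two_sphere_union_analytic(2.0, d),
                                           rel=0.01)

    def test_monte_carlo_matches_analytic_within_errors(self):
        s = SphereSet(centers=[[0.0, 0, 0], [2.0, 0, 0]], radii=[2.0, 2.0])
        est = union_volume(s, method="monte_carlo", n_samples=10 ** 6, seed=7)
        exact = two_sphere_union_analytic(2.0, 2.0)
        assert abs(est.volume - exact) < 4 * est.stochastic_error

    def test_monte_carlo_deterministic_given_seed(self):
        s = SphereSet(centers=[[0.0, 0, 0]], radii=[1.5])
        a = union_volume(s, method="monte_carlo", n_samples=10 ** 4, seed=3)
        b = union_volume(s, method="monte_carlo", n_samples=10 ** 4, seed=3)
        assert a.volume == b.volume

    def test_pruning_is_bit_identical(self, rng):
        # a small sphere swallowed by a big one plus random others
        centers = np.vstack([[0, 0, 0], [0.2, 0, 0],
                             rng.uniform(-2, 2, size=(3, 3))])
        radii = np.array([2.0, 0.5, 1.0, 1.2, 0.9])
        s = SphereSet(centers=centers, radii=radii)
        for method, kw in (("grid", {"grid_spacing": 0.1}),
                           ("monte_carlo", {"n_samples": 10 ** 4, "seed": 5})):
            a = union_volume(s, method=method, prune=True, **kw)
            b = union_volume(s, method=method, prune=False, **kw)
            assert a.volume == b.volume

    def test_bounds_hold_on_random_sets(self, rng):
        for _ in range(10):
            s = random_sphere_set(rng)
            est = union_volume(s, method="grid", grid_spacing=0.05)
            vols = sphere_ball_volume(s.radii)
            assert est.volume <= vols.sum() * 1.01
            assert est.volume >= vols.max() * 0.99

    def test_adding_sphere_and_growing_radius_monotone(self, rng):
        s = random_sphere_set(rng, m=4)
        base = union_volume(s, grid_spacing=0.05).volume
        bigger = SphereSet(centers=np.vstack([s.centers, [[5.0, 0, 0]]]),
                           radii=np.append(s.radii, 1.0))
        assert union_volume(bigger, grid_spacing=0.05).volume > base
        grown = SphereSet(centers=s.centers,
                          radii=s.radii + np.array([0.3, 0, 0, 0]))
        assert union_volume(grown, grid_spacing=0.05).volume >= base

    def test_grid_refinement_converges(self):
        """|V(h/2) - V(h)| stays below |V(h) - exact| on a single sphere."""
        s = SphereSet(centers=[[0.0, 0, 0]], radii=[2.0])
        exact = sphere_ball_volume(2.0)
        vh = union_volume(s, grid_spacing=0.1).volume
        vh2 = union_volume(s, grid_spacing=0.05).volume
        assert abs(vh2 - vh) <= abs(vh - exact) + 1e-9

    def test_parameter_validation(self):
        s = SphereSet(centers=[[0.0, 0, 0]], radii=[1.0])
        with pytest.raises(CavityError):
            union_volume(s, method="grid", grid_spacing=0.0)
        with pytest.raises(CavityError):
            union_volume(s, method="monte_carlo", n_samples=10)
        with pytest.raises(CavityError):
            union_volume(s, method="tessellation")


class TestVolumeSeries:
    def _traj(self, coords):
        return make_trajectory(coords, elements=["C"] * coords.shape[1])

    def _selection(self, traj):
        return [(str(traj.labels.residue_name[i]),
                 int(traj.labels.residue_id[i]),
                 str(traj.labels.atom_name[i]))
                for i in range(traj.n_atoms)]

    def test_rigid_trajectory_gives_constant_series(self):
        frame = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        traj = self._traj(np.repeat(frame[None], 5, axis=0))
        ts = volume_series(traj, self._selection(traj), load_uff_radii(),
                           grid_spacing=0.1)
        assert len(ts) == 5
        assert np.ptp(ts.values) == 0.0
        assert ts.units == "A^3"

    def test_separating_spheres_volume_increases(self):
        # two overlapping spheres pulled apart frame by frame
        gaps = np.linspace(1.0, 3.5, 6)
        coords = np.zeros((6, 2, 3))
        coords[:, 1, 0] = gaps
        traj = self._traj(coords)
        ts = volume_series(traj, self._selection(traj), load_uff_radii(),
                           grid_spacing=0.05)
        assert np.all(np.diff(ts.values) > 0)

    def test_mc_series_reproducible_from_master_seed(self):
        coords = np.zeros((3, 2, 3))
        coords[:, 1, 0] = [2.0, 2.2, 2.4]
        traj = self._traj(coords)
        kw = dict(method="monte_carlo", n_samples=10 ** 4, master_seed=11)
        a = volume_series(traj, self._selection(traj), load_uff_radii(), **kw)
        b = volume_series(traj, self._selection(traj), load_uff_radii(), **kw)
        np.testing.assert_array_equal(a.values, b.values)
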