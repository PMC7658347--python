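"""Map simulation, correlation, rigid-body fitting, zone masks and ligand scoring."""

import numpy as np
import pytest

from tuscmorph.densitymaps import (
    DensityError,
    DensityMap,
    SimulationParams,
    atom_zone_mask,
    cross_correlation,
    ligand_site_score,
    read_mrc,
    rigid_body_fit,
    simulate_density,
    write_mrc,
    zone_mask,
)
from tuscmorph.superpose import RigidTransform, rmsd_between
from tuscmorph.synthetic import ideal_helix_ca


def rot_z(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])


class TestSimulateDensity:
    def test_single_atom_peak_and_decay(self):
        m = simulate_density(np.array([[0.0, 0.0, 0.0]]), SimulationParams(resolution=4.0), 1.0)
        peak = np.unravel_index(np.argmax(m.values), m.shape)
        np.testing.assert_allclose(m.grid_to_world(np.array(peak)), [0, 0, 0], atol=m.voxel_size)
        # monotonic decay along +x from the peak
        line = m.values[peak[0]:, peak[1], peak[2]]
        assert np.all(np.diff(line) <= 1e-12)

    def test_two_distant_atoms_equal_peaks(self):
        atoms = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        m = simulate_density(atoms, SimulationParams(resolution=4.0), 1.0)
        mid = m.world_to_grid(np.array([25.0, 0, 0]))[0]
        left = m.values[: int(mid)].max()
        right = m.values[int(mid):].max()
        assert left == pytest.approx(right, abs=1e-9)

    def test_mass_conservation(self):
        p = SimulationParams(resolution=5.0)
        p4 = SimulationParams(resolution=5.0, padding=4.0 * p.sigma)
        atoms = np.array([[0.0, 0, 0], [6.0, 2, 1], [3.0, -4, 2]])
        m = simulate_density(atoms, p4, 0.8)
        mass = m.values.sum() * m.voxel_size**3
        expected = len(atoms) * (2 * np.pi * p.sigma**2) ** 1.5
        assert mass == pytest.approx(expected, rel=0.01)

    def test_sampling_guard(self):
        with pytest.raises(DensityError, match="voxel"):
            simulate_density(np.zeros((1, 3)), SimulationParams(resolution=1.0), 1.0)

    def test_commutes_with_rigid_motion(self):
        from scipy import ndimage

        helix = ideal_helix_ca(15)
        p = SimulationParams(resolution=5.0)
        rot = rot_z(25.0)
        t = np.array([3.0, -2.0, 1.0])
        sim_moved = simulate_density(helix @ rot.T + t, p, 0.5)
        sim_orig = simulate_density(helix, p, 0.5)
        # pull the original simulation through the rigid motion onto sim_moved's
        # grid: value at world x equals the original field at R⁻¹(x − t)
        idx = np.indices(sim_moved.shape, dtype=float)
        world = sim_moved.origin[:, None, None, None] + idx * sim_moved.voxel_size
        back = np.einsum("ij,jabc->iabc", rot.T, world - t[:, None, None, None])
        g = (back - sim_orig.origin[:, None, None, None]) / sim_orig.voxel_size
        resampled = ndimage.map_coordinates(
            sim_orig.values, g.reshape(3, -1), order=3, mode="constant", cval=0.0
        ).reshape(sim_moved.shape)
        res_map = DensityMap(resampled, sim_moved.voxel_size, sim_moved.origin)
        assert cross_correlation(sim_moved, res_map).cc > 0.999


class TestCrossCorrelation:
    @pytest.fixture
    def helix_map(self):
        return simulate_density(ideal_helix_ca(15), SimulationParams(resolution=5.0), 1.0)

    def test_self_correlation_is_one(self, helix_map):
        assert cross_correlation(helix_map, helix_map).cc == pytest.approx(1.0, abs=1e-12)

    def test_negation_gives_minus_one(self, helix_map):
        neg = DensityMap(-helix_map.values, helix_map.voxel_size, helix_map.origin)
        assert cross_correlation(helix_map, neg, about_mean=True).cc == pytest.approx(-1.0, abs=1e-12)

    def test_additive_noise_closed_form(self, helix_map):
        snr = 10.0
        sigma = helix_map.values.std() / snr
        ccs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = DensityMap(
                helix_map.values + rng.normal(0, sigma, helix_map.shape),
                helix_map.voxel_size,
                helix_map.origin,
            )
            ccs.append(cross_correlation(helix_map, noisy, about_mean=True).cc)
        expected = snr / np.sqrt(snr**2 + 1)
        assert np.mean(ccs) == pytest.approx(expected, rel=0.02)

    def test_symmetric_and_scale_invariant(self, helix_map):
        rng = np.random.default_rng(1)
        other = DensityMap(
            helix_map.values + rng.normal(0, 0.1, helix_map.shape),
            helix_map.voxel_size,
            helix_map.origin,
        )
        ab = cross_correlation(helix_map, other).cc
        ba = cross_correlation(other, helix_map).cc
        assert abs(ab - ba) < 1e-9
        scaled = DensityMap(3.0 * other.values + 2.0, other.voxel_size, other.origin)
        assert cross_correlation(helix_map, scaled, about_mean=True).cc == pytest.approx(ab, abs=1e-9)

    def test_zero_variance_rejected(self, helix_map):
        flat = DensityMap(np.ones(helix_map.shape), helix_map.voxel_size, helix_map.origin)
        with pytest.raises(DensityError, match="zero-variance"):
            cross_correlation(helix_map, flat, about_mean=True)

    def test_disjoint_maps_rejected(self, helix_map):
        far = DensityMap(helix_map.values.copy(), helix_map.voxel_size, helix_map.origin + 1000.0)
        with pytest.raises(DensityError, match="disjoint"):
            cross_correlation(helix_map, far)


class TestRigidBodyFit:
    @pytest.fixture
    def helix(self):
        return ideal_helix_ca(20)

    @pytest.fixture
    def helix_map(self, helix):
        return simulate_density(helix, SimulationParams(resolution=6.0), 1.0)

    def test_fit_from_truth_stays_put(self, helix, helix_map):
        t, _ = rigid_body_fit(helix, helix_map)
        moved = t.apply(helix)
        assert np.linalg.norm(moved - helix, axis=1).max() < 0.01

    def test_recovers_2A_5deg_perturbation(self, helix, helix_map):
        cen = helix.mean(axis=0)
        rot = rot_z(5.0)
        shift = np.array([1.2, -1.0, 1.0])  # |shift| = 1.86 Å
        pert = RigidTransform(rot, cen - rot @ cen + shift)
        t, _ = rigid_body_fit(pert.apply(helix), helix_map)
        net = t.compose(pert)  # should be identity
        assert net.angle_degrees() < 0.5
        assert rmsd_between(net.apply(helix), helix) < 0.1

    def test_local_optimality_against_random_perturbations(self, helix, helix_map):
        from tuscmorph.densitymaps import _MapScorer

        t, score = rigid_body_fit(helix, helix_map)
        scorer = _MapScorer(helix_map)
        fitted = t.apply(helix)
        rng = np.random.default_rng(123)
        for _ in range(50):
            d = rng.normal(size=3)
            d *= rng.uniform(0, 1.0) / np.linalg.norm(d)
            assert score >= scorer(fitted + d) - 1e-9

    def test_out_of_bounds_start_rejected(self, helix, helix_map):
        with pytest.raises(DensityError, match="bounds"):
            rigid_body_fit(helix + 500.0, helix_map)


class TestZoneMask:
    def test_radius_zero_off_center_atoms_unchanged(self):
        m = DensityMap(np.ones((4, 4, 4)), 1.0, np.zeros(3))
        atoms = np.array([[1.5, 1.5, 1.5]])  # off every voxel center
        out = zone_mask(m, atoms, 0.0, "remove")
        np.testing.assert_array_equal(out.values, m.values)

    def test_keep_plus_remove_partitions_map(self):
        rng = np.random.default_rng(4)
        m = DensityMap(rng.normal(size=(8, 8, 8)), 1.0, np.zeros(3))
        atoms = rng.uniform(0, 7, size=(5, 3))
        kept = zone_mask(m, atoms, 2.0, "keep")
        removed = zone_mask(m, atoms, 2.0, "remove")
        np.testing.assert_allclose(kept.values + removed.values, m.values)

    def test_exact_voxel_count_radius_1_5(self):
        m = DensityMap(np.ones((5, 5, 5)), 1.0, np.zeros(3))
        atom = np.array([[2.0, 2.0, 2.0]])
        out = zone_mask(m, atom, 1.5, "remove")
        # centers within 1.5 Å of (2,2,2): 1 center + 6 faces + 12 edges = 19
        assert int((out.values == 0).sum()) == 19

    def test_remove_is_idempotent(self):
        rng = np.random.default_rng(5)
        m = DensityMap(rng.normal(size=(6, 6, 6)), 1.0, np.zeros(3))
        atoms = np.array([[3.0, 3.0, 3.0]])
        once = zone_mask(m, atoms, 1.2, "remove")
        twice = zone_mask(once, atoms, 1.2, "remove")
        np.testing.assert_array_equal(once.values, twice.values)

    def test_empty_atom_list(self):
        m = DensityMap(np.ones((3, 3, 3)), 1.0, np.zeros(3))
        np.testing.assert_array_equal(zone_mask(m, np.zeros((0, 3)), 2.0, "remove").values, m.values)
        np.testing.assert_array_equal(zone_mask(m, np.zeros((0, 3)), 2.0, "keep").values, 0.0)


def _toy_nucleotide():
    """Synthetic GTP-like coordinates: base/sugar atoms and α/β/γ phosphates in a row.

    Atom spacing is uniform (~2.4 Å, the P–P repeat) so every moiety zone sees
    comparable Gaussian overlap from its neighbours.
    """
    core = np.array([[0.0, 0, 0], [2.4, 0.0, 0], [4.8, 0.0, 0]])
    pa = np.array([[7.2, 0.0, 0.0]])
    pb = np.array([[9.6, 0.0, 0.0]])
    pg = np.array([[12.0, 0.0, 0.0]])
    return core, pa, pb, pg


class TestLigandSiteScore:
    def test_gdp_map_flags_gdp_like(self):
        core, pa, pb, pg = _toy_nucleotide()
        gdp_atoms = np.vstack([core, pa, pb])  # no γ-phosphate
        m = simulate_density(gdp_atoms, SimulationParams(resolution=3.6), 0.8)
        rep = ligand_site_score(
            m,
            {"nucleotide_core": np.vstack([core, pa, pb]), "gamma_phosphate": pg},
            radius=1.5,
        )
        assert rep.ratio is not None and rep.ratio < 0.5
        assert rep.label == "GDP-like"

    def test_gtp_map_not_gdp_like(self):
        core, pa, pb, pg = _toy_nucleotide()
        gtp_atoms = np.vstack([core, pa, pb, pg])
        m = simulate_density(gtp_atoms, SimulationParams(resolution=3.6), 0.8)
        rep = ligand_site_score(
            m,
            {"nucleotide_core": np.vstack([core, pa, pb]), "gamma_phosphate": pg},
            radius=1.5,
        )
        assert rep.ratio == pytest.approx(1.0, abs=0.2)
        assert rep.label == "GTP-like"

    def test_uniform_zero_map_indeterminate(self):
        core, pa, pb, pg = _toy_nucleotide()
        m = DensityMap(np.zeros((20, 20, 20)), 1.0, np.array([-5.0, -5.0, -5.0]))
        rep = ligand_site_score(
            m, {"nucleotide_core": np.vstack([core, pa, pb]), "gamma_phosphate": pg}, radius=1.5
        )
        assert rep.ratio is None
        assert rep.label == "indeterminate"


class TestMrcRoundTrip:
    def test_write_read_preserves_grid(self, tmp_path):
        rng = np.random.default_rng(6)
        m = DensityMap(rng.normal(size=(7, 9, 11)), 1.25, np.array([2.0, -3.0, 4.0]))
        path = tmp_path / "toy.mrc"
        write_mrc(m, path)
        back = read_mrc(path)
        assert back.voxel_size == pytest.approx(m.voxel_size, rel=1e-5)
        np.testing.assert_allclose(back.origin, m.origin, atol=1e-4)
        np.testing.assert_allclose(back.values, m.values, atol=1e-5)
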