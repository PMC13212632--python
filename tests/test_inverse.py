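import itertools

import numpy as np
import pytest

from sepmap.forward import SolverConfig, dipole_rhs, solve_potential, current_density
from sepmap.inverse import (
    OmpConfig,
    StandardizedPowerMap,
    omp_localize,
    peak_source_coordinate,
    reconstruct_current_density,
    sloreta_localize,
)
from sepmap.leadfield import LeadFieldMatrix


def random_dictionary(m=24, n_vox=200, seed=0, spacing=2.0):
    rng = np.random.default_rng(seed)
    gain = rng.normal(size=(m, 3 * n_vox))
    side = int(np.ceil(n_vox ** (1 / 3)))
    vox = np.array(list(itertools.product(range(side), repeat=3)))[:n_vox]
    return LeadFieldMatrix(
        gain, [f"E{i:02d}" for i in range(m)], "E00", vox, spacing
    )


class TestOmp:
    def test_single_atom_recovered_exactly(self):
        L = random_dictionary(seed=1)
        phi = 3.7 * L.gain[:, 17]
        est = omp_localize(L, phi)
        assert list(est.columns) == [17]
        assert est.weights[0] == pytest.approx(3.7)
        assert est.relative_residual < 1e-12

    def test_two_atoms_match_exhaustive_pair_search(self):
        L = random_dictionary(m=16, n_vox=60, seed=2)
        A = L.gain
        phi = 2.0 * A[:, 11] - 1.5 * A[:, 95]
        est = omp_localize(L, phi)
        assert set(est.columns) == {11, 95}
        # combinatorial oracle: best least-squares fit over all column pairs
        best, best_res = None, np.inf
        for i, j in itertools.combinations(range(A.shape[1]), 2):
            sub = A[:, [i, j]]
            w, *_ = np.linalg.lstsq(sub, phi, rcond=None)
            r = np.linalg.norm(phi - sub @ w)
            if r < best_res:
                best, best_res = {i, j}, r
        assert set(est.columns) == best

    def test_budget_caps_selection_at_five(self):
        L = random_dictionary(m=32, n_vox=250, seed=3)
        rng = np.random.default_rng(4)
        cols = rng.choice(L.gain.shape[1], size=10, replace=False)
        phi = L.gain[:, cols] @ rng.uniform(0.5, 2.0, size=10)
        est = omp_localize(L, phi, OmpConfig(saturation=0.0))
        assert len(est) <= 5

    def test_residual_history_strictly_decreasing(self):
        L = random_dictionary(m=32, n_vox=250, seed=5)
        rng = np.random.default_rng(6)
        phi = L.gain @ rng.normal(size=L.gain.shape[1]) * 0.01
        est = omp_localize(L, phi, OmpConfig(saturation=0.0))
        h = est.residual_norms
        assert all(b < a for a, b in zip(h[:-1], h[1:]))

    def test_zero_input_rejected(self):
        L = random_dictionary()
        with pytest.raises(ValueError, match="zero"):
            omp_localize(L, np.zeros(L.n_electrodes))

    def test_saturation_stops_early(self):
        L = random_dictionary(m=24, n_vox=200, seed=7)
        rng = np.random.default_rng(8)
        noise = rng.normal(size=24) * 1e-6
        phi = L.gain[:, 42] + noise
        est = omp_localize(L, phi, OmpConfig(k_max=5, saturation=0.5))
        assert len(est) < 5
        assert est.columns[0] == 42

    def test_duplicate_column_harmless(self):
        L = random_dictionary(m=16, n_vox=40, seed=9)
        L.gain[:, 30] = L.gain[:, 12]  # exact duplicate atom
        phi = 1.3 * L.gain[:, 12]
        est = omp_localize(L, phi)
        assert est.columns[0] in (12, 30)
        assert est.relative_residual < 1e-12

    def test_block_selection_picks_whole_voxel(self):
        L = random_dictionary(m=24, n_vox=80, seed=10)
        moment = np.array([1.0, -0.5, 2.0])
        phi = L.voxel_column_block(33) @ moment
        est = omp_localize(L, phi, OmpConfig(k_max=3, block_selection=True))
        assert set(est.columns) == {99, 100, 101}
        np.testing.assert_allclose(np.sort(est.weights), np.sort(moment), atol=1e-9)


class TestReconstruction:
    def test_single_dipole_scales_unit_field(self, two_layer_vol, L_recip, two_layer_system):
        phi = 2.5 * L_recip.gain[:, 6]
        est = omp_localize(L_recip, phi)
        field = reconstruct_current_density(est, two_layer_vol, system=two_layer_system)
        vox = tuple(est.voxels[0])
        axis = int(est.axes[0])
        pf = solve_potential(
            two_layer_system, dipole_rhs(two_layer_system, vox, axis, 1.0), SolverConfig()
        )
        unit = current_density(two_layer_vol, pf).j
        unit[~two_layer_vol.gray_matter_mask] = 0.0
        np.testing.assert_allclose(field.j, est.weights[0] * unit, rtol=1e-6, atol=1e-12)

    def test_two_dipole_linearity(self, two_layer_vol, L_recip, two_layer_system):
        import copy

        phi = 1.0 * L_recip.gain[:, 3] - 2.0 * L_recip.gain[:, 40]
        est = omp_localize(L_recip, phi)
        assert len(est) == 2
        total = reconstruct_current_density(est, two_layer_vol, system=two_layer_system)
        parts = np.zeros_like(total.j)
        for i in range(2):
            single = copy.copy(est)
            single.columns = est.columns[i : i + 1]
            single.voxels = est.voxels[i : i + 1]
            single.axes = est.axes[i : i + 1]
            single.weights = est.weights[i : i + 1]
            parts += reconstruct_current_density(
                single, two_layer_vol, system=two_layer_system
            ).j
        np.testing.assert_allclose(total.j, parts, rtol=1e-6, atol=1e-14)

    def test_field_zero_outside_gray_matter(self, two_layer_vol, L_recip, two_layer_system):
        est = omp_localize(L_recip, L_recip.gain[:, 0])
        field = reconstruct_current_density(est, two_layer_vol, system=two_layer_system)
        assert np.all(field.j[~two_layer_vol.gray_matter_mask] == 0.0)

    def test_empty_estimate_warns_and_returns_zero(self, two_layer_vol):
        est = omp_localize(random_dictionary(), random_dictionary().gain[:, 0])
        est.columns = est.columns[:0]
        est.voxels = est.voxels[:0]
        est.axes = est.axes[:0]
        est.weights = est.weights[:0]
        with pytest.warns(RuntimeWarning, match="empty"):
            field = reconstruct_current_density(est, two_layer_vol)
        assert np.all(field.j == 0.0)


class TestSloreta:
    def test_null_data_gives_zero_map(self, sloreta_testbed):
        _, _, L = sloreta_testbed
        m = sloreta_localize(L, np.zeros(L.n_electrodes))
        assert np.all(m.power == 0.0)

    def test_zero_localization_error_single_source(self, sloreta_testbed):
        _, _, L = sloreta_testbed
        rng = np.random.default_rng(3)
        for v in rng.choice(L.n_sources, size=12, replace=False):
            moment = rng.normal(size=3) * 1e-9
            phi = L.voxel_column_block(int(v)) @ moment
            m = sloreta_localize(L, phi, regularization=1e-18)
            peak = peak_source_coordinate(m)
            np.testing.assert_allclose(peak, L.source_coordinates_mm()[v])

    def test_minimum_norm_peak_is_shallower_than_sloreta(self, sloreta_testbed):
        vol, _, L = sloreta_testbed
        center = np.array([14.0, 14.0, 14.0])
        depths = np.linalg.norm(L.source_coordinates_mm() - center, axis=1)
        deep = int(np.argmin(depths))  # most central source
        phi = L.voxel_column_block(deep) @ np.array([0.0, 1e-9, 0.5e-9])
        m = sloreta_localize(L, phi, regularization=1e-18, return_mn=True)
        mn_power = np.sum(m.moments**2, axis=1)
        r_mn = depths[int(np.argmax(mn_power))]
        r_slo = depths[int(np.argmax(m.power))]
        assert r_mn >= r_slo

    def test_negative_regularization_rejected(self, sloreta_testbed):
        _, _, L = sloreta_testbed
        with pytest.raises(ValueError):
            sloreta_localize(L, np.ones(L.n_electrodes), regularization=-1.0)


class TestPeakCoordinate:
    def test_power_map_single_voxel(self):
        vox = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        coords = (vox + 0.5) * 2.0
        m = StandardizedPowerMap(np.array([0.0, 5.0, 0.0]), vox, coords, 0.0)
        np.testing.assert_allclose(peak_source_coordinate(m), coords[1])

    def test_tie_breaks_to_lowest_linear_index(self):
        vox = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        coords = (vox + 0.5) * 2.0
        m = StandardizedPowerMap(np.array([0.0, 5.0, 5.0]), vox, coords, 0.0)
        np.testing.assert_allclose(peak_source_coordinate(m), coords[1])

    def test_all_zero_map_rejected(self):
        vox = np.array([[0, 0, 0]])
        m = StandardizedPowerMap(np.zeros(1), vox, (vox + 0.5) * 2.0, 0.0)
        with pytest.raises(ValueError):
            peak_source_coordinate(m)

    def test_centroid_of_symmetric_pair_is_midpoint(self):
        L = random_dictionary(m=16, n_vox=60, seed=11)
        phi = L.gain[:, 9] + L.gain[:, 150]
        est = omp_localize(L, phi)
        mid = peak_source_coordinate(est, mode="centroid")
        expect = 0.5 * (L.column_coordinate_mm(9) + L.column_coordinate_mm(150))
        np.testing.assert_allclose(mid, expect, atol=1e-9)

    def test_strongest_atom_mode(self):
        L = random_dictionary(m=16, n_vox=60, seed=12)
        phi = 5.0 * L.gain[:, 30] + 0.5 * L.gain[:, 100]
        est = omp_localize(L, phi)
        np.testing.assert_allclose(
            peak_source_coordinate(est, mode="strongest"), L.column_coordinate_mm(30)
        )

    def test_reconstruction_mode_peaks_at_source(
        self, two_layer_vol, L_recip, two_layer_system
    ):
        col = 21
        phi = 2.0 * L_recip.gain[:, col]
        est = omp_localize(L_recip, phi)
        peak = peak_source_coordinate(est, mode="reconstruction", vol=two_layer_vol)
        true = L_recip.column_coordinate_mm(col)
        assert np.linalg.norm(peak - true) <= 2.0 * np.sqrt(3) * 2.0


def test_exact_support_recovery_small():
    # noiseless 2-sparse recovery across seeds on a well-separated dictionary
    for seed in range(5):
        L = random_dictionary(m=32, n_vox=150, seed=seed)
        rng = np.random.default_rng(100 + seed)
        cols = rng.choice(L.gain.shape[1], size=2, replace=False)
        phi = L.gain[:, cols] @ rng.uniform(1.0, 2.0, size=2)
        est = omp_localize(L, phi, OmpConfig(k_max=2))
        assert set(est.columns) == set(cols)
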