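import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import fftconvolve

from sepmap.phantom import (
    ColeColeParams,
    EPS0,
    PhantomSpec,
    PlantedSource,
    build_layered_sphere,
    cole_cole_conductivity,
    fibonacci_layout,
    noise_sd_for_snr,
    place_electrodes,
    simulate_sep_dataset,
    smooth_conductivity,
    ten_ten_layout,
)


def make_spec(**kw):
    base = dict(
        layer_radii=(10.0, 13.0),
        layer_conductivities=(0.33, 0.1),
        grid_shape=(16, 16, 16),
        spacing_mm=2.0,
    )
    base.update(kw)
    return PhantomSpec(**base)


class TestLayeredSphere:
    def test_outer_shell_gets_skin_conductivity(self):
        spec = make_spec(
            layer_radii=(8.0, 10.0, 13.0), layer_conductivities=(0.33, 0.02, 0.1)
        )
        vol = build_layered_sphere(spec)
        centers = np.stack(
            np.meshgrid(*[(np.arange(16) + 0.5) * 2.0] * 3, indexing="ij"), axis=-1
        )
        r = np.linalg.norm(centers - np.asarray(spec.center_mm), axis=-1)
        outer = (r > 10.0) & (r <= 13.0)
        assert np.all(vol.sigma[outer] == 0.1)
        assert np.all(vol.sigma[r > 13.0] == 0.0)

    def test_uniform_sphere_inside_one_outside_zero(self):
        spec = make_spec(layer_radii=(12.0,), layer_conductivities=(1.0,))
        vol = build_layered_sphere(spec)
        centers = np.stack(
            np.meshgrid(*[(np.arange(16) + 0.5) * 2.0] * 3, indexing="ij"), axis=-1
        )
        r = np.linalg.norm(centers - np.asarray(spec.center_mm), axis=-1)
        assert np.all(vol.sigma[r <= 12.0] == 1.0)
        assert np.all(vol.sigma[r > 12.0] == 0.0)

    def test_voxel_count_matches_containment_oracle(self):
        # brute-force voxel-center containment loop + 2% volume check
        radius, h, n = 20.0, 1.0, 48
        spec = PhantomSpec((radius,), (1.0,), (n, n, n), h)
        vol = build_layered_sphere(spec)
        count = 0
        c = np.asarray(spec.center_mm)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    p = (np.array([i, j, k]) + 0.5) * h
                    if np.linalg.norm(p - c) <= radius:
                        count += 1
        assert int(vol.head_mask.sum()) == count
        analytic = 4.0 / 3.0 * math.pi * radius**3 / h**3
        assert abs(count - analytic) / analytic < 0.02

    def test_sphere_exceeding_grid_names_radius(self):
        with pytest.raises(ValueError, match="17"):
            build_layered_sphere(make_spec(layer_radii=(10.0, 17.0)))

    def test_axis_permutation_consistency(self):
        spec = PhantomSpec(
            (6.0, 9.0), (0.3, 0.1), (12, 14, 16), 2.0, center_mm=(11.0, 13.0, 15.0)
        )
        vol = build_layered_sphere(spec)
        perm = PhantomSpec(
            (6.0, 9.0), (0.3, 0.1), (16, 12, 14), 2.0, center_mm=(15.0, 11.0, 13.0)
        )
        vol_p = build_layered_sphere(perm)
        assert np.array_equal(vol_p.sigma, np.transpose(vol.sigma, (2, 0, 1)))

    def test_mask_inside_conductor(self, two_layer_vol):
        assert two_layer_vol.gray_matter_mask.sum() > 0
        assert np.all(two_layer_vol.sigma[two_layer_vol.gray_matter_mask] > 0)

    def test_radii_must_increase(self):
        with pytest.raises(ValueError):
            make_spec(layer_radii=(13.0, 10.0))


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, two_layer_vol):
        out = smooth_conductivity(two_layer_vol, 0.0)
        assert np.array_equal(out.sigma, two_layer_vol.sigma)

    def test_uniform_head_unchanged(self):
        vol = build_layered_sphere(make_spec(layer_radii=(12.0,), layer_conductivities=(0.4,)))
        out = smooth_conductivity(vol, 4.0)
        np.testing.assert_allclose(out.sigma[vol.head_mask], 0.4, rtol=1e-10)

    def test_negative_fwhm_rejected(self, two_layer_vol):
        with pytest.raises(ValueError):
            smooth_conductivity(two_layer_vol, -1.0)

    def test_step_softened_and_matches_direct_convolution(self, two_layer_vol):
        out = smooth_conductivity(two_layer_vol, 2.0)
        jump_in = max(
            np.abs(np.diff(two_layer_vol.sigma, axis=a)).max() for a in range(3)
        )
        jump_out = max(np.abs(np.diff(out.sigma, axis=a)).max() for a in range(3))
        assert jump_out < jump_in
        # independent oracle: explicit truncated-Gaussian kernel convolution,
        # renormalized by the convolved support
        s_vox = 2.0 / (2.0 * math.sqrt(2.0 * math.log(2.0))) / two_layer_vol.spacing_mm
        half = int(4 * s_vox)
        ax = np.arange(-half, half + 1)
        k1 = np.exp(-0.5 * (ax / s_vox) ** 2)
        kern = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        kern /= kern.sum()
        num = fftconvolve(two_layer_vol.sigma, kern, mode="same")
        den = fftconvolve(two_layer_vol.head_mask.astype(float), kern, mode="same")
        inside = two_layer_vol.head_mask
        expect = num[inside] / den[inside]
        np.testing.assert_allclose(out.sigma[inside], expect, rtol=2e-4, atol=1e-9)

    def test_air_stays_zero_and_no_negatives(self, two_layer_vol):
        out = smooth_conductivity(two_layer_vol, 5.0)
        assert np.all(out.sigma[~two_layer_vol.head_mask] == 0.0)
        assert np.all(out.sigma >= 0.0)


class TestColeCole:
    def test_no_dispersion_returns_ionic(self):
        p = ColeColeParams(eps_inf=4.0, terms=((0.0, 1e-3, 0.1),), ionic_conductivity=0.25)
        assert cole_cole_conductivity(p, 10.0) == pytest.approx(0.25)

    def test_single_term_matches_complex_arithmetic(self):
        p = ColeColeParams(eps_inf=4.0, terms=((4.5e7, 0.02, 0.2),), ionic_conductivity=0.02)
        f = 10.0
        w = 2 * math.pi * f
        eps = 4.0 + 4.5e7 / (1.0 + (1j * w * 0.02) ** 0.8)
        expect = (0.02 + 1j * w * EPS0 * eps).real
        assert cole_cole_conductivity(p, f) == pytest.approx(expect, rel=1e-12)

    def test_default_evaluation_frequency_is_10_hz(self):
        p = ColeColeParams(eps_inf=4.0, terms=((4.5e7, 0.02, 0.2),), ionic_conductivity=0.02)
        assert cole_cole_conductivity(p) == cole_cole_conductivity(p, 10.0)

    @pytest.mark.parametrize("alpha", [1.0, 1.2])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            ColeColeParams(eps_inf=4.0, terms=((1e7, 1e-2, alpha),), ionic_conductivity=0.1)


class TestElectrodes:
    def test_default_layout_has_65_unique_labels(self):
        entries = ten_ten_layout()
        labels = [lab for lab, _ in entries]
        assert len(labels) == 65
        assert len(set(labels)) == 65

    def test_default_cap_on_volume(self):
        spec = PhantomSpec((20.0, 24.0, 28.0), (0.33, 0.02, 0.1), (32, 32, 32), 2.0)
        vol = build_layered_sphere(spec)
        es = place_electrodes(vol, "10-10")
        assert len(es) == 65
        assert es.reference_label == "Cz"
        center = np.asarray(spec.center_mm)
        radii = np.linalg.norm(es.positions_mm - center, axis=1)
        assert np.all(np.abs(radii - 28.0) <= math.sqrt(3) * 2.0 + 2.0)

    def test_snapped_nodes_near_surface(self, two_layer_vol, electrodes8):
        center = np.asarray([16.0, 16.0, 16.0])
        radii = np.linalg.norm(electrodes8.positions_mm - center, axis=1)
        assert np.all(np.abs(radii - 13.0) <= math.sqrt(3) * 2.0 + 2.0)

    def test_coincident_electrodes_rejected(self, two_layer_vol):
        layout = [("A", np.array([0.0, 0.0, 1.0])), ("B", np.array([0.0, 0.0, 1.0]))]
        with pytest.raises(ValueError, match="same surface node"):
            place_electrodes(two_layer_vol, layout)

    def test_duplicate_labels_rejected(self, two_layer_vol):
        layout = [("A", np.array([0.0, 0.0, 1.0])), ("A", np.array([1.0, 0.0, 0.0]))]
        with pytest.raises(ValueError, match="duplicate"):
            place_electrodes(two_layer_vol, layout)

    def test_tsv_round_trip(self, electrodes8, tmp_path):
        import pandas as pd

        path = tmp_path / "elec.tsv"
        electrodes8.to_tsv(str(path))
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["label", "x_mm", "y_mm", "z_mm", "role"]
        assert (df.role == "ref").sum() == 1

    @given(st.integers(min_value=4, max_value=64))
    def test_fibonacci_layout_unique_unit_vectors(self, n):
        entries = fibonacci_layout(n)
        assert len({lab for lab, _ in entries}) == n
        for _, v in entries:
            assert np.linalg.norm(v) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def sim_setup(two_layer_vol, electrodes8, L_recip):
    vox = tuple(L_recip.voxel_indices[0])
    src = PlantedSource(vox, np.array([0.0, 1e-9, 0.0]))
    return two_layer_vol, electrodes8, src, L_recip


class TestSimulate:

    def test_noiseless_single_trial_is_clean_projection(self, sim_setup):
        vol, el, src, L = sim_setup
        ep = simulate_sep_dataset(vol, el, [src], L, noise_sd=0.0, n_trials=1, seed=0)
        topo = L.project_dipole(src.voxel, src.moment) * 1e6
        t = ep.times_ms
        course = np.where(t >= 0, np.exp(-0.5 * ((t - 20.0) / 2.0) ** 2), 0.0)
        np.testing.assert_allclose(ep.data[0], topo[:, None] * course[None, :], atol=1e-18)
        assert np.all(ep.data[0][:, t < 0] == 0.0)

    def test_epoch_geometry_2khz(self, sim_setup):
        vol, el, src, L = sim_setup
        ep = simulate_sep_dataset(vol, el, [src], L, noise_sd=1.0, n_trials=2, seed=3)
        assert ep.data.shape[2] == 1000
        assert int(round(ep.t0_ms * ep.fs_hz / 1000.0)) == 200

    def test_fixed_seed_bit_reproducible(self, sim_setup):
        vol, el, src, L = sim_setup
        a = simulate_sep_dataset(vol, el, [src], L, noise_sd=2.0, n_trials=3, seed=11)
        b = simulate_sep_dataset(vol, el, [src], L, noise_sd=2.0, n_trials=3, seed=11)
        assert np.array_equal(a.data, b.data)

    def test_average_noise_scales_as_inverse_sqrt_trials(self, sim_setup):
        vol, el, src, L = sim_setup
        sd, n = 2.0, 8
        sds = []
        for seed in range(20):
            ep = simulate_sep_dataset(vol, el, [src], L, noise_sd=sd, n_trials=n, seed=seed)
            pre = ep.data[:, :, ep.times_ms < 0].mean(axis=0)
            sds.append(pre.std())
        measured = float(np.mean(sds))
        assert measured == pytest.approx(sd / math.sqrt(n), rel=0.10)

    def test_source_outside_mask_rejected(self, sim_setup):
        vol, el, _, L = sim_setup
        bad = PlantedSource((0, 0, 0), np.array([1e-9, 0, 0]))
        with pytest.raises(ValueError, match="outside"):
            simulate_sep_dataset(vol, el, [bad], L, noise_sd=0.0, n_trials=1, seed=0)

    def test_noise_sd_for_snr_definition(self):
        clean = np.array([1.0, -1.0, 2.0, -2.0])
        sd = noise_sd_for_snr(clean, snr_db=20.0, n_trials=4, n_window_samples=9)
        rms = math.sqrt(np.mean(clean**2))
        assert sd == pytest.approx(rms * 6.0 / 10.0)
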