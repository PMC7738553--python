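"""Characteristic-matrix engine: layer/stack matrices and reflectance."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iridoptics import (
    LayerStack,
    MonteCarloConfig,
    angular_scan,
    layer_matrix,
    monte_carlo_spectrum,
    reflectivity,
    spectrum,
    stack_matrix,
)
from iridoptics.errors import ParameterError
from iridoptics.tmm import CharacteristicMatrix, Spectrum, snell_angle

N1, N2 = 1.83, 1.33


def random_stack(rng, k=None):
    k = k or int(rng.integers(1, 8))
    return LayerStack.from_arrays(
        rng.uniform(10, 60, k), rng.uniform(50, 300, k), N1, N2
    )


class TestLayerMatrix:
    def test_zero_thickness_is_identity(self):
        m = layer_matrix(1.83, 0.0, 500.0)
        assert np.allclose(m.as_array(), np.eye(2))

    def test_half_wave_is_minus_identity_and_absentee(self):
        lam = 520.0
        m = layer_matrix(1.5, lam / (2 * 1.5), lam)
        assert np.allclose(m.as_array(), -np.eye(2), atol=1e-12)
        # inserting a half-wave layer anywhere leaves reflectance unchanged
        rng = np.random.default_rng(0)
        a = stack_matrix(random_stack(rng), lam)
        b = stack_matrix(random_stack(rng), lam)
        assert reflectivity(a @ b) == pytest.approx(reflectivity(a @ m @ b), abs=1e-12)

    def test_quarter_wave_guanine_matrix(self):
        # direct evaluation at beta = pi/2
        lam = 500.0
        m = layer_matrix(N1, lam / (4 * N1), lam)
        expect = np.array([[0, -1j / N1], [-1j * N1, 0]])
        assert np.allclose(m.as_array(), expect, atol=1e-12)

    def test_layer_times_its_inverse_is_identity(self):
        m = layer_matrix(1.6, 123.0, 456.0)
        inv = CharacteristicMatrix(m.m22, -m.m12, -m.m21, m.m11)  # unimodular inverse
        assert np.allclose((m @ inv).as_array(), np.eye(2), atol=1e-12)

    def test_invalid_wavelength(self):
        with pytest.raises(ParameterError):
            layer_matrix(1.5, 10.0, 0.0)

    @settings(max_examples=200, deadline=None)
    @given(
        n=st.floats(1.0, 2.5),
        d=st.floats(0.0, 500.0),
        lam=st.floats(300.0, 1000.0),
        t=st.floats(0.0, 1.2),
        pol=st.sampled_from(["s", "p"]),
    )
    def test_unimodular(self, n, d, lam, t, pol):
        m = layer_matrix(n, d, lam, t, pol)
        assert abs(m.det() - 1) < 1e-9


class TestStackMatrix:
    def test_single_layer_stack_equals_layer_matrix(self):
        stack = LayerStack.from_arrays([30.0], [0.0], N1, N2)
        # zero cytoplasm layer contributes identity
        got = stack_matrix(stack, 450.0)
        want = layer_matrix(N1, 30.0, 450.0)
        assert np.allclose(got.as_array(), want.as_array())

    def test_empty_stack_is_identity(self):
        m = stack_matrix(LayerStack(), 450.0)
        assert np.allclose(m.as_array(), np.eye(2))

    def test_unimodular_for_random_stacks(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = stack_matrix(random_stack(rng, k=25), 450.0, angle=30.0, polarization="p")
            assert abs(m.det() - 1) < 1e-9

    def test_snell_angle(self):
        assert snell_angle(1.33, 0.0) == 0.0
        t = snell_angle(1.33, 40.0)
        assert np.isclose(1.33 * np.sin(t), np.sin(np.deg2rad(40.0)))


class TestReflectivity:
    def test_identity_matrix_gives_zero(self):
        assert reflectivity(CharacteristicMatrix.identity()) == 0.0

    def test_quarter_wave_guanine_amplitude(self):
        lam = 500.0
        m = layer_matrix(N1, lam / (4 * N1), lam)
        want = (N1**2 - 1) / (N1**2 + 1)  # algebraic evaluation
        assert reflectivity(m) == pytest.approx(want, abs=1e-12)
        assert reflectivity(m) == pytest.approx(0.5401, abs=5e-5)
        assert reflectivity(m, "standard_intensity") == pytest.approx(want**2, abs=1e-12)

    def test_bragg_stack_matches_closed_form(self):
        # k quarter-wave double layers: product is diagonal
        # [(-n2/n1)^k, (-n1/n2)^k]; amplitude reflectance (rho-1)/(rho+1)
        # with rho = (n1/n2)^(2k)
        lam = 450.0
        for k in (1, 3, 5, 8):
            stack = LayerStack.from_arrays(
                [lam / (4 * N1)] * k, [lam / (4 * N2)] * k, N1, N2
            )
            m = stack_matrix(stack, lam)
            diag = np.array([[(-N2 / N1) ** k, 0], [0, (-N1 / N2) ** k]])
            assert np.allclose(m.as_array(), diag, atol=1e-10)
            rho = (N1 / N2) ** (2 * k)
            assert reflectivity(m) == pytest.approx((rho - 1) / (rho + 1), abs=1e-8)

    def test_energy_bound_random_stacks_both_conventions(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            stack = random_stack(rng, k=20)
            for ang in (0.0, 25.0, 60.0):
                for pol in ("s", "p"):
                    m = stack_matrix(stack, float(rng.uniform(380, 780)), ang, pol)
                    eta0 = np.cos(np.deg2rad(ang)) if pol == "s" else 1 / np.cos(np.deg2rad(ang))
                    r = reflectivity(m, eta_in=eta0, eta_out=eta0)
                    assert 0.0 <= r <= 1.0
                    assert 0.0 <= reflectivity(m, "standard_intensity", eta0, eta0) <= 1.0

    def test_reversed_stack_has_equal_reflectance(self):
        # reciprocity: reversing the layer order of any lossless stack
        # between identical media leaves |r| unchanged
        rng = np.random.default_rng(3)
        stack = random_stack(rng, k=6)
        lam = 470.0
        fwd = stack_matrix(stack, lam)
        rev = CharacteristicMatrix.identity()
        for layer in reversed(stack.layers):
            rev = rev @ layer_matrix(layer.refractive_index, layer.thickness, lam)
        assert reflectivity(fwd) == pytest.approx(reflectivity(rev), abs=1e-12)


class TestSpectrum:
    def test_zero_variance_ordered_peak_near_quarter_wave(self):
        from iridoptics.colorimetry import peak_wavelength

        stack = LayerStack.uniform(25, 27.0, 131.0)
        spec = spectrum(stack, MonteCarloConfig(n_runs=1))
        peak = peak_wavelength(spec)
        assert abs(peak - 2 * (N1 * 27 + N2 * 131)) < 5.0  # 447.2 nm

    def test_empty_stack_all_zero(self):
        spec = spectrum(LayerStack(), MonteCarloConfig(n_runs=1))
        assert (spec.reflectance == 0).all()

    def test_non_ascending_grid_rejected(self):
        with pytest.raises(ParameterError):
            Spectrum(np.array([400.0, 390.0]), np.array([0.1, 0.2]))


class TestMonteCarlo:
    def test_single_run_zero_variance_equals_deterministic(self, zero_variance_ordered):
        cfg = MonteCarloConfig(n_runs=1, rng_seed=9)
        mc = monte_carlo_spectrum(zero_variance_ordered, cfg)
        det = spectrum(LayerStack.uniform(25, 27.0, 131.0), cfg)
        assert (mc.reflectance == det.reflectance).all()

    def test_deterministic_per_seed(self, ordered, fast_cfg):
        a = monte_carlo_spectrum(ordered, fast_cfg)
        b = monte_carlo_spectrum(ordered, fast_cfg)
        assert (a.reflectance == b.reflectance).all()

    def test_mean_reflectance_bounded(self, disordered, fast_cfg):
        spec = monte_carlo_spectrum(disordered, fast_cfg)
        assert ((spec.reflectance >= 0) & (spec.reflectance <= 1)).all()


class TestAngularScan:
    def test_zero_degrees_matches_monte_carlo(self, ordered, fast_cfg):
        scan = angular_scan(ordered, fast_cfg, [0.0, 45.0])
        mc = monte_carlo_spectrum(ordered, fast_cfg)
        assert (scan[0].reflectance == mc.reflectance).all()

    def test_angle_out_of_range_rejected(self, ordered, fast_cfg):
        with pytest.raises(ParameterError):
            angular_scan(ordered, fast_cfg, [0.0, 80.0])

    def test_blue_shift_with_angle(self, ordered):
        # Bragg cos-theta dependence: the reflection peak of the ordered
        # crystallotype moves to shorter wavelengths at oblique incidence
        from iridoptics.colorimetry import peak_wavelength

        cfg = MonteCarloConfig(
            n_runs=60, rng_seed=4, wavelength_min=300.0, wavelength_step=2.0
        )
        p0, p50 = [peak_wavelength(s) for s in angular_scan(ordered, cfg, [0.0, 50.0])]
        assert p50 < p0
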