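"""FMM grating solver: Fourier coefficients, limits, conservation, symmetry."""

import math

import numpy as np
import pytest

from evoptics.grating import (
    GeometryError,
    GratingStructure,
    LamellarLayer,
    diffraction_efficiencies,
    diffraction_spectrum,
    epsilon_fourier,
    layer_modes,
)
from evoptics.multilayer import Stack, cascade

CHITIN = 1.56


def quad_fourier(layer, period, m, n_quad=20001):
    """Independent quadrature oracle for the permittivity Fourier coefficient."""
    x = np.linspace(0, period, n_quad, endpoint=False)
    eps = np.full(x.size, complex(layer.background_index) ** 2)
    for a, b, n in layer.wrapped_intervals(period):
        eps[(x >= a) & (x < b)] = complex(n) ** 2
    return np.mean(eps * np.exp(-2j * math.pi * m * x / period))


class TestEpsilonFourier:
    def test_homogeneous_layer(self):
        layer = LamellarLayer(100.0, [], background_index=1.5)
        coef = epsilon_fourier(layer, 600.0, 4)
        c0 = coef[len(coef) // 2]
        assert c0 == pytest.approx(2.25)
        others = np.delete(coef, len(coef) // 2)
        assert np.all(np.abs(others) < 1e-14)

    def test_half_fill_square_wave(self):
        layer = LamellarLayer(100.0, [(0.0, 300.0, 2.0)], background_index=1.0)
        coef = epsilon_fourier(layer, 600.0, 4)
        mid = len(coef) // 2
        assert coef[mid] == pytest.approx((4.0 + 1.0) / 2)
        # even harmonics vanish for a 50% square wave
        for m in (2, 4, 6, 8):
            assert abs(coef[mid + m]) < 1e-12

    @pytest.mark.parametrize("m", [-5, -1, 0, 1, 3, 7])
    def test_single_block_matches_quadrature(self, m):
        layer = LamellarLayer(80.0, [(130.0, 370.0, CHITIN)], background_index=1.0)
        coef = epsilon_fourier(layer, 600.0, 4)
        assert coef[len(coef) // 2 + m] == pytest.approx(
            quad_fourier(layer, 600.0, m), abs=2e-4
        )

    def test_wrapping_splits_interval(self):
        layer = LamellarLayer(80.0, [(550.0, 700.0, CHITIN)])
        ivs = layer.wrapped_intervals(600.0)
        assert ivs == [(0.0, 100.0, CHITIN), (550.0, 600.0, CHITIN)]

    def test_overlap_raises(self):
        layer = LamellarLayer(80.0, [(0.0, 300.0, 1.5), (200.0, 400.0, 1.6)])
        with pytest.raises(GeometryError):
            epsilon_fourier(layer, 600.0, 4)


class TestLayerModes:
    def test_homogeneous_eigenvalues_analytic(self):
        lam, d, n = 450.0, 600.0, 1.56
        beta, W = layer_modes(LamellarLayer(50.0, [], n), lam, d, 6)
        k0 = 2 * math.pi / lam
        kx = 2 * math.pi * np.arange(-6, 7) / d
        expected = np.sqrt((k0**2 * n**2 - kx**2).astype(complex))
        assert np.allclose(beta, expected, atol=1e-12)
        assert np.allclose(W, np.eye(13), atol=1e-12)

    def test_eigenvalues_against_dense_reconstruction(self):
        # W diag(beta^2) W^-1 must reproduce the modal operator
        lam, d = 450.0, 600.0
        layer = LamellarLayer(50.0, [(100.0, 400.0, CHITIN)], 1.0)
        beta, W = layer_modes(layer, lam, d, 5)
        k0 = 2 * math.pi / lam
        kx = 2 * math.pi * np.arange(-5, 6) / d
        from evoptics.grating import _toeplitz_eps

        A = k0**2 * _toeplitz_eps(layer, d, 5) - np.diag(kx**2)
        recon = W @ np.diag(beta**2) @ np.linalg.inv(W)
        assert np.allclose(recon, A, atol=1e-8 * np.abs(A).max())

    def test_truncation_self_convergence(self):
        g = GratingStructure(
            600.0,
            [LamellarLayer(150.0, [(100.0, 400.0, CHITIN)], 1.0)],
        )
        r_lo = diffraction_efficiencies(g, 450.0, 10)
        r_hi = diffraction_efficiencies(g, 450.0, 20)
        for i in (-1, 0, 1):
            assert r_lo.r(i) == pytest.approx(r_hi.r(i), abs=1e-4)


class TestDiffraction:
    def test_no_blocks_everything_transmits(self):
        g = GratingStructure(600.0, [LamellarLayer(200.0, [], 1.0)])
        res = diffraction_efficiencies(g, 450.0, 8)
        assert res.total_reflected < 1e-12
        assert res.t(0) == pytest.approx(1.0, abs=1e-10)

    def test_uniform_limit_matches_multilayer(self):
        layers = [
            LamellarLayer(120.0, [(0.0, 600.0, CHITIN)], 1.0),
            LamellarLayer(80.0, [], 1.0),
            LamellarLayer(90.0, [(0.0, 600.0, CHITIN)], 1.0),
        ]
        g = GratingStructure(600.0, layers)
        res = diffraction_efficiencies(g, 450.0, 8)
        stack = Stack(1.0, [(CHITIN, 120.0), (1.0, 80.0), (CHITIN, 90.0)], 1.0)
        r, _ = cascade(stack, 450.0)
        assert res.r(0) == pytest.approx(abs(r) ** 2, abs=1e-6)
        for i in range(1, 9):
            assert res.r(i) < 1e-10 and res.r(-i) < 1e-10

    def test_subwavelength_only_zero_order(self):
        g = GratingStructure(
            400.0, [LamellarLayer(150.0, [(50.0, 250.0, CHITIN)], 1.0)]
        )
        res = diffraction_efficiencies(g, 450.0, 8)
        assert res.propagating_orders == frozenset({0})
        assert res.r(1) == 0.0 and res.r(-1) == 0.0
        assert res.total_reflected + res.total_transmitted == pytest.approx(1.0, abs=1e-6)

    def test_propagating_set_grating_equation(self):
        # order i propagates iff |i| lambda / d < 1 in vacuum
        g = GratingStructure(1000.0, [LamellarLayer(100.0, [(0.0, 500.0, CHITIN)], 1.0)])
        res = diffraction_efficiencies(g, 450.0, 8)
        expected = {i for i in range(-8, 9) if abs(i) * 450.0 / 1000.0 < 1}
        assert res.propagating_orders == frozenset(expected)

    def test_energy_conservation_lossless(self):
        rng = np.random.default_rng(11)
        for _ in range(3):
            layers = []
            for _ in range(int(rng.integers(1, 5))):
                x0 = float(rng.uniform(0, 600))
                w = float(rng.uniform(20, 500))
                layers.append(
                    LamellarLayer(float(rng.uniform(20, 300)), [(x0, x0 + w, CHITIN)], 1.0)
                )
                layers.append(LamellarLayer(float(rng.uniform(10, 200)), [], 1.0))
            g = GratingStructure(600.0, layers)
            res = diffraction_efficiencies(g, 450.0, 20)
            assert res.total_reflected + res.total_transmitted == pytest.approx(
                1.0, abs=1e-6
            )

    def test_mirror_symmetry(self):
        # x-mirror-symmetric structure: r_{+i} = r_{-i} at normal incidence,
        # asserted on the full-basis solver (no parity reduction)
        layers = [
            LamellarLayer(150.0, [(175.0, 425.0, CHITIN)], 1.0),
            LamellarLayer(60.0, [], 1.0),
            LamellarLayer(120.0, [(225.0, 375.0, CHITIN)], 1.0),
        ]
        g = GratingStructure(600.0, layers)
        orders, r, t = diffraction_spectrum(g, [450.0], 12, exploit_symmetry=False)
        for i in (1, 2):
            assert r[0, 12 + i] == pytest.approx(r[0, 12 - i], abs=1e-8)
            assert t[0, 12 + i] == pytest.approx(t[0, 12 - i], abs=1e-8)

    def test_even_parity_path_matches_full_solver(self):
        # mirror-symmetric stack with the common axis away from x = 0 and the
        # two centres half a period apart; the even-parity reduction is exact
        layers = [
            LamellarLayer(110.0, [(100.0, 380.0, CHITIN)], 1.0),
            LamellarLayer(55.0, [], 1.0),
            LamellarLayer(95.0, [(460.0, 620.0, CHITIN)], 1.0),
        ]
        g = GratingStructure(600.0, layers, 1.0, 1.3)
        lams = np.array([405.0, 450.0, 523.0, 777.0])
        o_full, r_full, t_full = diffraction_spectrum(g, lams, 6, exploit_symmetry=False)
        o_even, r_even, t_even = diffraction_spectrum(g, lams, 6, exploit_symmetry=True)
        assert np.array_equal(o_full, o_even)
        np.testing.assert_allclose(r_even, r_full, rtol=0, atol=1e-10)
        np.testing.assert_allclose(t_even, t_full, rtol=0, atol=1e-10)
        np.testing.assert_allclose(
            r_even.sum(axis=1) + t_even.sum(axis=1), 1.0, rtol=0, atol=1e-8
        )

    def test_asymmetric_structure_has_no_symmetry_axis(self):
        from evoptics.grating import _symmetry_axis

        g = GratingStructure(
            600.0,
            [
                LamellarLayer(110.0, [(100.0, 380.0, CHITIN)], 1.0),
                LamellarLayer(95.0, [(150.0, 500.0, CHITIN)], 1.0),
            ],
        )
        assert _symmetry_axis(g) is None
        lossy = GratingStructure(
            600.0, [LamellarLayer(110.0, [(100.0, 380.0, 1.5 + 0.1j)], 1.0)]
        )
        assert _symmetry_axis(lossy) is None

    def test_spectrum_batches_match_single(self):
        g = GratingStructure(600.0, [LamellarLayer(150.0, [(100.0, 400.0, CHITIN)], 1.0)])
        lams = np.array([420.0, 450.0, 500.0])
        orders, r, t = diffraction_spectrum(g, lams, 8)
        for row, lam in enumerate(lams):
            single = diffraction_efficiencies(g, lam, 8)
            for j, i in enumerate(orders):
                assert r[row, j] == pytest.approx(single.r(int(i)), abs=1e-12)

    def test_json_round_trip(self):
        g = GratingStructure(
            600.0,
            [LamellarLayer(150.0, [(100.0, 400.0, CHITIN)], 1.0)],
            1.0,
            1.5,
        )
        g2 = GratingStructure.from_json(g.to_json())
        assert g2.period == g.period
        assert g2.substrate_index == g.substrate_index
        assert g2.layers[0].intervals == g.layers[0].intervals
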