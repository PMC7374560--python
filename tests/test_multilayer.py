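"""Multilayer S-matrix solver: closed forms, conservation, field profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evoptics.multilayer import (
    InvalidMaterialError,
    OpticalMaterial,
    Stack,
    cascade,
    field_profile,
    interface_coefficients,
    spectral_response,
)
from evoptics.oracles import quarterwave_closed_form, make_reference


@pytest.mark.parametrize(
    "n1,n2,r_expected,t_expected",
    [
        (1.0, 1.0, 0.0, 1.0),
        (1.0, 3.0, -0.5, 0.5),
        (1.4, 1.7, (1.4 - 1.7) / (1.4 + 1.7), 2 * 1.4 / 3.1),
    ],
)
def test_fresnel_interface(n1, n2, r_expected, t_expected):
    r, t = interface_coefficients(n1, n2)
    assert r == pytest.approx(r_expected, abs=1e-12)
    assert t == pytest.approx(t_expected, abs=1e-12)


def test_fresnel_energy_reflectance_value():
    r, _ = interface_coefficients(1.4, 1.7)
    assert abs(r) ** 2 == pytest.approx(0.0093652445369407, rel=1e-10)


def test_degenerate_interface_raises():
    with pytest.raises(InvalidMaterialError):
        interface_coefficients(1.0, -1.0)


def test_empty_stack_vacuum():
    st_ = Stack(1.0, [], 1.0)
    r, t = cascade(st_, 550.0)
    assert r == pytest.approx(0.0, abs=1e-14)
    assert t == pytest.approx(1.0, abs=1e-14)


def test_absent_layer_reproduces_bare_interface():
    # lambda/(2n) lossless layer is optically absent: R equals the bare
    # vacuum|1.7 Fresnel value 0.06721...
    bare = ((1 - 1.7) / (1 + 1.7)) ** 2
    st_ = Stack(1.0, [(1.4, 600.0 / 2.8)], 1.7)
    r, _ = cascade(st_, 600.0)
    assert abs(r) ** 2 == pytest.approx(bare, abs=1e-12)


def test_absent_layer_insertion_anywhere():
    rng = np.random.default_rng(7)
    lam = 600.0
    layers = [(1.7, 90.0), (1.4, 120.0), (1.6, 75.0)]
    base = Stack(1.0, layers, 1.5)
    r0, _ = cascade(base, lam)
    for pos in range(len(layers) + 1):
        n = float(rng.uniform(1.2, 2.2))
        inserted = layers[:pos] + [(n, lam / (2 * n))] + layers[pos:]
        r1, _ = cascade(Stack(1.0, inserted, 1.5), lam)
        assert abs(abs(r1) ** 2 - abs(r0) ** 2) < 1e-10


@pytest.mark.parametrize("pairs", [1, 3, 6, 12, 20])
def test_quarterwave_matches_closed_form(pairs):
    st_ = make_reference("quarterwave", lambda0=600.0, pairs=pairs)
    r, _ = cascade(st_, 600.0)
    expected = quarterwave_closed_form(1.0, 1.7, 1.4, 1.0, pairs)
    assert abs(r) ** 2 == pytest.approx(expected, abs=1e-8)


def test_wavelength_scale_invariance():
    layers = [(1.7, 88.0), (1.4, 107.0), (1.7, 88.0)]
    r1, _ = cascade(Stack(1.0, layers, 1.5), 600.0)
    scaled = [(n, 2 * d) for n, d in layers]
    r2, _ = cascade(Stack(1.0, scaled, 1.5), 1200.0)
    assert abs(r1 - r2) < 1e-12


def test_lossless_stack_conserves_without_absorption():
    st_ = make_reference("quarterwave", lambda0=600.0, pairs=4)
    resp = spectral_response(st_, np.linspace(400, 800, 21))
    assert np.all(np.abs(resp.A_per_layer) < 1e-12)
    assert np.allclose(resp.R + resp.T, 1.0, atol=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_energy_conservation_random_absorbing_stacks(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 41))
    layers = [
        (complex(rng.uniform(1.0, 3.5), rng.uniform(0.0, 1.0)), float(rng.uniform(0, 800)))
        for _ in range(k)
    ]
    st_ = Stack(1.0, layers, float(rng.uniform(1.0, 2.5)))
    resp = spectral_response(st_, np.linspace(350, 900, 4))
    budget = resp.R + resp.T + resp.A_per_layer.sum(axis=0)
    assert np.all(np.abs(budget - 1.0) < 1e-9)
    assert np.all(resp.R >= 0) and np.all(resp.T >= 0)
    assert np.all(resp.A_per_layer > -1e-12)


def test_thick_absorber_stable():
    # 10 um absorbing layer: raw transfer-matrix products overflow here,
    # the S-matrix recursion must not.
    st_ = Stack(1.0, [(complex(4.0, 0.5), 10_000.0)], 1.0)
    resp = spectral_response(st_, np.array([500.0]))
    assert np.isfinite(resp.R).all() and np.isfinite(resp.T).all()
    assert resp.T[0] < 1e-30  # optically opaque
    assert resp.R[0] + resp.A_per_layer.sum() == pytest.approx(1.0, abs=1e-9)


def test_reciprocity_transmittance_lossless():
    layers = [(1.7, 90.0), (1.4, 120.0), (1.6, 60.0)]
    fwd = Stack(1.0, layers, 1.5)
    rev = fwd.reversed()
    _, t1 = cascade(fwd, 600.0)
    _, t2 = cascade(rev, 600.0)
    T1 = 1.5 / 1.0 * abs(t1) ** 2
    T2 = 1.0 / 1.5 * abs(t2) ** 2
    assert T1 == pytest.approx(T2, abs=1e-12)


def test_reversed_lossless_stack_same_reflectance():
    st_ = make_reference("chirped_linear", lambda_start=500.0, lambda_stop=800.0, pairs=10)
    grid = np.linspace(450, 850, 30)
    r1, _ = cascade(st_, grid)
    r2, _ = cascade(st_.reversed(), grid)
    assert np.all(np.abs(np.abs(r1) ** 2 - np.abs(r2) ** 2) < 1e-9)


def test_bare_absorbing_substrate_single_interface():
    n_sub = complex(4.0, 1.0)
    st_ = Stack(1.0, [], n_sub)
    resp = spectral_response(st_, np.array([600.0]))
    r_expected = abs((1 - n_sub) / (1 + n_sub)) ** 2
    assert resp.R[0] == pytest.approx(r_expected, abs=1e-12)
    assert resp.R[0] + resp.T[0] == pytest.approx(1.0, abs=1e-12)


def test_json_round_trip_bit_exact():
    st_ = Stack(1.0, [(complex(1.7, 0.01), 88.23529), (1.4, 107.142857)], 1.5)
    st2 = Stack.from_json(st_.to_json())
    assert st2.incidence_medium.index == st_.incidence_medium.index
    assert st2.substrate.index == st_.substrate.index
    for (m1, d1), (m2, d2) in zip(st_.layers, st2.layers):
        assert m1.index == m2.index and d1 == d2


def test_spectrum_csv_header():
    st_ = Stack(1.0, [(1.5, 100.0)], 1.0)
    csv = spectral_response(st_, np.array([500.0, 600.0])).to_csv()
    assert csv.splitlines()[0] == "wavelength_nm,R,T,A_layer_1"
    assert len(csv.splitlines()) == 3


class TestFieldProfile:
    def test_vacuum_everywhere_unit_field(self):
        st_ = Stack(1.0, [(1.0, 200.0)], 1.0)
        fm = field_profile(st_, 600.0, 5.0)
        assert np.allclose(fm.field_magnitude, 1.0, atol=1e-10)

    def test_strong_mirror_standing_wave(self):
        st_ = make_reference("quarterwave", lambda0=600.0, pairs=30)
        fm = field_profile(st_, 600.0, 1.0)
        above = fm.field_magnitude[fm.z_grid < 0]
        assert above.max() > 1.9  # |1| + |r| with R -> 1
        assert above.min() < 0.2  # standing-wave node

    def test_continuity_across_interfaces(self):
        st_ = Stack(1.0, [(1.7, 90.0), (1.4, 120.0)], 1.5)
        fm = field_profile(st_, 600.0, 0.25)
        jumps = np.abs(np.diff(fm.field_magnitude))
        assert jumps.max() < 0.02  # no discontinuity at grid resolution

    def test_transparent_structure_transmits_field(self):
        # when R is small at some wavelength the field crosses the whole
        # structure essentially undamped into the substrate
        st_ = make_reference("chirped_linear", lambda_start=550.0, lambda_stop=800.0, pairs=10)
        lam = 420.0
        r, t = cascade(st_, lam)
        assert abs(r) ** 2 < 0.35
        fm = field_profile(st_, lam, 2.0)
        below = fm.field_magnitude[fm.z_grid > fm.z_grid.max() - lam / 2]
        assert below.max() > 0.5
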