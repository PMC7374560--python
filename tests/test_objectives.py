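"""The four objective functions: printed-formula arithmetic and bounds."""

import numpy as np
import pytest

from evoptics.genomes import CoatingProblem, MorphoProblem, MultilayerProblem
from evoptics.objectives import (
    BraggObjectiveSpec,
    BroadbandObjectiveSpec,
    MorphoObjectiveSpec,
    PhotovoltaicObjectiveSpec,
    bragg_objective,
    broadband_objective,
    conversion_efficiency,
    load_asi_material,
    load_solar_spectrum,
    morpho_objective,
    photovoltaic_objective,
    short_circuit_current,
)
from evoptics.oracles import quarterwave_closed_form


class TestBragg:
    def test_zero_thickness_stack_scores_one(self):
        prob = MultilayerProblem(4, mode="free_index")
        f = bragg_objective(prob, BraggObjectiveSpec(600.0))
        assert f([0, 0, 0, 0, 1.5, 1.5, 1.5, 1.5]) == pytest.approx(1.0)

    def test_ideal_quarterwave_scores_below_05(self):
        prob = MultilayerProblem(
            40, mode="forced_alternation", alternation_start="high"
        )
        genome = [600 / (4 * (1.7 if j % 2 == 0 else 1.4)) for j in range(40)]
        f = bragg_objective(prob, BraggObjectiveSpec(600.0))
        score = f(genome)
        assert score == pytest.approx(
            1 - quarterwave_closed_form(1, 1.7, 1.4, 1, 20), abs=1e-8
        )
        assert score < 0.05

    def test_score_in_unit_interval(self):
        prob = MultilayerProblem(3, mode="free_index")
        f = bragg_objective(prob, BraggObjectiveSpec(600.0))
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = rng.uniform(-100, 500, size=6)
            assert 0.0 <= f(g) <= 1.0


class TestBroadband:
    def test_grid_is_inclusive_equidistant(self):
        g = BroadbandObjectiveSpec().grid()
        assert g.size == 50
        assert g[0] == 500.0 and g[-1] == 800.0
        assert np.allclose(np.diff(g), g[1] - g[0])

    def test_formula_grid_preset(self):
        g = BroadbandObjectiveSpec.formula_grid().grid()
        assert np.array_equal(g, 500.0 + 50.0 * np.arange(8))

    def test_bare_interface_dispersionless_value(self):
        # empty coating on an n=1.7 substrate reflects the Fresnel value at
        # every wavelength, so the objective is 1 - 0.0672... everywhere
        prob = MultilayerProblem(1, mode="forced_alternation", substrate_index=1.7)
        f = broadband_objective(prob, BroadbandObjectiveSpec())
        expected = 1 - ((1 - 1.7) / (1 + 1.7)) ** 2
        assert f([0.0]) == pytest.approx(expected, abs=1e-12)

    def test_grid_density_irrelevant_for_flat_response(self):
        prob = MultilayerProblem(1, mode="forced_alternation", substrate_index=1.7)
        f50 = broadband_objective(prob, BroadbandObjectiveSpec(n_wavelengths=50))
        f7 = broadband_objective(prob, BroadbandObjectiveSpec(n_wavelengths=7))
        assert f50([0.0]) == pytest.approx(f7([0.0]), abs=1e-12)


class TestMorpho:
    def test_no_blocks_scores_one(self):
        prob = MorphoProblem(1, period=600.0, width_range=(0.0, 600.0), height_range=(0.0, 600.0), gap_range=(0.0, 600.0))
        f = morpho_objective(prob, MorphoObjectiveSpec(truncation=6))
        # zero-size block: vacuum everywhere, r_i = 0 for all i
        assert f([0.0, 0.0, 0.0, 0.0]) == pytest.approx(1.0, abs=1e-9)

    def test_weight_penalty_arithmetic(self):
        prob = MorphoProblem(4, period=600.0)
        spec0 = MorphoObjectiveSpec(a=0.0, truncation=4)
        spec5 = MorphoObjectiveSpec(a=0.5, truncation=4)
        genome = []
        for _ in range(4):
            genome += [300.0, 50.0, 150.0, 40.0]  # w = d/2 each
        f0 = morpho_objective(prob, spec0)(genome)
        f5 = morpho_objective(prob, spec5)(genome)
        # penalty term = (a/n_b) sum w_j/d = (0.5/4) * 4 * 0.5 = 0.25
        assert f5 - f0 == pytest.approx(0.25, abs=1e-12)

    def test_antispecular_grid(self):
        spec = MorphoObjectiveSpec()
        g = spec.antispecular_grid()
        assert g.size == 8 and g[0] == 400.0 and g[-1] == 800.0

    def test_lower_bound_term_wise(self):
        prob = MorphoProblem(2, period=600.0)
        f = morpho_objective(prob, MorphoObjectiveSpec(truncation=6))
        rng = np.random.default_rng(1)
        for _ in range(5):
            g = rng.uniform(10, 500, size=8)
            assert f(g) >= -0.5


class TestPhotovoltaic:
    def test_short_circuit_linearity(self):
        wl_s, irr_s = load_solar_spectrum()
        grid = np.arange(375.0, 750.5, 1.0)
        J_max = short_circuit_current(np.ones_like(grid), grid, wl_s, irr_s)
        J_half = short_circuit_current(0.5 * np.ones_like(grid), grid, wl_s, irr_s)
        J_zero = short_circuit_current(np.zeros_like(grid), grid, wl_s, irr_s)
        assert J_half / J_max == pytest.approx(0.5, abs=1e-12)
        assert J_zero == 0.0

    def test_range_outside_table_raises(self):
        wl_s, irr_s = load_solar_spectrum()
        with pytest.raises(ValueError):
            short_circuit_current(np.ones(3), np.array([100.0, 200.0, 250.0]), wl_s, irr_s)

    def test_score_in_unit_interval_and_eta_consistency(self):
        prob = CoatingProblem(2, absorber=load_asi_material(), absorber_thickness=89.0)
        f = photovoltaic_objective(prob)
        g = np.array([80.0, 90.0])
        score = f(g)
        assert 0.0 < score < 1.0
        assert score == pytest.approx(1.0 - conversion_efficiency(prob, g), abs=1e-12)

    def test_bare_cell_regression_value(self):
        # bare 89 nm a-Si cell (all-zero coating); solver evaluation pinned
        # on first run as a regression anchor
        prob = CoatingProblem(2, absorber=load_asi_material(), absorber_thickness=89.0)
        eta_bare = conversion_efficiency(prob, np.zeros(2))
        assert 0.3 < eta_bare < 0.8
        assert eta_bare == pytest.approx(conversion_efficiency(prob, np.zeros(2)))


def test_objectives_deterministic():
    prob = MorphoProblem(2, period=600.0)
    f = morpho_objective(prob, MorphoObjectiveSpec(truncation=5))
    g = np.array([200.0, 80.0, 30.0, 100.0, 150.0, 90.0, 400.0, 60.0])
    assert f(g) == f(g)
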