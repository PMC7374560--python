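"""The four objective functions, each mapping a genome to a scalar to minimize.

(i)   Bragg: ``1 - R(lambda_0)`` — maximize reflectance at one working
      wavelength.
(ii)  Broadband: ``1 - mean R`` over an equidistant wavelength grid
      (default 50 points on 500-800 nm) — the chirped-mirror problem.
(iii) Morpho: ``1 - (r_{+1} + r_{-1} - r_0)/2`` at 450 nm, plus the mean
      specular reflectance over N anti-specular wavelengths, plus a weight
      penalty ``(a/n_b) * sum_j w_j/d`` — scatter blue into the first orders,
      kill specular reflection everywhere, optionally keep the structure
      light.
(iv)  Photovoltaic: ``1 - eta`` where eta is the ratio of the short-circuit
      current (quantum yield one, AM1.5-style photon flux, 375-750 nm) to the
      maximum achievable over the same range.

Every objective is deterministic given genome + spec + solver truncation, and
evaluation count is the unit of budget accounting everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genomes import CoatingProblem, MorphoProblem, MultilayerProblem
from .grating import diffraction_spectrum
from .multilayer import OpticalMaterial, SpectralResponse, Stack, cascade, spectral_response

__all__ = [
    "BraggObjectiveSpec",
    "BroadbandObjectiveSpec",
    "MorphoObjectiveSpec",
    "PhotovoltaicObjectiveSpec",
    "bragg_objective",
    "broadband_objective",
    "morpho_objective",
    "short_circuit_current",
    "photovoltaic_objective",
    "load_solar_spectrum",
    "load_asi_material",
]

_DATA = Path(__file__).parent / "data"

# Planck constant times c in W s nm units is irrelevant here: photon flux is
# used only in ratios, so irradiance * wavelength (proportional to photons) is
# the natural weight; hc cancels. We keep hc explicit for readability.
_HC = 6.62607015e-34 * 2.99792458e8  # J m


def load_solar_spectrum():
    """(wavelength_nm, irradiance) from the bundled synthetic AM1.5 table."""
    raw = np.loadtxt(_DATA / "am15_synthetic.csv", delimiter=",", comments="#", skiprows=4)
    return raw[:, 0], raw[:, 1]


def load_asi_material() -> OpticalMaterial:
    """Amorphous silicon as a dispersive material (synthetic Tauc-Lorentz table)."""
    raw = np.loadtxt(_DATA / "asi_nk_synthetic.csv", delimiter=",", comments="#", skiprows=4)
    return OpticalMaterial.from_table(raw[:, 0], raw[:, 1], raw[:, 2], label="a-Si")


# ---------------------------------------------------------------------------
# (i) Bragg mirror
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BraggObjectiveSpec:
    """Working wavelength for the single-wavelength mirror objective."""

    lambda0: float = 600.0

    def __post_init__(self):
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be > 0")


def bragg_objective(problem: MultilayerProblem, spec: BraggObjectiveSpec):
    """Objective factory: ``f(genome) = 1 - R(lambda_0)``."""
    lam0 = float(spec.lambda0)

    def f(genome) -> float:
        stack = problem.decode(genome)
        r, _ = cascade(stack, lam0)
        return 1.0 - abs(r) ** 2

    return f


# ---------------------------------------------------------------------------
# (ii) Broadband mirror
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BroadbandObjectiveSpec:
    """Equidistant reflectance-averaging grid, endpoints included.

    The default is 50 wavelengths on 500-800 nm. ``formula_grid()`` gives the
    alternative 8-point preset ``500 + 50 n`` (n = 0..7) reaching 850 nm.
    """

    lambda_min: float = 500.0
    lambda_max: float = 800.0
    n_wavelengths: int = 50

    def __post_init__(self):
        if not (self.lambda_min < self.lambda_max and self.n_wavelengths >= 2):
            raise ValueError("need lambda_min < lambda_max and >= 2 points")

    def grid(self) -> np.ndarray:
        return np.linspace(self.lambda_min, self.lambda_max, self.n_wavelengths)

    @staticmethod
    def formula_grid() -> "BroadbandObjectiveSpec":
        return BroadbandObjectiveSpec(500.0, 850.0, 8)


def broadband_objective(problem: MultilayerProblem, spec: BroadbandObjectiveSpec):
    """Objective factory: ``f(genome) = 1 - mean_lambda R(lambda)``."""
    grid = spec.grid()

    def f(genome) -> float:
        stack = problem.decode(genome)
        r, _ = cascade(stack, grid)
        return 1.0 - float(np.mean(np.abs(r) ** 2))

    return f


# ---------------------------------------------------------------------------
# (iii) Morpho grating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphoObjectiveSpec:
    """Parameters of the blue-scattering / anti-specular objective.

    ``a`` is the weight-penalty coefficient (0 for the optical optimum, 0.5
    to retrieve Morpho-like architectures); the ``n_antispecular``
    wavelengths are evenly distributed on ``antispecular_range``.
    """

    lambda_blue: float = 450.0
    a: float = 0.0
    n_antispecular: int = 8
    antispecular_range: tuple = (400.0, 800.0)
    truncation: int = 8

    def __post_init__(self):
        if self.a < 0 or self.n_antispecular < 1:
            raise ValueError("need a >= 0 and n_antispecular >= 1")

    def antispecular_grid(self) -> np.ndarray:
        lo, hi = self.antispecular_range
        return np.linspace(lo, hi, self.n_antispecular)


def morpho_objective(problem: MorphoProblem, spec: MorphoObjectiveSpec):
    """Objective factory for the four-term Morpho score.

    ``1 - (r_{+1}(450) + r_{-1}(450) - r_0(450))/2
    + (1/N) sum_i r_0(lambda_i) + (a/n_b) sum_j w_j/d``.
    """
    lams = np.concatenate([[spec.lambda_blue], spec.antispecular_grid()])
    N = spec.n_antispecular
    Nh = spec.truncation
    centre = Nh  # index of order 0 in the -Nh..Nh ladder

    def f(genome) -> float:
        structure = problem.decode(genome)
        _, r, _ = diffraction_spectrum(structure, lams, Nh)
        r_blue = r[0]
        blue_term = 0.5 * (r_blue[centre + 1] + r_blue[centre - 1] - r_blue[centre])
        antispec = float(np.mean(r[1:, centre]))
        penalty = 0.0
        if spec.a > 0:
            w = problem.block_widths(genome)
            penalty = spec.a / problem.n_blocks * float(np.sum(w / problem.period))
        return 1.0 - float(blue_term) + antispec + penalty

    return f


# ---------------------------------------------------------------------------
# (iv) Photovoltaic anti-reflective coating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhotovoltaicObjectiveSpec:
    """Spectral range and quadrature grid for the conversion-efficiency score.

    Quantum yield is fixed at one; the short-circuit current is the
    absorbed-photon flux integral over ``lambda_range`` on a ``grid_step`` nm
    trapezoidal grid, weighted by the bundled solar spectrum.
    """

    lambda_range: tuple = (375.0, 750.0)
    grid_step: float = 1.0

    def grid(self) -> np.ndarray:
        lo, hi = self.lambda_range
        return np.arange(lo, hi + self.grid_step / 2, self.grid_step)


def short_circuit_current(
    absorptance: np.ndarray,
    wavelengths: np.ndarray,
    spectrum_wl: np.ndarray,
    spectrum_irr: np.ndarray,
) -> float:
    """Photon-flux-weighted absorption integral (short-circuit current proxy).

    ``J = integral A(lambda) Phi(lambda) dlambda`` with photon flux
    ``Phi = irradiance * lambda / (h c)``, trapezoidal quadrature on the
    evaluation grid. Units cancel in the efficiency ratio.
    """
    if wavelengths[0] < spectrum_wl[0] or wavelengths[-1] > spectrum_wl[-1]:
        raise ValueError("requested range is outside the solar spectrum table")
    irr = np.interp(wavelengths, spectrum_wl, spectrum_irr)
    phi = irr * (wavelengths * 1e-9) / _HC
    return float(np.trapezoid(absorptance * phi, wavelengths))


def conversion_efficiency(
    problem: CoatingProblem,
    genome,
    spec: PhotovoltaicObjectiveSpec = PhotovoltaicObjectiveSpec(),
) -> float:
    """eta = J / J_max for the decoded coating + cell stack."""
    grid = spec.grid()
    wl_s, irr_s = load_solar_spectrum()
    stack = problem.decode(genome)
    resp = spectral_response(stack, grid)
    A_abs = resp.A_per_layer[problem.absorber_layer_position]
    J = short_circuit_current(A_abs, grid, wl_s, irr_s)
    J_max = short_circuit_current(np.ones_like(grid), grid, wl_s, irr_s)
    return J / J_max


def photovoltaic_objective(
    problem: CoatingProblem, spec: PhotovoltaicObjectiveSpec = PhotovoltaicObjectiveSpec()
):
    """Objective factory: ``f(genome) = 1 - eta``."""
    grid = spec.grid()
    wl_s, irr_s = load_solar_spectrum()
    irr = np.interp(grid, wl_s, irr_s)
    phi = irr * (grid * 1e-9) / _HC
    J_max = float(np.trapezoid(phi, grid))
    pos = problem.absorber_layer_position

    def f(genome) -> float:
        stack = problem.decode(genome)
        resp = spectral_response(stack, grid)
        A_abs = resp.A_per_layer[pos]
        J = float(np.trapezoid(A_abs * phi, grid))
        return 1.0 - J / J_max

    return f
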