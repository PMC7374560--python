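"""Independent reference computations used to validate the solvers.

These deliberately use a different formulation from the production code: the
quarterwave reflectance is a textbook closed form, and the transfer-matrix
evaluation is the naive 2x2 characteristic-matrix product (stable only for
benign stacks, which is all it is ever used on). They also build the
canonical reference structures — quarterwave Bragg stacks, half-wave-first
variants, linearly chirped mirrors, and aligned Morpho-style block lattices —
that the regularity classifiers are tested against.
"""

from __future__ import annotations

import cmath
import math

import numpy as np

from .multilayer import OpticalMaterial, Stack
from .grating import GratingStructure, LamellarLayer

__all__ = [
    "quarterwave_closed_form",
    "brute_force_transfer_matrix",
    "make_reference",
    "selftest",
]


def quarterwave_closed_form(n_inc, n_high, n_low, n_sub, pairs: int) -> float:
    """Reflectance of a high-first quarterwave stack of ``pairs`` bilayers.

    Standard admittance result for lossless quarter-wave layers at the design
    wavelength: a stack of ``pairs`` complete (high, low) bilayers on a
    substrate of index ``n_sub`` presents the input admittance
    ``Y = (n_high/n_low)^(2 pairs) * n_sub`` and reflects
    ``R = ((n_inc - Y)/(n_inc + Y))^2``. With ``pairs = 0`` this reduces to
    the bare ``n_inc | n_sub`` Fresnel reflectance, and with
    ``n_high = n_low`` the contrast vanishes and R is pairs-independent.
    """
    Y = (n_high / n_low) ** (2 * pairs) * n_sub
    return float(((n_inc - Y) / (n_inc + Y)) ** 2)


def brute_force_transfer_matrix(stack: Stack, wavelength: float):
    """Amplitude ``(r, t)`` by the naive characteristic-matrix product.

    Textbook formulation: per-layer characteristic matrix
    ``[[cos d, -i sin d / n], [-i n sin d, cos d]]`` with phase thickness
    ``d = 2 pi n t / lambda`` (signs fixed by the ``exp(-i omega t)`` time
    convention shared with the S-matrix solver); numerically naive by design,
    reserved for stacks whose product stays well-conditioned (few lossless
    layers).
    """
    ns = stack.indices(wavelength)
    n0, nsub = ns[0], ns[-1]
    M = np.eye(2, dtype=complex)
    k0 = 2 * math.pi / wavelength
    for j, (_, d) in enumerate(stack.layers):
        n = ns[j + 1]
        delta = k0 * n * d
        c, s = cmath.cos(delta), cmath.sin(delta)
        Mj = np.array([[c, -1j * s / n], [-1j * n * s, c]])
        M = M @ Mj
    B, C = M @ np.array([1.0, nsub])
    denom = n0 * B + C
    r = (n0 * B - C) / denom
    t = 2 * n0 / denom
    return complex(r), complex(t)


def make_reference(kind: str, **params):
    """Deterministic canonical structures for tests and classifier checks.

    kinds
    -----
    quarterwave:
        ``lambda0``, ``pairs``, optional ``n_high``/``n_low``/``n_inc``/``n_sub``.
        High-index-first Bragg stack, every layer lambda0/(4n).
    halfwave_first:
        Same, but starting with a low-index layer of thickness lambda0/(2n)
        followed by a high-first quarterwave stack.
    chirped_linear:
        ``lambda_start``, ``lambda_stop``, ``pairs``: quarterwave pairs whose
        design wavelength ramps linearly with depth.
    morpho_lattice:
        ``n_blocks``, ``width``, ``height``, ``gap``, ``period``: vertically
        aligned chitin blocks separated by air layers (stacked alignment).
    """
    n_high = params.get("n_high", 1.7)
    n_low = params.get("n_low", 1.4)
    n_inc = params.get("n_inc", 1.0)
    n_sub = params.get("n_sub", 1.0)
    inc = OpticalMaterial(n_inc, "incidence")
    sub = OpticalMaterial(n_sub, "substrate")
    hi = OpticalMaterial(n_high, "high")
    lo = OpticalMaterial(n_low, "low")

    if kind == "quarterwave":
        lam0, pairs = params["lambda0"], params["pairs"]
        layers = []
        for _ in range(pairs):
            layers.append((hi, lam0 / (4 * n_high)))
            layers.append((lo, lam0 / (4 * n_low)))
        return Stack(inc, layers, sub)

    if kind == "halfwave_first":
        lam0, pairs = params["lambda0"], params["pairs"]
        layers = [(lo, lam0 / (2 * n_low))]
        for _ in range(pairs):
            layers.append((hi, lam0 / (4 * n_high)))
            layers.append((lo, lam0 / (4 * n_low)))
        return Stack(inc, layers, sub)

    if kind == "chirped_linear":
        lam_a, lam_b = params["lambda_start"], params["lambda_stop"]
        pairs = params["pairs"]
        lams = np.linspace(lam_a, lam_b, pairs)
        layers = []
        for lam in lams:
            layers.append((hi, lam / (4 * n_high)))
            layers.append((lo, lam / (4 * n_low)))
        return Stack(inc, layers, sub)

    if kind == "morpho_lattice":
        nb = params["n_blocks"]
        w, h, g = params["width"], params["height"], params["gap"]
        d = params.get("period", 600.0)
        n_chitin = params.get("n_chitin", 1.56)
        x0 = (d - w) / 2.0
        layers = []
        for _ in range(nb):
            layers.append(
                LamellarLayer(h, [(x0, x0 + w, n_chitin)], background_index=1.0)
            )
            layers.append(LamellarLayer(g, [], background_index=1.0))
        return GratingStructure(d, layers, incidence_index=1.0, substrate_index=1.0)

    raise ValueError(f"unknown reference kind: {kind!r}")


def selftest(seed: int = 0, verbose: bool = False) -> dict:
    """Run the oracle/solver agreement suite; returns {check: bool}.

    Exercised by the CLI ``selftest`` subcommand and the test suite.
    """
    from .multilayer import cascade, spectral_response

    rng = np.random.default_rng(seed)
    results = {}

    # quarterwave closed form vs cascade, 1..20 pairs
    ok = True
    for pairs in range(1, 21):
        st = make_reference("quarterwave", lambda0=600.0, pairs=pairs)
        r, _ = cascade(st, 600.0)
        ok &= abs(abs(r) ** 2 - quarterwave_closed_form(1, 1.7, 1.4, 1, pairs)) < 1e-8
    results["quarterwave_closed_form"] = ok

    # brute-force transfer matrix vs cascade on random benign stacks
    ok = True
    for _ in range(200):
        k = int(rng.integers(0, 11))
        layers = [
            (OpticalMaterial(float(rng.uniform(1.0, 2.5))), float(rng.uniform(0, 400)))
            for _ in range(k)
        ]
        st = Stack(1.0, layers, float(rng.uniform(1.0, 2.5)))
        lam = float(rng.uniform(350, 900))
        r1, t1 = cascade(st, lam)
        r2, t2 = brute_force_transfer_matrix(st, lam)
        ok &= abs(r1 - r2) < 1e-10 and abs(t1 - t2) < 1e-10
    results["transfer_matrix_agreement"] = ok

    # energy conservation with random absorbing layers
    ok = True
    for _ in range(50):
        k = int(rng.integers(1, 41))
        layers = [
            (
                OpticalMaterial(
                    complex(rng.uniform(1.0, 3.0), rng.uniform(0.0, 0.5))
                ),
                float(rng.uniform(0, 500)),
            )
            for _ in range(k)
        ]
        st = Stack(1.0, layers, float(rng.uniform(1.0, 2.5)))
        resp = spectral_response(st, np.linspace(400, 800, 5))
        budget = resp.R + resp.T + resp.A_per_layer.sum(axis=0)
        ok &= bool(np.all(np.abs(budget - 1.0) < 1e-9))
    results["energy_conservation"] = ok

    # absent layer: lambda/(2n) insertion leaves R unchanged
    st0 = Stack(1.0, [(OpticalMaterial(1.7), 90.0)], 1.5)
    r0, _ = cascade(st0, 600.0)
    st1 = Stack(
        1.0,
        [(OpticalMaterial(1.4), 600.0 / 2.8), (OpticalMaterial(1.7), 90.0)],
        1.5,
    )
    r1, _ = cascade(st1, 600.0)
    results["absent_layer"] = bool(abs(abs(r0) ** 2 - abs(r1) ** 2) < 1e-10)

    if verbose:
        for name, passed in results.items():
            print(f"{name}: {'PASS' if passed else 'FAIL'}")
    return results
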