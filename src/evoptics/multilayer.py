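"""Scattering-matrix solver for planar stratified media at normal incidence.

The solver computes amplitude reflection/transmission coefficients, energy
spectra (reflectance, transmittance, per-layer absorptance) and electric-field
depth profiles for a stack of homogeneous layers between an incidence medium
and a substrate. Composition uses the Redheffer-star (S-matrix) recursion,
which stays numerically stable for arbitrarily thick absorbing layers where a
raw transfer-matrix product would overflow.

Conventions
-----------
* Normal incidence, non-magnetic media, time convention ``exp(-i omega t)``
  so a passive medium has ``Im(n) >= 0`` and the layer phase factor
  ``exp(i k0 n d)`` never grows.
* Layers are ordered from the incidence side (top) to the substrate (bottom).
* Energy reflectance ``R = |r|^2``; transmittance is the normal Poynting flux
  transmitted into the substrate relative to the incident flux,
  ``T = Re(n_sub)/Re(n_inc) * |t|^2``.
"""

from __future__ import annotations

import cmath
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "OpticalMaterial",
    "Stack",
    "SpectralResponse",
    "FieldMap",
    "interface_coefficients",
    "cascade",
    "spectral_response",
    "field_profile",
]


class InvalidMaterialError(ValueError):
    """Raised for degenerate optical constants (e.g. n_left + n_right = 0)."""


@dataclass(frozen=True)
class OpticalMaterial:
    """A dispersive or constant-index optical material.

    Parameters
    ----------
    index:
        Either a complex constant or a callable mapping wavelength (nm) to a
        complex refractive index ``n + i k`` with ``k >= 0``.
    label:
        Free-text name used in serialization and reports.
    """

    index: complex | Callable[[np.ndarray], np.ndarray]
    label: str = ""

    def refractive_index(self, wavelength):
        """Complex index at ``wavelength`` (nm); vectorizes over arrays."""
        if callable(self.index):
            return self.index(wavelength)
        if np.isscalar(wavelength):
            return complex(self.index)
        return np.full(np.shape(wavelength), complex(self.index))

    @property
    def is_constant(self) -> bool:
        return not callable(self.index)

    @staticmethod
    def from_table(
        wavelengths_nm: Sequence[float],
        n: Sequence[float],
        k: Sequence[float] | None = None,
        label: str = "",
    ) -> "OpticalMaterial":
        """Material with linearly interpolated tabulated optical constants."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        n = np.asarray(n, dtype=float)
        k = np.zeros_like(n) if k is None else np.asarray(k, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength table must be strictly increasing")

        def interp(w):
            wr = np.clip(w, wl[0], wl[-1])
            val = np.interp(wr, wl, n) + 1j * np.interp(wr, wl, k)
            return complex(val) if np.isscalar(w) else val

        return OpticalMaterial(interp, label=label)


def _as_material(m) -> OpticalMaterial:
    if isinstance(m, OpticalMaterial):
        return m
    return OpticalMaterial(complex(m))


@dataclass(frozen=True)
class Stack:
    """An ordered stratified medium: incidence medium, layers, substrate.

    ``layers`` is a sequence of ``(material, thickness_nm)`` pairs ordered
    from the incidence side down. Zero-thickness layers are legal and
    optically absent.
    """

    incidence_medium: OpticalMaterial
    layers: tuple
    substrate: OpticalMaterial

    def __init__(self, incidence_medium, layers, substrate):
        norm = []
        for mat, d in layers:
            d = float(d)
            if not math.isfinite(d) or d < 0:
                raise ValueError(f"layer thickness must be finite and >= 0, got {d}")
            norm.append((_as_material(mat), d))
        object.__setattr__(self, "incidence_medium", _as_material(incidence_medium))
        object.__setattr__(self, "layers", tuple(norm))
        object.__setattr__(self, "substrate", _as_material(substrate))

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def thicknesses(self) -> np.ndarray:
        return np.array([d for _, d in self.layers], dtype=float)

    def indices(self, wavelength):
        """Complex indices [incidence, layer_1..layer_k, substrate].

        Constant-index materials yield scalar complex values (they broadcast
        against wavelength grids); dispersive ones vectorize over the grid.
        """
        mats = [self.incidence_medium, *(m for m, _ in self.layers), self.substrate]
        return [
            complex(m.index) if m.is_constant else m.refractive_index(wavelength)
            for m in mats
        ]

    # -- JSON serialization (bit-exact for constant-index stacks) -----------
    def to_json(self) -> str:
        def mat_obj(m: OpticalMaterial):
            if not m.is_constant:
                raise ValueError("only constant-index materials serialize to JSON")
            n = complex(m.index)
            obj = {"n_re": n.real, "n_im": n.imag}
            if m.label:
                obj["material"] = m.label
            return obj

        return json.dumps(
            {
                "incidence": mat_obj(self.incidence_medium),
                "layers": [
                    {**mat_obj(m), "thickness_nm": d} for m, d in self.layers
                ],
                "substrate": mat_obj(self.substrate),
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "Stack":
        obj = json.loads(text)

        def mat(o):
            return OpticalMaterial(
                complex(o["n_re"], o.get("n_im", 0.0)), label=o.get("material", "")
            )

        return Stack(
            mat(obj["incidence"]),
            [(mat(lo), lo["thickness_nm"]) for lo in obj["layers"]],
            mat(obj["substrate"]),
        )

    def reversed(self) -> "Stack":
        """Same layers bottom-to-top with incidence and substrate swapped."""
        return Stack(self.substrate, tuple(reversed(self.layers)), self.incidence_medium)


@dataclass
class SpectralResponse:
    """Energy balance of a stack on a wavelength grid.

    ``A_per_layer`` has shape ``(n_layers, n_wavelengths)``; the conservation
    identity ``R + T + sum_j A_j = 1`` holds to solver precision.
    """

    wavelengths: np.ndarray
    R: np.ndarray
    T: np.ndarray
    A_per_layer: np.ndarray

    def to_csv(self) -> str:
        k = self.A_per_layer.shape[0]
        header = "wavelength_nm,R,T," + ",".join(f"A_layer_{j + 1}" for j in range(k))
        rows = [header] if k else ["wavelength_nm,R,T"]
        for i, wl in enumerate(self.wavelengths):
            vals = [f"{wl:.6g}", f"{self.R[i]:.12g}", f"{self.T[i]:.12g}"]
            vals += [f"{self.A_per_layer[j, i]:.12g}" for j in range(k)]
            rows.append(",".join(vals))
        return "\n".join(rows) + "\n"


@dataclass
class FieldMap:
    """|E(z)| depth profile at one wavelength, unit incident amplitude."""

    z_grid: np.ndarray
    field_magnitude: np.ndarray
    wavelength: float

    def to_csv(self) -> str:
        rows = [f"# wavelength_nm={self.wavelength:.6g}", "z_nm,abs_E"]
        rows += [
            f"{z:.6g},{e:.12g}" for z, e in zip(self.z_grid, self.field_magnitude)
        ]
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Amplitude-level building blocks
# ---------------------------------------------------------------------------

def interface_coefficients(n_left, n_right):
    """Fresnel amplitude coefficients at normal incidence.

    Returns ``(r, t)`` for light going from ``n_left`` into ``n_right``:
    ``r = (n_left - n_right) / (n_left + n_right)``,
    ``t = 2 n_left / (n_left + n_right)``.
    """
    s = n_left + n_right
    if np.isscalar(s) and s == 0:
        raise InvalidMaterialError("degenerate interface: n_left + n_right = 0")
    return (n_left - n_right) / s, 2 * n_left / s


def _star(r1, t1, rp1, tp1, r2, t2, rp2, tp2):
    """Redheffer star of two scalar S-matrices (r, t, r', t').

    r: left reflection, t: left->right transmission, r': right reflection,
    t': right->left transmission. Works on python complex or ndarrays.
    """
    denom = 1.0 - rp1 * r2
    inv = 1.0 / denom
    r = r1 + tp1 * r2 * t1 * inv
    t = t2 * inv * t1
    rp = rp2 + t2 * rp1 * tp2 * inv
    tp = tp1 * inv * tp2
    return r, t, rp, tp


def _interface_smatrix(n1, n2):
    s = n1 + n2
    r = (n1 - n2) / s
    return r, 2 * n1 / s, -r, 2 * n2 / s


def _phase(n, d, wavelength):
    """One-way propagation factor exp(i 2 pi n d / lambda); |.| <= 1 for Im n >= 0."""
    arg = 2j * math.pi * d / wavelength * n
    if np.isscalar(arg):
        return cmath.exp(arg)
    return np.exp(arg)


def cascade(stack: Stack, wavelength):
    """Global amplitude coefficients ``(r, t)`` of the stack.

    ``wavelength`` may be a scalar (fast scalar-complex path) or an ndarray
    (vectorized). Composition is the stable S-matrix recursion, so stacks with
    optically thick absorbing layers do not overflow.
    """
    if not np.isscalar(wavelength) or wavelength <= 0:
        if np.isscalar(wavelength):
            raise ValueError("wavelength must be > 0")
        wavelength = np.asarray(wavelength, dtype=float)
        if np.any(wavelength <= 0):
            raise ValueError("wavelengths must be > 0")
    ns = stack.indices(wavelength)
    k = stack.n_layers
    # fold the S-matrix recursion from the substrate upward; only the
    # accumulated (r, t) of the sub-stack below each boundary is needed
    r_acc, t_acc, _, _ = _interface_smatrix(ns[k], ns[k + 1])
    for j in range(k - 1, -1, -1):
        ph = _phase(ns[j + 1], stack.layers[j][1], wavelength)
        r_acc = ph * ph * r_acc
        t_acc = ph * t_acc
        r1, t1, r1p, t1p = _interface_smatrix(ns[j], ns[j + 1])
        inv = 1.0 / (1.0 - r1p * r_acc)
        t_acc = t_acc * (t1 * inv)
        r_acc = r1 + t1p * r_acc * t1 * inv
    return r_acc, t_acc


def _boundary_amplitudes(stack: Stack, wavelength):
    """Forward/backward amplitudes at the top of every region.

    Returns a list of ``(A_j, B_j)`` for regions ``j = 0..k+1`` (incidence,
    layers, substrate), each referenced to the top boundary of the region,
    with unit incident amplitude in the incidence medium.
    """
    ns = stack.indices(wavelength)
    k = stack.n_layers

    # prefix[j]: S-matrix of everything above the top boundary of layer j
    # (interfaces 0..j-1 and layers 1..j-1), i.e. mapping incidence <-> layer j.
    elems = []  # alternating interface / propagation scattering elements
    for j in range(k + 1):
        elems.append(_interface_smatrix(ns[j], ns[j + 1]))
        if j < k:
            ph = _phase(ns[j + 1], stack.layers[j][1], wavelength)
            elems.append((0.0, ph, 0.0, ph))

    # Region j (1-based layer) top boundary sits after element 2j-1.
    prefix = [(0.0, 1.0, 0.0, 1.0)]
    S = prefix[0]
    for e in elems:
        S = _star(*S, *e)
        prefix.append(S)
    # suffix[i]: composition of elems[i:]
    suffix = [None] * (len(elems) + 1)
    suffix[len(elems)] = (0.0, 1.0, 0.0, 1.0)
    S = suffix[len(elems)]
    for i in range(len(elems) - 1, -1, -1):
        S = _star(*elems[i], *S)
        suffix[i] = S

    out = [(1.0 + 0j if np.isscalar(wavelength) else np.ones_like(ns[0]), prefix[-1][0])]
    for region in range(1, k + 2):
        i = 2 * region - 1  # element index at which the region starts
        front = prefix[i]
        back = suffix[i]
        denom = 1.0 - front[2] * back[0]
        A = front[1] / denom
        B = back[0] * A
        out.append((A, B))
    return out, ns


def spectral_response(stack: Stack, wavelengths) -> SpectralResponse:
    """Energy reflectance, transmittance and per-layer absorptance.

    Per-layer absorptance is the difference of the normal Poynting flux
    across the layer's two boundaries, so ``R + T + sum A = 1`` holds by
    construction (telescoping sum).
    """
    wavelengths = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    if wavelengths.size == 0:
        raise ValueError("wavelength grid must be non-empty")
    k = stack.n_layers
    R = np.empty(wavelengths.size)
    T = np.empty(wavelengths.size)
    A = np.empty((k, wavelengths.size))
    amps, ns = _boundary_amplitudes(stack, wavelengths)
    n_inc = np.real(ns[0])
    # flux at the top boundary of each region, normalized by the incident flux
    flux = []
    for region in range(1, k + 2):
        Aj, Bj = amps[region]
        n = ns[region]
        # S_z ~ Re[(A+B) conj(n (A-B))] at the boundary (local z = 0)
        f = np.real((Aj + Bj) * np.conj(n * (Aj - Bj)))
        flux.append(f / n_inc)
    r = amps[0][1]
    R[:] = np.abs(r) ** 2
    T[:] = flux[-1]
    for j in range(k):
        A[j] = flux[j] - flux[j + 1]
    return SpectralResponse(wavelengths, R, T, A)


def field_profile(stack: Stack, wavelength: float, z_resolution: float) -> FieldMap:
    """Sample |E(z)| through the stack on a regular depth grid.

    The grid spans one wavelength of incidence medium above the first
    interface and one wavelength of substrate below the last, with ``z = 0``
    at the first interface and z increasing downward.
    """
    if z_resolution <= 0:
        raise ValueError("z_resolution must be > 0")
    wavelength = float(wavelength)
    amps, ns = _boundary_amplitudes(stack, wavelength)
    thick = stack.thicknesses()
    total = float(thick.sum())
    z = np.arange(-wavelength, total + wavelength + z_resolution / 2, z_resolution)
    tops = np.concatenate([[0.0], np.cumsum(thick)])  # layer top depths
    k0 = 2 * math.pi / wavelength
    E = np.empty(z.size, dtype=complex)
    r = amps[0][1]
    t = amps[-1][0]
    for i, zi in enumerate(z):
        if zi < 0:  # incidence medium: incident + reflected standing wave
            n = ns[0]
            E[i] = cmath.exp(1j * k0 * n * zi) + r * cmath.exp(-1j * k0 * n * zi)
        elif zi >= total:  # substrate
            n = ns[-1]
            E[i] = t * cmath.exp(1j * k0 * n * (zi - total))
        else:
            j = int(np.searchsorted(tops, zi, side="right")) - 1
            j = min(j, stack.n_layers - 1)
            Aj, Bj = amps[j + 1]
            n = ns[j + 1]
            zl = zi - tops[j]
            E[i] = Aj * cmath.exp(1j * k0 * n * zl) + Bj * cmath.exp(-1j * k0 * n * zl)
    return FieldMap(z, np.abs(E), wavelength)
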