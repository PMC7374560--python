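"""Fourier Modal Method (RCWA) for 1D lamellar gratings at normal incidence.

Each layer of a :class:`GratingStructure` is invariant along y and z within
the layer and piecewise-constant along x with period ``d`` (rectangular
inclusions in a background medium). The field in every layer is expanded on
the plane-wave ladder ``kx_m = 2 pi m / d`` truncated to ``|m| <= N_h``; the
layer eigenmodes couple through the same stable S-matrix (Redheffer star)
recursion as the multilayer solver, and the solver returns the power carried
by each reflected and transmitted diffraction order.

Polarization is TE (electric field along the grooves), for which the plain
Laurent factorization of the permittivity is exact. Incidence and substrate
media must be homogeneous.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import toeplitz

__all__ = [
    "LamellarLayer",
    "GratingStructure",
    "DiffractionResult",
    "epsilon_fourier",
    "layer_modes",
    "diffraction_efficiencies",
    "diffraction_spectrum",
]

DEFAULT_TRUNCATION = 20


class GeometryError(ValueError):
    """Raised when lamellar intervals overlap after modulo-period wrapping."""


@dataclass(frozen=True)
class LamellarLayer:
    """One lamella: rectangular inclusions tiling a single period.

    ``intervals`` is a sequence of ``(x_start_nm, x_end_nm, complex_index)``;
    interval ends may exceed the period and are wrapped modulo ``d``. A layer
    with no intervals is homogeneous background.
    """

    thickness: float
    intervals: tuple = ()
    background_index: complex = 1.0

    def __init__(self, thickness, intervals=(), background_index=1.0):
        object.__setattr__(self, "thickness", float(thickness))
        object.__setattr__(
            self,
            "intervals",
            tuple((float(a), float(b), complex(n)) for a, b, n in intervals),
        )
        object.__setattr__(self, "background_index", complex(background_index))
        if self.thickness < 0:
            raise ValueError("layer thickness must be >= 0")

    @property
    def is_homogeneous(self) -> bool:
        return len(self.intervals) == 0

    def wrapped_intervals(self, period: float):
        """Intervals folded into [0, period), split at the wrap point."""
        out = []
        for a, b, n in self.intervals:
            w = b - a
            if w < 0:
                raise GeometryError(f"interval with negative width: ({a}, {b})")
            w = min(w, period)
            a = a % period
            if a + w <= period:
                out.append((a, a + w, n))
            else:
                out.append((a, period, n))
                out.append((0.0, a + w - period, n))
        out.sort(key=lambda iv: iv[0])
        for (a1, b1, _), (a2, _, _) in zip(out, out[1:]):
            if a2 < b1 - 1e-9:
                raise GeometryError("overlapping lamellar intervals")
        return out


@dataclass(frozen=True)
class GratingStructure:
    """Stack of lamellar layers sharing one horizontal period.

    Layers are ordered top (incidence side) to bottom (substrate side).
    """

    period: float
    layers: tuple
    incidence_index: complex = 1.0
    substrate_index: complex = 1.0

    def __init__(self, period, layers, incidence_index=1.0, substrate_index=1.0):
        period = float(period)
        if period <= 0:
            raise ValueError("period must be > 0")
        object.__setattr__(self, "period", period)
        object.__setattr__(self, "layers", tuple(layers))
        object.__setattr__(self, "incidence_index", complex(incidence_index))
        object.__setattr__(self, "substrate_index", complex(substrate_index))

    def to_json(self) -> str:
        def c(z):
            z = complex(z)
            return z.real if z.imag == 0 else [z.real, z.imag]

        return json.dumps(
            {
                "period_nm": self.period,
                "incidence_n": c(self.incidence_index),
                "substrate_n": c(self.substrate_index),
                "layers": [
                    {
                        "thickness_nm": la.thickness,
                        "background_n": c(la.background_index),
                        "intervals": [
                            {"x0_nm": a, "x1_nm": b, "n": c(n)}
                            for a, b, n in la.intervals
                        ],
                    }
                    for la in self.layers
                ],
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "GratingStructure":
        obj = json.loads(text)

        def c(v):
            return complex(v[0], v[1]) if isinstance(v, list) else complex(v)

        return GratingStructure(
            obj["period_nm"],
            [
                LamellarLayer(
                    lo["thickness_nm"],
                    [(iv["x0_nm"], iv["x1_nm"], c(iv["n"])) for iv in lo["intervals"]],
                    c(lo["background_n"]),
                )
                for lo in obj["layers"]
            ],
            c(obj["incidence_n"]),
            c(obj["substrate_n"]),
        )


@dataclass
class DiffractionResult:
    """Power in each diffraction order at one wavelength.

    ``orders[i] = (r_i, t_i)`` maps the order index to reflected and
    transmitted efficiencies (fractions of the incident power); evanescent
    orders carry exactly zero.
    """

    wavelength: float
    orders: dict
    propagating_orders: frozenset
    truncation: int

    def r(self, i: int) -> float:
        return self.orders.get(i, (0.0, 0.0))[0]

    def t(self, i: int) -> float:
        return self.orders.get(i, (0.0, 0.0))[1]

    @property
    def total_reflected(self) -> float:
        return sum(v[0] for v in self.orders.values())

    @property
    def total_transmitted(self) -> float:
        return sum(v[1] for v in self.orders.values())

    def scattered_fraction(self) -> float:
        """Power in all non-specular (i != 0) orders, reflected + transmitted."""
        return sum(r + t for i, (r, t) in self.orders.items() if i != 0)

    def to_csv(self) -> str:
        rows = [
            f"# wavelength_nm={self.wavelength:.6g},truncation={self.truncation}",
            "order,r,t",
        ]
        for i in sorted(self.orders):
            r, t = self.orders[i]
            rows.append(f"{i},{r:.12g},{t:.12g}")
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Fourier decomposition and layer eigenmodes
# ---------------------------------------------------------------------------

def epsilon_fourier(layer: LamellarLayer, period: float, order: int) -> np.ndarray:
    """Fourier coefficients of the layer permittivity profile.

    Returns ``eps_hat[m]`` for ``m = -2*order .. 2*order`` (array of length
    ``4*order + 1``), with ``eps_hat[0]`` at the centre — enough to fill the
    ``(2*order+1)`` Toeplitz matrix. ``eps_hat_0`` is the area-weighted mean
    permittivity; a single block of width ``w`` contributes
    ``(eps_b - eps_bg) * (w/d) * sinc(m w / d)`` with a centre phase factor.
    """
    if order < 1:
        raise ValueError("truncation order must be >= 1")
    m = np.arange(-2 * order, 2 * order + 1)
    eps_bg = complex(layer.background_index) ** 2
    coef = np.zeros(m.size, dtype=complex)
    coef[m == 0] = eps_bg
    for a, b, n in layer.wrapped_intervals(period):
        w = b - a
        if w <= 0:
            continue
        eps_b = complex(n) ** 2
        centre = (a + b) / 2.0
        coef += (
            (eps_b - eps_bg)
            * (w / period)
            * np.sinc(m * w / period)
            * np.exp(-2j * math.pi * m * centre / period)
        )
    return coef


def _toeplitz_eps(layer: LamellarLayer, period: float, N: int) -> np.ndarray:
    coef = epsilon_fourier(layer, period, N)
    c0 = 2 * N  # index of m = 0
    col = coef[c0 : c0 + 2 * N + 1]  # eps_hat_{0..2N}
    row = coef[c0::-1]  # eps_hat_{0..-2N}
    return toeplitz(col, row)


from functools import lru_cache


@lru_cache(maxsize=32)
def _grids(N: int, period: float):
    """Cached plane-wave ladder and Toeplitz index matrix for (N, period)."""
    m = np.arange(-N, N + 1)
    kx = 2 * math.pi * m / period
    idx = 2 * N + (m[:, None] - m[None, :])  # coef[idx] is the Toeplitz matrix
    return m, kx, idx


def _branch_sqrt(q: np.ndarray) -> np.ndarray:
    beta = np.sqrt(q.astype(complex))
    flip = beta.imag < 0
    beta = np.where(flip, -beta, beta)
    return beta


def _regularize_beta(beta: np.ndarray, k0: np.ndarray) -> np.ndarray:
    """Nudge exactly-grazing orders (Wood anomaly, beta = 0) off zero.

    A vanishing propagation constant makes the mode-matching admittance
    singular; the grazing order is replaced by a barely evanescent one.
    """
    floor = 1e-9 * k0[:, None]
    tiny = np.abs(beta) < floor
    if np.any(tiny):
        beta = np.where(tiny, 1j * floor + 0 * beta, beta)
    return beta


def _modes_full(layer: LamellarLayer, k0: np.ndarray, period: float, N: int):
    """Eigenmodes ``(beta, W, Winv)`` for all wavenumbers in ``k0`` at once.

    ``beta`` has shape (L, 2N+1), ``W``/``Winv`` shape (L, 2N+1, 2N+1) with
    L = len(k0); ``Winv`` is ``None`` for a homogeneous layer (W = identity,
    ``beta_m^2 = k0^2 eps - kx_m^2`` analytically).

    A single-inclusion layer is solved in a shifted frame where the block is
    centred (its permittivity Fourier series is then real and even, so the
    modal operator is real symmetric); the eigenvectors transform back with a
    diagonal phase, and the inverse basis comes from orthogonality instead of
    a linear solve.
    """
    k0 = np.atleast_1d(np.asarray(k0, dtype=float))
    dim = 2 * N + 1
    m, kx, idx = _grids(N, period)
    if layer.is_homogeneous:
        eps = complex(layer.background_index) ** 2
        q = (k0[:, None] ** 2) * eps - kx[None, :] ** 2
        return _regularize_beta(_branch_sqrt(q), k0), None, None

    ivs = layer.wrapped_intervals(period)
    single = (
        len(layer.intervals) == 1
        and layer.background_index.imag == 0
        and all(complex(n).imag == 0 for _, _, n in ivs)
    )
    if single:
        a, b, n = layer.intervals[0]
        w = min(b - a, period)
        eps_bg = complex(layer.background_index).real ** 2
        eps_b = complex(n).real ** 2
        mm = np.arange(-2 * N, 2 * N + 1)
        coef = (eps_b - eps_bg) * (w / period) * np.sinc(mm * w / period)
        coef[2 * N] += eps_bg
        A = (k0[:, None, None] ** 2) * coef[idx][None]
        diag = np.arange(dim)
        A[:, diag, diag] -= kx**2
        q, Wr = np.linalg.eigh(A)
        centre = ((a + b) / 2.0) % period
        D = np.exp(-2j * math.pi * m * centre / period)
        W = D[None, :, None] * Wr
        Winv = Wr.transpose(0, 2, 1) * D.conj()[None, None, :]
        return _regularize_beta(_branch_sqrt(q), k0), W, Winv

    E = _toeplitz_eps(layer, period, N)
    A = (k0[:, None, None] ** 2) * E[None, :, :] - np.diag(kx**2)[None, :, :]
    if np.allclose(E, E.conj().T, rtol=0, atol=1e-13):
        q, W = np.linalg.eigh(A)
        W = W.astype(complex)
        Winv = W.conj().transpose(0, 2, 1)
    else:
        q, W = np.linalg.eig(A)
        W = W.astype(complex)
        Winv = np.linalg.inv(W)
    return _regularize_beta(_branch_sqrt(q), k0), W, Winv


def _modes_batched(layer: LamellarLayer, k0: np.ndarray, period: float, N: int):
    """Eigenmodes (beta, W) for all wavenumbers in ``k0`` at once."""
    k0 = np.atleast_1d(np.asarray(k0, dtype=float))
    beta, W, _ = _modes_full(layer, k0, period, N)
    if W is None:
        dim = 2 * N + 1
        W = np.broadcast_to(np.eye(dim, dtype=complex), (k0.size, dim, dim)).copy()
    return beta, W


def layer_modes(layer: LamellarLayer, wavelength: float, period: float, N_h: int):
    """Modal eigenvalues ``beta`` and eigenvector matrix ``W`` for one layer.

    ``beta[m]`` are the longitudinal propagation constants (branch with
    ``Im(beta) >= 0``); columns of ``W`` are the modal field profiles in the
    plane-wave basis.
    """
    k0 = 2 * math.pi / float(wavelength)
    beta, W = _modes_batched(layer, np.array([k0]), period, N_h)
    return beta[0], W[0]


# ---------------------------------------------------------------------------
# S-matrix assembly
# ---------------------------------------------------------------------------

def _interface_blocks(W1inv, beta1, W2, beta2):
    """Mode-matching S-matrix blocks between two layer bases.

    Continuity of Ey and dEy/dz gives ``X = W1^-1 W2`` and
    ``Y = diag(1/beta1) X diag(beta2)``; ``W1inv``/``W2`` may be ``None`` for
    a homogeneous layer (identity basis).
    """
    if W1inv is None and W2 is None:
        L, dim = beta1.shape
        X = np.broadcast_to(np.eye(dim, dtype=complex), (L, dim, dim))
    elif W1inv is None:
        X = W2
    elif W2 is None:
        X = W1inv
    else:
        X = W1inv @ W2
    Y = X * (beta2[:, None, :] / beta1[:, :, None])
    Apq = X + Y
    Amm = X - Y
    inv = np.linalg.inv(Apq)
    S11 = Amm @ inv
    S21 = 2.0 * inv
    S22 = -inv @ Amm
    S12 = 0.5 * (Apq - S11 @ Amm)
    return S11, S12, S21, S22


def _fold_interface(blocks, r_acc, t_acc):
    """Prepend an interface to the accumulated sub-stack (S11, S21) blocks."""
    A11, A12, A21, A22 = blocks
    I = np.broadcast_to(np.eye(A11.shape[-1], dtype=complex), A11.shape)
    T = np.linalg.inv(I - A22 @ r_acc) @ A21
    return A11 + A12 @ (r_acc @ T), t_acc @ T


try:  # optional acceleration of the per-wavelength fold loop
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally available
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco


@_njit(cache=True)
def _gauss_inv(A):  # pragma: no cover - jitted
    """In-place-ish Gauss-Jordan inverse with partial pivoting.

    LAPACK per-call overhead dominates at these matrix sizes (order 10); a
    hand-rolled elimination is several times faster inside the fold loop.
    """
    D = A.shape[0]
    M = A.copy()
    B = np.eye(D) + 0j
    for col in range(D):
        piv = col
        best = abs(M[col, col])
        for r in range(col + 1, D):
            v = abs(M[r, col])
            if v > best:
                best = v
                piv = r
        if piv != col:
            for c in range(D):
                M[col, c], M[piv, c] = M[piv, c], M[col, c]
                B[col, c], B[piv, c] = B[piv, c], B[col, c]
        inv_p = 1.0 / M[col, col]
        for c in range(D):
            M[col, c] *= inv_p
            B[col, c] *= inv_p
        for r in range(D):
            if r != col:
                factor = M[r, col]
                if factor != 0:
                    for c in range(D):
                        M[r, c] -= factor * M[col, c]
                        B[r, c] -= factor * B[col, c]
    return B


@_njit(cache=True)
def _mm(A, B):  # pragma: no cover - jitted
    D = A.shape[0]
    C = np.zeros((D, D), np.complex128)
    for i in range(D):
        for k in range(D):
            a = A[i, k]
            if a != 0:
                for j in range(D):
                    C[i, j] += a * B[k, j]
    return C


@_njit(cache=True)
def _fold_chain(W, Winv, beta, thick, skip, centre):  # pragma: no cover - jitted
    """Substrate-up Redheffer fold for every wavelength; returns the
    reflected/transmitted modal amplitude columns for unit m=0 incidence."""
    C, L, D, _ = W.shape
    r_out = np.empty((L, D), np.complex128)
    t_out = np.empty((L, D), np.complex128)
    eye = np.eye(D) + 0j
    for l in range(L):
        # (0, I) is the identity element of the fold
        r_acc = np.zeros((D, D), np.complex128)
        t_acc = eye.copy()
        for j in range(C - 2, -1, -1):
            if skip[j] == 0:
                X = _mm(Winv[j, l], W[j + 1, l])
                Y = np.empty_like(X)
                for a in range(D):
                    for b in range(D):
                        Y[a, b] = X[a, b] * beta[j + 1, l, b] / beta[j, l, a]
                Apq = X + Y
                Amm = X - Y
                inv1 = _gauss_inv(Apq)
                S11 = _mm(Amm, inv1)
                S21 = 2.0 * inv1
                S22 = -_mm(inv1, Amm)
                S12 = 0.5 * (Apq - _mm(S11, Amm))
                T = _mm(_gauss_inv(eye - _mm(S22, r_acc)), S21)
                r_acc = S11 + _mm(S12, _mm(r_acc, T))
                t_acc = _mm(t_acc, T)
            if j > 0 and thick[j] > 0.0:
                ph = np.exp(1j * beta[j, l] * thick[j])
                for a in range(D):
                    for b in range(D):
                        r_acc[a, b] *= ph[a] * ph[b]
                        t_acc[a, b] *= ph[b]
        r_out[l] = r_acc[:, centre]
        t_out[l] = t_acc[:, centre]
    return r_out, t_out


def _fold_modes(modes, chain, centre):
    """Fold the chain's Redheffer recursion; returns the reflected and
    transmitted amplitude columns for unit incidence in basis index ``centre``.

    ``modes`` is a list of ``(beta, W, Winv)`` per chain element. The
    per-wavelength loop is jitted when numba is importable; the numpy path is
    the reference implementation (asserted equal in the test suite).
    """
    L, dim = modes[0][0].shape
    C = len(chain)
    skip = np.zeros(C - 1, dtype=np.int8)
    for j in range(C - 1):
        skip[j] = (
            modes[j][1] is None
            and modes[j + 1][1] is None
            and chain[j].background_index == chain[j + 1].background_index
        )

    if _HAVE_NUMBA:
        W_all = np.empty((C, L, dim, dim), dtype=np.complex128)
        Winv_all = np.empty_like(W_all)
        beta_all = np.empty((C, L, dim), dtype=np.complex128)
        eye = np.eye(dim, dtype=np.complex128)
        for j, (beta, W, Winv) in enumerate(modes):
            beta_all[j] = beta
            W_all[j] = eye if W is None else W
            Winv_all[j] = eye if Winv is None else Winv
        thick = np.array([la.thickness for la in chain], dtype=float)
        return _fold_chain(W_all, Winv_all, beta_all, thick, skip, centre)

    eyeL = np.broadcast_to(np.eye(dim, dtype=complex), (L, dim, dim))
    r_acc = None
    # fold from the bottom interface upward
    for j in range(C - 2, -1, -1):
        beta1, _, W1inv = modes[j]
        beta2, W2, _ = modes[j + 1]
        if not skip[j]:
            blocks = _interface_blocks(W1inv, beta1, W2, beta2)
            if r_acc is None:
                r_acc, t_acc = blocks[0], blocks[2]
            else:
                r_acc, t_acc = _fold_interface(blocks, r_acc, t_acc)
        elif r_acc is None:
            r_acc = np.zeros((L, dim, dim), dtype=complex)
            t_acc = eyeL.copy()
        # propagation through layer j (skipped for the semi-infinite incidence
        # medium and zero-thickness layers)
        if j > 0 and chain[j].thickness > 0:
            ph = np.exp(1j * beta1 * chain[j].thickness)
            r_acc = ph[:, :, None] * r_acc * ph[:, None, :]
            t_acc = t_acc * ph[:, None, :]
    return r_acc[:, :, centre], t_acc[:, :, centre]


def _chain(structure: GratingStructure):
    inc = LamellarLayer(0.0, (), structure.incidence_index)
    sub = LamellarLayer(0.0, (), structure.substrate_index)
    return [inc, *structure.layers, sub]


def _solve_structure(structure: GratingStructure, k0: np.ndarray, N: int):
    """Reflected/transmitted modal amplitudes for unit m = 0 incidence,
    plus the incidence/substrate betas (full plane-wave basis)."""
    chain = _chain(structure)
    modes = [_modes_full(layer, k0, structure.period, N) for layer in chain]
    r_col, t_col = _fold_modes(modes, chain, N)
    return r_col, t_col, modes[0][0], modes[-1][0]


# ---------------------------------------------------------------------------
# Mirror-symmetric fast path (even-parity subspace)
# ---------------------------------------------------------------------------

def _symmetry_axis(structure: GratingStructure):
    """x-mirror axis shared by every layer, or None.

    A structure of single lossless rectangular inclusions whose centres all
    sit on one axis (modulo half a period) is invariant under the mirror; at
    normal incidence only even-parity modes are excited, so the modal problem
    can be solved in the (N+1)-dimensional even subspace.
    """
    if (
        complex(structure.incidence_index).imag != 0
        or complex(structure.substrate_index).imag != 0
    ):
        return None
    axis = None
    d = structure.period
    for la in structure.layers:
        if la.is_homogeneous:
            if complex(la.background_index).imag != 0:
                return None
            continue
        if len(la.intervals) != 1 or complex(la.background_index).imag != 0:
            return None
        a, b, n = la.intervals[0]
        if complex(n).imag != 0:
            return None
        c = ((a + b) / 2.0) % d
        if axis is None:
            axis = c
        else:
            delta = (c - axis) % (d / 2.0)
            if min(delta, d / 2.0 - delta) > 1e-6:
                return None
    return 0.0 if axis is None else axis


def _modes_even(layer: LamellarLayer, k0: np.ndarray, period: float, N: int, axis: float):
    """Eigenmodes of the even-parity modal operator (dimension N+1)."""
    jj = np.arange(0, N + 1)
    kx = 2 * math.pi * jj / period
    if layer.is_homogeneous:
        eps = complex(layer.background_index).real ** 2
        q = (k0[:, None] ** 2) * eps - kx[None, :] ** 2
        return _regularize_beta(_branch_sqrt(q), k0), None, None
    a, b, n = layer.intervals[0]
    w = min(b - a, period)
    c = ((a + b) / 2.0) % period
    eps_bg = complex(layer.background_index).real ** 2
    eps_b = complex(n).real ** 2
    mm = np.arange(0, 2 * N + 1)
    # Fourier coefficients in the frame centred on the mirror axis: the block
    # centre sits at 0 or d/2 there, so the series is real and even
    coef = (
        (eps_b - eps_bg)
        * (w / period)
        * np.sinc(mm * w / period)
        * np.cos(2 * math.pi * mm * (c - axis) / period)
    )
    coef[0] += eps_bg
    dim = N + 1
    E = np.empty((dim, dim))
    E[0, 0] = coef[0]
    for i in range(1, dim):
        E[0, i] = E[i, 0] = math.sqrt(2.0) * coef[i]
        for j2 in range(1, dim):
            E[i, j2] = coef[abs(i - j2)] + coef[i + j2]
    A = (k0[:, None, None] ** 2) * E[None]
    diag = np.arange(dim)
    A[:, diag, diag] -= kx**2
    q, Wr = np.linalg.eigh(A)
    W = Wr.astype(complex)
    Winv = W.transpose(0, 2, 1)
    return _regularize_beta(_branch_sqrt(q), k0), W, Winv


def _spectrum_even(structure: GratingStructure, k0: np.ndarray, N: int, axis: float):
    """Order efficiencies via the even-parity subproblem (exact for
    mirror-symmetric structures at normal incidence)."""
    chain = _chain(structure)
    modes = [_modes_even(layer, k0, structure.period, N, axis) for layer in chain]
    b, a = _fold_modes(modes, chain, 0)
    beta_inc, beta_sub = modes[0][0], modes[-1][0]
    beta0 = beta_inc[:, 0].real
    L = k0.size
    dim = 2 * N + 1
    r = np.zeros((L, dim))
    t = np.zeros((L, dim))
    r_even = np.abs(b) ** 2 * beta_inc.real / beta0[:, None]
    t_even = np.abs(a) ** 2 * beta_sub.real / beta0[:, None]
    r_even[beta_inc.real <= 1e-12 * k0[:, None]] = 0.0
    t_even[beta_sub.real <= 1e-12 * k0[:, None]] = 0.0
    r[:, N] = r_even[:, 0]
    t[:, N] = t_even[:, 0]
    for j in range(1, N + 1):
        # the even mode (e_j + e_-j)/sqrt(2) splits its power equally
        r[:, N + j] = r[:, N - j] = 0.5 * r_even[:, j]
        t[:, N + j] = t[:, N - j] = 0.5 * t_even[:, j]
    return r, t


def diffraction_spectrum(
    structure: GratingStructure,
    wavelengths,
    N_h: int = DEFAULT_TRUNCATION,
    exploit_symmetry: bool = True,
):
    """Diffraction efficiencies for every wavelength in one batched solve.

    Returns ``(orders, r, t)`` with ``orders`` the integer order vector
    ``-N_h..N_h`` and ``r``, ``t`` real arrays of shape
    ``(len(wavelengths), 2*N_h + 1)``.

    When the structure is mirror-symmetric about a vertical axis (and all
    media are lossless) the solve is run in the even-parity subspace, which
    is exact at normal incidence; pass ``exploit_symmetry=False`` to force
    the full-basis path.
    """
    wavelengths = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    if np.any(wavelengths <= 0):
        raise ValueError("wavelengths must be > 0")
    N = int(N_h)
    k0 = 2 * math.pi / wavelengths
    axis = _symmetry_axis(structure) if exploit_symmetry else None
    if axis is not None:
        r, t = _spectrum_even(structure, k0, N, axis)
        return np.arange(-N, N + 1), r, t
    # b, a: reflected/transmitted modal amplitudes for a unit-amplitude
    # normally incident plane wave (m = 0)
    b, a, beta_inc, beta_sub = _solve_structure(structure, k0, N)
    beta0 = beta_inc[:, N].real
    # TE power flux of order m is proportional to Re(beta_m) |amplitude|^2
    r = np.abs(b) ** 2 * beta_inc.real / beta0[:, None]
    t = np.abs(a) ** 2 * beta_sub.real / beta0[:, None]
    # evanescent orders (Re beta = 0) carry exactly zero power
    r[beta_inc.real <= 1e-12 * k0[:, None]] = 0.0
    t[beta_sub.real <= 1e-12 * k0[:, None]] = 0.0
    orders = np.arange(-N, N + 1)
    return orders, r, t


def diffraction_efficiencies(
    structure: GratingStructure, wavelength: float, N_h: int = DEFAULT_TRUNCATION
) -> DiffractionResult:
    """Power carried by each reflected/transmitted order at one wavelength."""
    orders, r, t = diffraction_spectrum(structure, [float(wavelength)], N_h)
    k0 = 2 * math.pi / float(wavelength)
    d = structure.period
    n_inc = complex(structure.incidence_index)
    propagating = frozenset(
        int(i)
        for i in orders
        if (k0 * n_inc.real) ** 2 - (2 * math.pi * i / d) ** 2 > 0
    )
    return DiffractionResult(
        wavelength=float(wavelength),
        orders={int(i): (float(r[0, j]), float(t[0, j])) for j, i in enumerate(orders)},
        propagating_orders=propagating,
        truncation=int(N_h),
    )
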