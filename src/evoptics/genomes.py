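"""Bounded real-vector search spaces and their decoders into structures.

Every optimization problem is a box-bounded real vector ("genome") plus a
deterministic decoding rule into either a :class:`~evoptics.multilayer.Stack`
or a :class:`~evoptics.grating.GratingStructure`. Out-of-bounds vectors are
projected onto the box (clamped) before decoding, so every optimizer sees the
identical feasible set.

Problem variants
----------------
* ``MultilayerProblem`` — ``free_index`` mode searches thicknesses and
  refractive indices of every layer (dimension 2k); ``forced_alternation``
  fixes the indices to strictly alternate between the two extreme allowed
  values and searches thicknesses only (dimension k).
* ``MorphoProblem`` — vertical sequence of rectangular chitin blocks in air,
  one block per lamellar layer, separated by air spacers; ``free`` alignment
  searches (width, height, offset, gap) per block (dimension 4 n_b);
  ``stacked`` shares one centre abscissa (dimension 3 n_b + 1).
* ``CoatingProblem`` — anti-reflective coating of alternating 1.4/1.7 layers
  (low index first) on an absorbing cell, searching coating thicknesses only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grating import GratingStructure, LamellarLayer
from .multilayer import OpticalMaterial, Stack

__all__ = [
    "Bounds",
    "clamp_to_bounds",
    "MultilayerProblem",
    "MorphoProblem",
    "CoatingProblem",
]


@dataclass(frozen=True)
class Bounds:
    """Elementwise box bounds for a genome vector."""

    lower: np.ndarray
    upper: np.ndarray

    def __init__(self, lower, upper):
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("bounds must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
            raise ValueError("bounds must be finite")
        if np.any(lower > upper):
            raise ValueError("lower bound exceeds upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dimension(self) -> int:
        return self.lower.size

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower


def clamp_to_bounds(vector, bounds: Bounds) -> np.ndarray:
    """Componentwise projection onto the box; idempotent."""
    v = np.asarray(vector, dtype=float)
    if v.shape != bounds.lower.shape:
        raise ValueError(
            f"dimension mismatch: vector {v.shape} vs bounds {bounds.lower.shape}"
        )
    return np.minimum(np.maximum(v, bounds.lower), bounds.upper)


@dataclass(frozen=True)
class MultilayerProblem:
    """Multilayer mirror search space.

    In ``free_index`` mode the genome is ``[t_1..t_k, n_1..n_k]``; in
    ``forced_alternation`` mode it is ``[t_1..t_k]`` and indices strictly
    alternate between ``index_range`` extremes starting with
    ``alternation_start`` ("high" or "low").
    """

    n_layers: int
    mode: str = "free_index"
    index_range: tuple = (1.4, 1.7)
    thickness_range: tuple = (0.0, 300.0)
    alternation_start: str = "high"
    incidence_index: complex = 1.0
    substrate_index: complex = 1.0

    def __post_init__(self):
        if self.mode not in ("free_index", "forced_alternation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.alternation_start not in ("high", "low"):
            raise ValueError(f"alternation_start must be 'high' or 'low'")

    @property
    def dimension(self) -> int:
        return 2 * self.n_layers if self.mode == "free_index" else self.n_layers

    def bounds(self) -> Bounds:
        k = self.n_layers
        t_lo, t_hi = self.thickness_range
        if self.mode == "free_index":
            n_lo, n_hi = self.index_range
            return Bounds([t_lo] * k + [n_lo] * k, [t_hi] * k + [n_hi] * k)
        return Bounds([t_lo] * k, [t_hi] * k)

    def decode(self, genome) -> Stack:
        b = self.bounds()
        x = clamp_to_bounds(genome, b)
        k = self.n_layers
        thick = x[:k]
        if self.mode == "free_index":
            idx = x[k:]
        else:
            n_lo, n_hi = self.index_range
            first_high = self.alternation_start == "high"
            idx = [
                (n_hi if (j % 2 == 0) == first_high else n_lo) for j in range(k)
            ]
        layers = [(OpticalMaterial(complex(n)), t) for n, t in zip(idx, thick)]
        return Stack(self.incidence_index, layers, self.substrate_index)


@dataclass(frozen=True)
class MorphoProblem:
    """Morpho-style block-grating search space.

    Decodes to an alternating sequence of block layers (one chitin interval
    of width ``w_j`` at left-edge offset ``x_j``, air background, thickness
    ``h_j``) and homogeneous air spacers of thickness ``g_j``, top to bottom,
    all sharing the fixed horizontal period ``d``. Offsets wrap modulo ``d``;
    ``stacked`` alignment forces all blocks onto one common centre.
    """

    n_blocks: int
    period: float = 600.0
    alignment: str = "free"
    chitin_index: float = 1.56
    width_range: tuple = (10.0, 600.0)
    height_range: tuple = (10.0, 600.0)
    gap_range: tuple = (10.0, 600.0)
    incidence_index: complex = 1.0
    substrate_index: complex = 1.0

    def __post_init__(self):
        if self.alignment not in ("free", "stacked"):
            raise ValueError("alignment must be 'free' or 'stacked'")

    @property
    def dimension(self) -> int:
        # free: (w, h, x, g) per block; stacked: (w, h, g) per block + shared x
        return 4 * self.n_blocks if self.alignment == "free" else 3 * self.n_blocks + 1

    def bounds(self) -> Bounds:
        w_lo, w_hi = self.width_range
        w_hi = min(w_hi, self.period)
        h_lo, h_hi = self.height_range
        g_lo, g_hi = self.gap_range
        d = self.period
        if self.alignment == "free":
            lo = [w_lo, h_lo, 0.0, g_lo] * self.n_blocks
            hi = [w_hi, h_hi, d, g_hi] * self.n_blocks
        else:
            lo = [w_lo, h_lo, g_lo] * self.n_blocks + [0.0]
            hi = [w_hi, h_hi, g_hi] * self.n_blocks + [d]
        return Bounds(lo, hi)

    def block_widths(self, genome) -> np.ndarray:
        """Decoded block widths w_j (used by the weight-penalty term)."""
        x = clamp_to_bounds(genome, self.bounds())
        step = 4 if self.alignment == "free" else 3
        return x[0 : step * self.n_blocks : step]

    def decode(self, genome) -> GratingStructure:
        x = np.asarray(genome, dtype=float).copy()
        d = self.period
        # horizontal offsets wrap modulo the period rather than clamping
        if self.alignment == "free":
            x[2 : 4 * self.n_blocks : 4] %= d
        else:
            x[-1] %= d
        x = clamp_to_bounds(x, self.bounds())
        layers = []
        if self.alignment == "free":
            blocks = x[: 4 * self.n_blocks].reshape(self.n_blocks, 4)
            for w, h, x0, g in blocks:
                x0 = x0 % d
                layers.append(
                    LamellarLayer(h, [(x0, x0 + w, self.chitin_index)], 1.0)
                )
                layers.append(LamellarLayer(g, [], 1.0))
        else:
            centre = x[-1] % d
            blocks = x[: 3 * self.n_blocks].reshape(self.n_blocks, 3)
            for w, h, g in blocks:
                x0 = (centre - w / 2.0) % d
                layers.append(
                    LamellarLayer(h, [(x0, x0 + w, self.chitin_index)], 1.0)
                )
                layers.append(LamellarLayer(g, [], 1.0))
        return GratingStructure(d, layers, self.incidence_index, self.substrate_index)


@dataclass(frozen=True)
class CoatingProblem:
    """Anti-reflective coating on an absorbing solar cell.

    The genome holds the thicknesses of the coating layers, which alternate
    between ``index_pair`` starting with the lower index at the top. The
    decoded stack is coating + absorber layer over ``back_index``.
    """

    n_coating_layers: int
    absorber: OpticalMaterial
    absorber_thickness: float = 89.0
    index_pair: tuple = (1.4, 1.7)
    thickness_range: tuple = (0.0, 300.0)
    incidence_index: complex = 1.0
    back_index: complex = 1.0

    @property
    def dimension(self) -> int:
        return self.n_coating_layers

    @property
    def absorber_layer_position(self) -> int:
        """Index of the absorber within the decoded stack's layer list."""
        return self.n_coating_layers

    def bounds(self) -> Bounds:
        t_lo, t_hi = self.thickness_range
        k = self.n_coating_layers
        return Bounds([t_lo] * k, [t_hi] * k)

    def decode(self, genome) -> Stack:
        x = clamp_to_bounds(genome, self.bounds())
        n_lo, n_hi = min(self.index_pair), max(self.index_pair)
        layers = [
            (OpticalMaterial(n_lo if j % 2 == 0 else n_hi), t)
            for j, t in enumerate(x)
        ]
        layers.append((self.absorber, self.absorber_thickness))
        return Stack(self.incidence_index, layers, self.back_index)
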