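"""Finite-difference derivative rules on uniform grids with dynamic stencils.

A stencil is a set of integer grid offsets ``s_1..s_N`` around a point of
interest.  The weights ``c_1..c_N`` of the corresponding derivative rule of
order ``d`` solve the Vandermonde moment system

    sum_j c_j * s_j**k = d! * delta(k, d),   k = 0..N-1,

which makes the rule exact for every polynomial of degree <= N-1.  Because
that system is notoriously ill-conditioned in floating point (already at
N = 7), the solve is done in exact rational arithmetic and converted to
floats only at the end.

Near the ends of the data the centered stencil would reach outside the grid,
so the point of interest is shifted inside a one-sided or lopsided stencil
("dynamic" placement): every grid index gets its own offset list, all of
whose points stay inside the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Sequence

import numpy as np
import sympy


class StencilError(ValueError):
    """Invalid stencil: repeated offsets or too few points for the order."""


@dataclass(frozen=True)
class Stencil:
    """Integer offsets around a point of interest plus a derivative order."""

    offsets: tuple[int, ...]
    order: int = 1

    def __post_init__(self) -> None:
        offs = tuple(int(s) for s in self.offsets)
        object.__setattr__(self, "offsets", offs)
        if len(set(offs)) != len(offs):
            raise StencilError(f"repeated offsets in stencil {offs}")
        if self.order < 0:
            raise StencilError("derivative order must be >= 0")
        if len(offs) <= self.order:
            raise StencilError(
                f"stencil with N={len(offs)} points cannot produce a "
                f"derivative of order d={self.order} (need N >= d + 1)"
            )

    @property
    def n_points(self) -> int:
        return len(self.offsets)


@dataclass(frozen=True)
class CoefficientSet:
    """Solved finite-difference weights aligned with a stencil's offsets."""

    offsets: tuple[int, ...]
    coefficients: tuple[Fraction, ...]
    order: int
    exact: bool = True

    def as_floats(self) -> np.ndarray:
        return np.array([float(c) for c in self.coefficients], dtype=float)

    def moment_residuals(self) -> list[Fraction]:
        """Exact residuals of the defining moment system (all zero if valid)."""
        n = len(self.offsets)
        fact_d = Fraction(sympy.factorial(self.order))
        res = []
        for k in range(n):
            lhs = sum(
                c * Fraction(s) ** k for c, s in zip(self.coefficients, self.offsets)
            )
            rhs = fact_d if k == self.order else Fraction(0)
            res.append(lhs - rhs)
        return res


@lru_cache(maxsize=512)
def _solve_exact(offsets: tuple[int, ...], order: int) -> tuple[Fraction, ...]:
    n = len(offsets)
    a = sympy.Matrix(n, n, lambda k, j: sympy.Integer(offsets[j]) ** k)
    rhs = sympy.Matrix(
        n, 1, lambda k, _: sympy.factorial(order) if k == order else 0
    )
    sol = a.solve(rhs)
    return tuple(Fraction(int(c.p), int(c.q)) for c in sol)


def fd_coefficients(stencil: Stencil) -> CoefficientSet:
    """Solve the moment system for a stencil's derivative weights.

    The solution is exact (``fractions.Fraction``); use
    :meth:`CoefficientSet.as_floats` for numerical work.
    """
    coeffs = _solve_exact(stencil.offsets, stencil.order)
    return CoefficientSet(stencil.offsets, coeffs, stencil.order, exact=True)


def boundary_stencils(n_grid: int, n_points: int = 7) -> list[list[int]]:
    """Per-index offset lists keeping all points inside ``[0, n_grid - 1]``.

    Interior indices get the centered stencil; indices near either end get
    progressively one-sided stencils of the same width, so the derivative
    retains full polynomial order at the boundaries.
    """
    if n_grid < n_points:
        raise ValueError(
            f"grid of {n_grid} nodes is shorter than the {n_points}-point stencil"
        )
    half = (n_points - 1) // 2
    out = []
    for i in range(n_grid):
        lo = min(max(i - half, 0), n_grid - n_points)
        out.append([lo - i + j for j in range(n_points)])
    return out


def differentiate(
    values: Sequence[float],
    step: float = 1.0,
    n_points: int = 7,
    order: int = 1,
) -> np.ndarray:
    """Estimate the derivative of uniformly sampled values at every sample.

    Parameters
    ----------
    values
        Samples of a smooth function on a uniform grid.
    step
        Grid spacing (same units as the independent variable).
    n_points
        Stencil width N; the rule is exact for polynomials of degree
        <= N - 1.
    order
        Derivative order d (d < N).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if step <= 0:
        raise ValueError("step must be positive")
    n = y.size
    stencils = boundary_stencils(n, n_points)
    out = np.empty(n, dtype=float)
    scale = step**order
    for i, offs in enumerate(stencils):
        c = fd_coefficients(Stencil(tuple(offs), order)).as_floats()
        idx = np.array(offs) + i
        out[i] = float(c @ y[idx]) / scale
    return out
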