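"""Cubic-regression-spline basis over lag windows for the FLM climate term.

The lag-coefficient function f_c(w) of the functional linear model is a
natural cubic spline over the window index, parameterized by its values at
the knots (the "cr" value-based form): with knots k_1 < ... < k_K spanning
[1, W], the basis matrix B (W x K) satisfies

    f_c(w) = sum_j B[w, j] * gamma_j,

where f_c is the natural cubic interpolant of the points (k_j, gamma_j).
Rows at knot positions therefore reduce to the identity pattern, so priors on
gamma are priors on f_c at the knots.  No smoothing penalty is applied;
regularization enters only through the prior on gamma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["FlmTerm", "build_cr_basis", "eval_flm", "cr_basis_matrix"]


@dataclass
class FlmTerm:
    """Spline basis over lag windows plus (optionally) coefficients gamma."""

    n_windows: int
    knots: np.ndarray            # (K,) strictly increasing, spanning [1, W]
    basis: np.ndarray            # (W, K)
    gamma: Optional[np.ndarray] = None
    variable_name: str = "climate"

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
            if self.gamma.shape != (len(self.knots),):
                raise ValueError("gamma length must equal the number of knots")
        if self.basis.shape != (self.n_windows, len(self.knots)):
            raise ValueError("basis must be (n_windows, n_knots)")

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    def with_gamma(self, gamma: np.ndarray) -> "FlmTerm":
        return FlmTerm(self.n_windows, self.knots, self.basis,
                       np.asarray(gamma, dtype=float), self.variable_name)


def cr_basis_matrix(x_eval: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Evaluate the value-based natural-cubic-spline basis at ``x_eval``.

    Column j is the natural cubic interpolant through the unit vector e_j at
    the knots, evaluated at ``x_eval``; linear in the knot values by
    construction.
    """
    knots = np.asarray(knots, dtype=float)
    eye = np.eye(len(knots))
    # CubicSpline broadcasts over trailing axes of y: one spline per column.
    cs = CubicSpline(knots, eye, axis=0, bc_type="natural")
    return cs(np.asarray(x_eval, dtype=float))


def build_cr_basis(n_windows: int, n_knots: int = 8,
                   knots: Optional[np.ndarray] = None,
                   variable_name: str = "climate") -> FlmTerm:
    """Construct the cr basis with evenly spaced knots over [1, n_windows].

    Custom knot positions may be supplied; they must be strictly increasing
    and span the full window range.
    """
    if n_knots < 4:
        raise ValueError("cubic regression spline needs at least 4 knots")
    if n_knots > n_windows:
        raise ValueError("cannot place more knots than windows")
    if knots is None:
        knots = np.linspace(1.0, float(n_windows), n_knots)
    else:
        knots = np.asarray(knots, dtype=float)
        if len(knots) != n_knots:
            raise ValueError("len(knots) must equal n_knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if not (knots[0] == 1.0 and knots[-1] == float(n_windows)):
            raise ValueError("knots must span [1, n_windows]")
    windows = np.arange(1, n_windows + 1, dtype=float)
    B = cr_basis_matrix(windows, knots)
    return FlmTerm(n_windows, knots, B, None, variable_name)


def eval_flm(term: FlmTerm) -> np.ndarray:
    """Realized lag-coefficient function f_c(w) = B @ gamma for w = 1..W."""
    if term.gamma is None:
        raise ValueError("gamma is unset")
    if term.gamma.shape != (term.basis.shape[1],):
        raise ValueError("gamma / basis dimension mismatch")
    return term.basis @ term.gamma
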