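"""Buckling-mode shapes reconstructed from the converged eigen-series.

The lateral deflection follows from the deflection-angle series by
term-wise integration, y(u) proportional to B(u) + c3 with
B(u) = sum_k a_k(lambda_c) u^(k+1) / (k+1).  The fixed-end condition
y(1) = 0 sets the integration constant, and the arbitrary amplitude is
removed by normalising with the free-end deflection, which is where the
maximum occurs (verified numerically, not assumed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P

from .density import CumulativeWeightShape
from .eigensolver import (
    DEFAULT_ORDER,
    SolverSettings,
    build_characteristic,
    smallest_positive_root,
)


@dataclass(frozen=True)
class BucklingMode:
    """Normalised first buckling mode y/y_max sampled on u_grid.

    u runs from the free end (u = 0, deflection ratio 1) to the fixed end
    (u = 1, deflection ratio 0).
    """

    u_grid: np.ndarray
    deflection_ratio: np.ndarray
    xi_c: float


def mode_shape(
    shape: CumulativeWeightShape,
    settings: SolverSettings | None = None,
    u_grid: np.ndarray | None = None,
    N: int = DEFAULT_ORDER,
) -> BucklingMode:
    """First buckling mode of the column with cumulative weight ``shape``.

    Solves the eigenproblem, integrates the theta-series term-wise
    (b_{k+1} = a_k / (k+1)), anchors y(1) = 0 and normalises by y(0).
    Raises if the maximum deflection does not occur at the free end.
    """
    if u_grid is None:
        u_grid = np.linspace(0.0, 1.0, 101)
    u_grid = np.asarray(u_grid, dtype=float)
    if u_grid.ndim != 1 or np.any(u_grid < 0) or np.any(u_grid > 1):
        raise ValueError("u_grid must be 1-D within [0, 1]")
    if np.any(np.diff(u_grid) < 0):
        raise ValueError("u_grid must be sorted ascending")

    series = build_characteristic(shape, N)
    eig = smallest_positive_root(series, settings)
    a_vals = np.array([P.polyval(eig.lambda_c, np.asarray(c)) for c in series.a_coeffs])
    # y(u) - y(1) = B(u) - B(1), with B the term-wise antiderivative of theta
    b = np.concatenate(([0.0], a_vals / np.arange(1, a_vals.size + 1)))
    B1 = P.polyval(1.0, b)
    y = P.polyval(u_grid, b) - B1
    y0 = -B1  # y(0) with the same anchoring
    # checked invariant: the free end is the deflection maximum
    dense = P.polyval(np.linspace(0.0, 1.0, 1001), b) - B1
    if np.max(np.abs(dense)) > abs(y0) * (1.0 + 1e-9):
        raise RuntimeError(
            "maximum deflection did not occur at the free end; "
            "mode normalisation is invalid for this shape"
        )
    return BucklingMode(u_grid=u_grid, deflection_ratio=y / y0, xi_c=eig.xi_c)
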