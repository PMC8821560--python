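"""Physical critical heights, ratio curves, and the real-tree application.

The eigensolver delivers the dimensionless critical length xi_c; here it is
converted to metres via l_c = xi_c / omega, normalised into the
critical-height ratio

    f = xi_c / (4 C)^(1/3),        C = 1.959 (Greenhill's constant),

which compares a variable-density column with the uniform one of the same
section (for models E/F, with the branchless tree, W_R = 0), and turned
into the quantities a tree ecologist cares about: ratio extremes over the
realistic parameter region, the safety factor against the observed heights
of real trees, and closed-form engineering approximations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .density import DensityModel, cumulative_weight_shape, make_density_model
from .eigensolver import DEFAULT_ORDER, SolverSettings, solve_xi
from .section import ColumnSection

#: Greenhill's constant for the uniform heavy cylinder.
C_GREENHILL = 1.959

#: Reference safety factor of Greenhill's critical height against observed
#: tree heights (Niklas).
S0_NIKLAS = 4.0


def _greenhill_norm() -> float:
    return (4.0 * C_GREENHILL) ** (1.0 / 3.0)


@dataclass(frozen=True)
class CriticalHeightResult:
    """Critical height of one column/density combination."""

    l_c: float  # m
    xi_c: float
    f_ratio: float
    model: str
    n: float
    W_R: float | None = None
    N_used: int = DEFAULT_ORDER
    C_greenhill: float = C_GREENHILL


@dataclass(frozen=True)
class TreeApplicationResult:
    """Ratio extremes and safety-factor range over a tree-parameter region."""

    f_min: float
    f_max: float
    S_low: float
    S_high: float
    S0: float = S0_NIKLAS


def critical_height(
    section: ColumnSection,
    model: DensityModel,
    settings: SolverSettings | None = None,
    N: int = DEFAULT_ORDER,
) -> CriticalHeightResult:
    """Solve the eigenproblem for ``model`` and scale to metres.

    l_c = xi_c / omega; the ratio field normalises by the uniform-density
    (Greenhill) height of the same section.
    """
    res = solve_xi(cumulative_weight_shape(model), N, settings)
    return CriticalHeightResult(
        l_c=res.xi_c / section.omega,
        xi_c=res.xi_c,
        f_ratio=res.xi_c / _greenhill_norm(),
        model=model.model_id,
        n=model.n,
        W_R=model.W_R,
        N_used=N,
    )


def height_ratio(
    model_id: str,
    n: float,
    settings: SolverSettings | None = None,
    N: int = DEFAULT_ORDER,
) -> float:
    """Critical-height ratio f(n) = xi_c(n) / (4C)^(1/3) for models A-D.

    Dimensionless and independent of the column section.
    """
    shape = cumulative_weight_shape(make_density_model(model_id, n))
    return solve_xi(shape, N, settings).xi_c / _greenhill_norm()


def tree_height_ratio(
    model_id: str,
    n: float,
    W_R: float,
    settings: SolverSettings | None = None,
    N: int = DEFAULT_ORDER,
) -> float:
    """f(n, W_R) for the trunk-plus-branches models E/F.

    Normalised by the branchless tree (W_R = 0), whose eigenvalue is the
    uniform-column one, so the same (4C)^(1/3) denominator applies.
    """
    if model_id not in ("E", "F"):
        raise ValueError(f"tree_height_ratio applies to models E/F, got {model_id!r}")
    shape = cumulative_weight_shape(make_density_model(model_id, n, W_R))
    return solve_xi(shape, N, settings).xi_c / _greenhill_norm()


def ratio_extremes(
    model_id: str,
    n_range: tuple[float, float],
    WR_range: tuple[float, float] | None = None,
    grid_steps: tuple[int, int] = (21, 21),
    settings: SolverSettings | None = None,
    N: int = DEFAULT_ORDER,
) -> tuple[float, float]:
    """(f_min, f_max) over a tensor grid of the parameter region.

    For models A-D only ``n_range`` is used; for E/F a ``WR_range`` is
    required and the grid is ``grid_steps[0] x grid_steps[1]``.
    """
    n_lo, n_hi = n_range
    if n_lo > n_hi:
        raise ValueError("empty n range")
    ns = np.linspace(n_lo, n_hi, grid_steps[0])
    if model_id in ("E", "F"):
        if WR_range is None:
            raise ValueError(f"model {model_id} requires a W_R range")
        w_lo, w_hi = WR_range
        if w_lo > w_hi:
            raise ValueError("empty W_R range")
        wrs = np.linspace(w_lo, w_hi, grid_steps[1])
        values = [
            tree_height_ratio(model_id, n, wr, settings, N) for n in ns for wr in wrs
        ]
    else:
        values = [height_ratio(model_id, n, settings, N) for n in ns]
    return float(min(values)), float(max(values))


def safety_factor_range(
    f_min: float, f_max: float, S0: float = S0_NIKLAS
) -> tuple[float, float]:
    """Scale the reference safety factor by the ratio extremes.

    With S0 the uniform-column safety factor against observed tree height,
    the branch-aware factor spans (S0 f_min, S0 f_max), rounded to one
    decimal as conventionally reported.
    """
    if not (0 < f_min <= f_max):
        raise ValueError("require 0 < f_min <= f_max")
    if S0 <= 0:
        raise ValueError("S0 must be positive")
    return round(S0 * f_min, 1), round(S0 * f_max, 1)


def tree_application(
    model_id: str,
    n_range: tuple[float, float] = (0.0, 1.0),
    WR_range: tuple[float, float] = (0.1, 0.6),
    grid_steps: tuple[int, int] = (21, 21),
    settings: SolverSettings | None = None,
    N: int = DEFAULT_ORDER,
    S0: float = S0_NIKLAS,
) -> TreeApplicationResult:
    """Ratio extremes and safety range over the realistic-tree region."""
    f_min, f_max = ratio_extremes(model_id, n_range, WR_range, grid_steps, settings, N)
    S_low, S_high = safety_factor_range(f_min, f_max, S0)
    return TreeApplicationResult(f_min, f_max, S_low, S_high, S0)


#: Closed-form height approximations fitted to the ratio curves; each maps
#: n to the multiplier of the Greenhill height G = (C E r^2 / gamma)^(1/3).
_SIMPLIFIED = {
    "A": lambda n: (11.0 / 10.0) * math.exp(-3.0 * n / 40.0),
    "B": lambda n: n ** (-1.0 / 5.0),
    "C": lambda n: math.exp(n / 5.0),
    "D": lambda n: math.exp(n / 4.0),
}


def greenhill_height(section: ColumnSection) -> float:
    """Greenhill's uniform-column critical height (C E r^2 / gamma)^(1/3), m."""
    return (C_GREENHILL * section.E * section.r**2 / section.gamma0) ** (1.0 / 3.0)


def simplified_height(model_id: str, n: float, section: ColumnSection) -> float:
    """Closed-form critical height in metres (fraction-coefficient fits).

    Applicable over each model's full n range, except model B whose
    power-law form excludes n = 0.
    """
    if model_id not in _SIMPLIFIED:
        raise ValueError(f"no simplified formula for model {model_id!r}")
    lo, hi = (0.0, 3.0) if model_id in ("A", "B") else (-1.0, 1.0)
    if not (lo <= n <= hi) or (model_id == "B" and n == 0.0):
        raise ValueError(
            f"n={n} outside the applicable limit of model {model_id}'s formula"
        )
    return _SIMPLIFIED[model_id](n) * greenhill_height(section)


def allowable_weight_ratio(f: float) -> float:
    """Allowable unit-weight multiplier at fixed height, f**3.

    Since l_c scales as gamma^(-1/3), a column whose critical height is f
    times the uniform one can carry f^3 times the unit weight before
    buckling at the same height.
    """
    if f <= 0:
        raise ValueError("f must be positive")
    return f**3
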