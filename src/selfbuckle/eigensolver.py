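"""Series eigensolver for the self-buckling boundary-value problem.

On the unit domain u = x / l_c (u = 0 at the free end) the linearised
deflection-angle equation for a heavy cantilever is

    theta''(u) + lambda * W(u) * theta(u) = 0,
    theta'(0) = 0 (free end),  theta(1) = 0 (fixed end),

where W(u) is the dimensionless cumulative weight of the column above u
and lambda = (omega l_c)^3 = xi_c^3 is the single dimensionless eigenvalue.
Writing theta as a truncated power series in u with a_0 = 1 (the arbitrary
amplitude) and a_1 = 0 (free-end condition) gives the recurrence

    a_{k+2} = -lambda / ((k+2)(k+1)) * sum_j w_j a_{k-j},

with each a_k a polynomial in lambda.  The fixed-end condition turns the
series value at u = 1 into the characteristic polynomial
F(lambda) = sum_k a_k(lambda); its smallest positive root gives the
buckling threshold, xi_c = lambda_c^(1/3) and l_c = xi_c / omega.

The smallest root is found by an upward bracket scan followed by secant
iteration on the xi = lambda^(1/3) scale.  The truncation order N is
validated by the relative change of xi_c between successive orders
(convergence-judgement function).  A fixed-step RK4 shooting integrator is
provided as an independent cross-check of the series route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P

from .density import CumulativeWeightShape

#: Default truncation order of the theta-series (highest power of u kept).
DEFAULT_ORDER = 25


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings for the series solver.

    N0, dN drive the order-selection sweep; judge_tol is the threshold on
    the convergence-judgement function |xi_N - xi_{N+dN}| / xi_{N+dN};
    secant_tol is the relative convergence criterion on the xi iterates;
    bracket_step and bracket_max control the upward eigenvalue scan in
    lambda.
    """

    N0: int = 5
    dN: int = 5
    judge_tol: float = 1.0e-4
    secant_tol: float = 1.0e-5
    bracket_step: float = 0.1
    bracket_max: float = 500.0
    max_order: int = 100

    def __post_init__(self) -> None:
        if self.N0 <= 0 or self.dN <= 0:
            raise ValueError("N0 and dN must be positive")
        if not (0 < self.judge_tol < 1 and 0 < self.secant_tol < 1):
            raise ValueError("judge_tol and secant_tol must lie in (0, 1)")
        if self.bracket_step <= 0 or self.bracket_max <= 0:
            raise ValueError("bracket parameters must be positive")


@dataclass(frozen=True)
class CharacteristicSeries:
    """Truncated theta-series and its characteristic polynomial.

    ``a_coeffs[k]`` holds the ascending lambda-polynomial coefficients of
    a_k; ``F_coeffs`` those of F(lambda) = sum_{k<=N} a_k(lambda), the
    series value of theta at the fixed end u = 1.
    """

    N: int
    a_coeffs: tuple[tuple[float, ...], ...]
    F_coeffs: tuple[float, ...]

    def F(self, lam):
        """Evaluate the characteristic polynomial at lambda."""
        return P.polyval(lam, np.asarray(self.F_coeffs))

    def theta(self, u, lam: float):
        """Deflection-angle series theta(u) at a given eigenvalue."""
        ak = np.array([P.polyval(lam, np.asarray(c)) for c in self.a_coeffs])
        return P.polyval(np.asarray(u, dtype=float), ak)


@dataclass(frozen=True)
class EigenResult:
    """Smallest positive characteristic root and solver diagnostics."""

    lambda_c: float
    xi_c: float
    N_used: int
    iterations: int
    judge_value: float | None = None


class BucklingRootError(RuntimeError):
    """No buckling root found, or the iteration failed to converge."""


def build_characteristic(
    shape: CumulativeWeightShape, N: int = DEFAULT_ORDER
) -> CharacteristicSeries:
    """Generate the series coefficients a_k(lambda) up to order N.

    Each a_k is represented by its ascending coefficients in lambda; the
    recurrence multiplies by -lambda/((k+2)(k+1)), i.e. shifts the lambda
    polynomial up one degree.
    """
    if N < 3:
        raise ValueError("N must be >= 3 for any lambda dependence to survive")
    w = shape.coeffs  # w[j-1] multiplies u^j in W(u)
    a: list[np.ndarray] = [np.array([1.0]), np.array([0.0])]
    for k in range(2, N + 1):
        # coefficient of u^(k-2) in W(u) * theta(u): sum_j w_j a_{k-2-j}
        acc = np.array([0.0])
        for j, wj in enumerate(w, start=1):
            idx = k - 2 - j
            if idx < 0:
                break
            if wj == 0.0:
                continue
            acc = P.polyadd(acc, wj * a[idx])
        shifted = np.concatenate(([0.0], acc)) / (k * (k - 1))  # * lambda
        a.append(-shifted)
    F = np.array([0.0])
    for ak in a:
        F = P.polyadd(F, ak)
    return CharacteristicSeries(
        N=N,
        a_coeffs=tuple(tuple(ak) for ak in a),
        F_coeffs=tuple(np.trim_zeros(F, "b") if np.any(F) else (0.0,)),
    )


def _bracket(f, step: float, fmax: float) -> tuple[float, float]:
    """Scan lambda upward from 0 until f changes sign."""
    lo, flo = 0.0, f(0.0)
    lam = step
    while lam <= fmax + 1e-12:
        fhi = f(lam)
        if flo * fhi < 0:
            return lo, lam
        if fhi == 0.0:
            return lam, lam
        lo, flo = lam, fhi
        lam += step
    raise BucklingRootError(
        f"no buckling root found: characteristic function has no sign change "
        f"for lambda in (0, {fmax}]"
    )


def smallest_positive_root(
    series: CharacteristicSeries, settings: SolverSettings | None = None
) -> EigenResult:
    """Locate the smallest positive root of F by bracket scan plus secant.

    The secant update runs on the xi = lambda^(1/3) scale and stops when
    the relative change of the xi iterates drops below ``secant_tol``.
    """
    settings = settings or SolverSettings()
    f = lambda lam: float(series.F(lam))
    lam_lo, lam_hi = _bracket(f, settings.bracket_step, settings.bracket_max)
    if lam_lo == lam_hi:
        xi = lam_lo ** (1.0 / 3.0)
        return EigenResult(lam_lo, xi, series.N, 0)
    g = lambda xi: f(xi**3)
    x_prev, x_cur = lam_lo ** (1.0 / 3.0), lam_hi ** (1.0 / 3.0)
    f_prev, f_cur = g(x_prev), g(x_cur)
    for k in range(1, 101):
        if f_cur == f_prev:
            break
        x_next = x_cur - f_cur * (x_cur - x_prev) / (f_cur - f_prev)
        x_prev, f_prev = x_cur, f_cur
        x_cur = x_next
        f_cur = g(x_cur)
        if abs(x_cur - x_prev) / abs(x_cur) <= settings.secant_tol:
            return EigenResult(x_cur**3, x_cur, series.N, k)
    raise BucklingRootError("secant iteration did not converge in 100 steps")


def solve_xi(
    shape: CumulativeWeightShape,
    N: int = DEFAULT_ORDER,
    settings: SolverSettings | None = None,
) -> EigenResult:
    """Convenience: build the series at order N and return its smallest root."""
    return smallest_positive_root(build_characteristic(shape, N), settings)


def convergence_judgement(
    shape: CumulativeWeightShape,
    N: int,
    dN: int,
    settings: SolverSettings | None = None,
) -> float:
    """Relative change of xi_c between truncation orders N and N + dN."""
    xi_lo = solve_xi(shape, N, settings).xi_c
    xi_hi = solve_xi(shape, N + dN, settings).xi_c
    return abs(xi_lo - xi_hi) / abs(xi_hi)


def select_expansion_order(
    shape: CumulativeWeightShape, settings: SolverSettings | None = None
) -> tuple[int, float]:
    """Smallest truncation order whose judgement value passes ``judge_tol``.

    Starting at N0, the order is raised by dN until
    |xi_N - xi_{N+dN}| / xi_{N+dN} <= judge_tol; returns the smallest such
    N and the judgement value.
    """
    settings = settings or SolverSettings()
    N = settings.N0
    while N <= settings.max_order:
        try:
            judge = convergence_judgement(shape, N, settings.dN, settings)
        except BucklingRootError:
            # a truncation this low can lose the root entirely (e.g. a
            # rootless quadratic): treat as not converged and raise N
            N += settings.dN
            continue
        if judge <= settings.judge_tol:
            return N, judge
        N += settings.dN
    raise BucklingRootError(
        f"series did not converge below order {settings.max_order}"
    )


def shooting_oracle(
    shape: CumulativeWeightShape,
    settings: SolverSettings | None = None,
    n_steps: int = 2000,
    tol: float = 1e-8,
) -> float:
    """Independent xi_c by RK4 shooting and bisection (cross-check route).

    Integrates theta'' + lambda W(u) theta = 0 from the free end with
    theta(0) = 1, theta'(0) = 0 using fixed-step classical RK4, brackets
    the smallest lambda with theta(1) = 0 by the same upward scan as the
    series solver, and bisects to relative width ``tol``.
    """
    settings = settings or SolverSettings()
    wcoeffs = tuple(shape.coeffs)
    h = 1.0 / n_steps
    # precompute W(u) on the half-step grid once; RK4 stage nodes only ever
    # sit on u = i*h/2, so the batched and scalar integrators share it
    u_half = np.arange(2 * n_steps + 1) * (h / 2.0)
    W_half = P.polyval(u_half, np.concatenate(([0.0], wcoeffs)))

    def theta_end(lam: float) -> float:
        """theta(1) for a single lambda; classical RK4 with scalar floats."""
        y, yp = 1.0, 0.0
        W = W_half
        for i in range(n_steps):
            w0, wm, w1 = W[2 * i], W[2 * i + 1], W[2 * i + 2]
            k1y, k1p = yp, -lam * w0 * y
            k2y, k2p = yp + h / 2 * k1p, -lam * wm * (y + h / 2 * k1y)
            k3y, k3p = yp + h / 2 * k2p, -lam * wm * (y + h / 2 * k2y)
            k4y, k4p = yp + h * k3p, -lam * w1 * (y + h * k3y)
            y, yp = (
                y + h / 6 * (k1y + 2 * k2y + 2 * k3y + k4y),
                yp + h / 6 * (k1p + 2 * k2p + 2 * k3p + k4p),
            )
        return y

    def theta_end_batch(lams: np.ndarray) -> np.ndarray:
        """theta(1) for many lambdas at once (used only for bracketing)."""
        y = np.ones_like(lams)
        yp = np.zeros_like(lams)
        W = W_half
        for i in range(n_steps):
            w0, wm, w1 = W[2 * i], W[2 * i + 1], W[2 * i + 2]
            k1y, k1p = yp, -lams * (w0 * y)
            k2y, k2p = yp + h / 2 * k1p, -lams * (wm * (y + h / 2 * k1y))
            k3y, k3p = yp + h / 2 * k2p, -lams * (wm * (y + h / 2 * k2y))
            k4y, k4p = yp + h * k3p, -lams * (w1 * (y + h * k3y))
            y = y + h / 6 * (k1y + 2 * k2y + 2 * k3y + k4y)
            yp = yp + h / 6 * (k1p + 2 * k2p + 2 * k3p + k4p)
        return y

    # upward scan in blocks until the first sign change
    step, fmax = settings.bracket_step, settings.bracket_max
    lo = hi = None
    prev_lam, prev_val = 0.0, 1.0  # theta(1) at lambda=0 is exactly 1
    block = 200
    lam0 = step
    while lam0 <= fmax + 1e-12 and lo is None:
        lams = lam0 + step * np.arange(block)
        lams = lams[lams <= fmax + 1e-12]
        if lams.size == 0:
            break
        vals = theta_end_batch(lams)
        all_l = np.concatenate(([prev_lam], lams))
        all_v = np.concatenate(([prev_val], vals))
        sign = all_v[:-1] * all_v[1:]
        idx = np.flatnonzero(sign < 0)
        if idx.size:
            lo, hi = float(all_l[idx[0]]), float(all_l[idx[0] + 1])
        else:
            prev_lam, prev_val = float(lams[-1]), float(vals[-1])
            lam0 = lams[-1] + step
    if lo is None:
        raise BucklingRootError(
            f"no buckling root found: shooting function has no sign change "
            f"for lambda in (0, {fmax}]"
        )
    flo = theta_end(lo)
    while (hi - lo) / hi > tol:
        mid = 0.5 * (lo + hi)
        fmid = theta_end(mid)
        if flo * fmid <= 0:
            hi = mid
        else:
            lo, flo = mid, fmid
    return (0.5 * (lo + hi)) ** (1.0 / 3.0)
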