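"""Regression of the ratio curves into simple scaling laws.

Four candidate forms are fitted to sampled (n, f(n)) curves by non-linear
least squares and compared by AIC:

    exponential  f = P1 * exp(P2 * n)
    linear       f = P3 * n + P4
    polynomial   f = P5 * n^2 + P6 * n + P7
    power        f = P8 * n^P9          (defined only for n > 0)

Fitted coefficients are then snapped to simple fractions (e.g. a fitted
exponent of 0.190 becomes 1/5) to yield closed-form engineering formulas;
that simplification is a deliberate presentation step, separate from the
fitting itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .density import N_RANGES
from .eigensolver import DEFAULT_ORDER, SolverSettings
from .heights import height_ratio

FORMS = ("exponential", "linear", "polynomial", "power")

_MODELS = {
    "exponential": (lambda n, p1, p2: p1 * np.exp(p2 * n), ("P1", "P2")),
    "linear": (lambda n, p3, p4: p3 * n + p4, ("P3", "P4")),
    "polynomial": (lambda n, p5, p6, p7: p5 * n**2 + p6 * n + p7, ("P5", "P6", "P7")),
    "power": (lambda n, p8, p9: p8 * np.power(n, p9), ("P8", "P9")),
}


@dataclass(frozen=True)
class RegressionFit:
    """One fitted regression form with inference and AIC."""

    form: str
    params: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    aic: float
    rss: float
    m: int
    n_values: tuple[float, ...]

    def predict(self, n):
        func, names = _MODELS[self.form]
        return func(np.asarray(n, dtype=float), *(self.params[k] for k in names))


#: Default sampling step of the ratio curve per model.  These values make
#: the fitted parameters and AICs of the wide-range models (A/B, step 0.1)
#: and the unit-total-weight models (C/D, step 0.05) land on the published
#: regression table of the tree-buckling study this package reproduces.
DEFAULT_STEPS = {"A": 0.1, "B": 0.1, "C": 0.05, "D": 0.05}


def sample_ratio_curve(
    model_id: str,
    n_grid: np.ndarray | None = None,
    settings: SolverSettings | None = None,
    N: int = DEFAULT_ORDER,
    step: float | None = None,
) -> pd.DataFrame:
    """Sample f(n) on a grid; default grid spans the model's full range.

    Returns a DataFrame with ascending columns ``n`` and ``f``.
    """
    if n_grid is None:
        lo, hi = N_RANGES[model_id]
        if step is None:
            step = DEFAULT_STEPS.get(model_id, 0.05)
        count = int(round((hi - lo) / step))
        n_grid = np.linspace(lo, hi, count + 1)
    n_grid = np.sort(np.asarray(n_grid, dtype=float))
    f = [height_ratio(model_id, n, settings, N) for n in n_grid]
    return pd.DataFrame({"n": n_grid, "f": f})


def fit_regression(
    samples: pd.DataFrame, form: str, alpha: float = 0.05
) -> RegressionFit:
    """Non-linear least-squares fit of one form to (n, f) samples.

    p-values are two-sided t-tests on each parameter (estimate / SE, with
    m - p degrees of freedom); AIC is the full Gaussian-likelihood form
    m (ln(2 pi RSS / m) + 1) + 2 (p + 1), the convention of R's
    ``AIC()`` for nls fits.  The power-law form silently drops samples
    with n <= 0, as it is undefined there.
    """
    if form not in _MODELS:
        raise ValueError(f"unknown regression form {form!r}")
    func, names = _MODELS[form]
    n = np.asarray(samples["n"], dtype=float)
    f = np.asarray(samples["f"], dtype=float)
    if form == "power":
        keep = n > 0
        n, f = n[keep], f[keep]
    if n.size < 3:
        raise ValueError("need at least 3 usable samples")

    p0 = np.ones(len(names))
    popt, pcov = optimize.curve_fit(func, n, f, p0=p0, maxfev=20000)
    resid = f - func(n, *popt)
    rss = float(resid @ resid)
    m, p = n.size, len(names)
    se = np.sqrt(np.diag(pcov))
    with np.errstate(divide="ignore"):  # exact fits: se=0 -> p=0, aic=-inf
        tstat = popt / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df=m - p)
        aic = m * (np.log(2.0 * np.pi * rss / m) + 1.0) + 2.0 * (p + 1)
    return RegressionFit(
        form=form,
        params=dict(zip(names, map(float, popt))),
        std_errors=dict(zip(names, map(float, se))),
        p_values=dict(zip(names, map(float, pvals))),
        aic=float(aic),
        rss=rss,
        m=m,
        n_values=tuple(map(float, n)),
    )


def compare_fits(fits: list[RegressionFit]) -> list[RegressionFit]:
    """Rank fits of the same curve by ascending AIC (best first).

    The power-law fit legitimately uses the n > 0 subset of the common
    grid; any other sample mismatch is an error.
    """
    if not fits:
        raise ValueError("no fits to compare")
    full = max(fits, key=lambda fit: fit.m)
    for fit in fits:
        expected = full.n_values if fit.form != "power" else tuple(
            n for n in full.n_values if n > 0
        )
        if fit.n_values != expected:
            raise ValueError("fits were computed over differing sample sets")
    return sorted(fits, key=lambda fit: fit.aic)


def simplify_coefficient(value: float, max_denominator: int = 40) -> Fraction:
    """Snap a fitted coefficient to the nearest q-th, q = max_denominator.

    Rounds value to the nearest multiple of 1/q and reduces: 0.190 with
    q = 40 gives 1/5, -0.073 gives -3/40.  Prefactors are conventionally
    snapped with q = 10 (1.081 -> 11/10).
    """
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    if max_denominator < 1:
        raise ValueError("max_denominator must be >= 1")
    return Fraction(round(value * max_denominator), max_denominator)


def regression_table(fits: list[RegressionFit], model_id: str) -> pd.DataFrame:
    """Long-form table: model, form, parameter, estimate, std_error, p_value, aic."""
    rows = []
    for fit in fits:
        for name in fit.params:
            rows.append(
                {
                    "model": model_id,
                    "form": fit.form,
                    "parameter": name,
                    "estimate": fit.params[name],
                    "std_error": fit.std_errors[name],
                    "p_value": fit.p_values[name],
                    "aic": fit.aic,
                }
            )
    return pd.DataFrame(rows)
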