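"""Axial density distributions and their cumulative-weight shapes.

Six density models describe how mass is distributed along the column axis.
The axial coordinate is u = x / l_c with u = 0 at the FREE end (tree top)
and u = 1 at the fixed end (ground); all shapes and buckling modes use this
convention.

Normalised density shapes s(u) = rho(u l_c) / rho0:

=====  ==============================  ===========  =====================
Model  s(u)                            n range      constant-density state
=====  ==============================  ===========  =====================
A      (n - 1) u + 1                   0 <= n <= 3  n = 1
B      (1 - n) u + n                   0 <= n <= 3  n = 1
C      2 n u + (1 - n)                 -1 <= n <= 1 n = 0
D      1 - n cos(pi u)                 -1 <= n <= 1 n = 0
E      W_R * s_C(u) + 1                -1 <= n <= 1 W_R = 0
F      W_R * s_D(u) + 1                -1 <= n <= 1 W_R = 0
=====  ==============================  ===========  =====================

Models E and F add a uniform trunk (density rho_T, the reference density)
to a branch distribution shaped like C or D with branch density
rho_B = W_R * rho_T; W_R is the branch-to-trunk weight ratio.

The eigensolver only needs the dimensionless cumulative weight
W(u) = integral_0^u s(v) dv, stored as exact polynomial coefficients (the
sine term of D/F is pre-expanded in its Maclaurin series), so the
downstream recurrence is purely polynomial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

MODEL_IDS = ("A", "B", "C", "D", "E", "F")

#: Inclusive parameter range for n, per model.
N_RANGES = {
    "A": (0.0, 3.0),
    "B": (0.0, 3.0),
    "C": (-1.0, 1.0),
    "D": (-1.0, 1.0),
    "E": (-1.0, 1.0),
    "F": (-1.0, 1.0),
}


@dataclass(frozen=True)
class DensityModel:
    """One of the six axial density distributions.

    ``W_R`` (branch/trunk weight ratio) is meaningful only for models E
    and F and must be omitted otherwise.
    """

    model_id: str
    n: float
    W_R: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(
                f"model_id must be one of {MODEL_IDS}, got {self.model_id!r}"
            )
        lo, hi = N_RANGES[self.model_id]
        if not (lo <= self.n <= hi):
            raise ValueError(
                f"Model {self.model_id} requires {lo} <= n <= {hi}, got n={self.n}"
            )
        if self.model_id in ("E", "F"):
            if self.W_R is None:
                raise ValueError(f"Model {self.model_id} requires a weight ratio W_R")
            if self.W_R < 0:
                raise ValueError(f"W_R must be >= 0, got {self.W_R}")
        elif self.W_R is not None:
            raise ValueError(
                f"W_R applies only to models E and F, not {self.model_id}"
            )

    def density_shape(self, u):
        """Normalised density s(u) = rho(u l_c) / rho0 for u in [0, 1]."""
        u = np.asarray(u, dtype=float)
        n = self.n
        if self.model_id == "A":
            return (n - 1.0) * u + 1.0
        if self.model_id == "B":
            return (1.0 - n) * u + n
        if self.model_id == "C":
            return 2.0 * n * u + (1.0 - n)
        if self.model_id == "D":
            return 1.0 - n * np.cos(math.pi * u)
        base = DensityModel("C" if self.model_id == "E" else "D", n)
        return self.W_R * base.density_shape(u) + 1.0


def make_density_model(model_id: str, n: float, W_R: float | None = None) -> DensityModel:
    """Build and validate a density model (see module table for ranges)."""
    return DensityModel(model_id=model_id, n=n, W_R=W_R)


@dataclass(frozen=True)
class CumulativeWeightShape:
    """Dimensionless cumulative weight W(u) = sum_j coeffs[j-1] * u^j.

    ``coeffs[j]`` is the coefficient of u^(j+1); there is no constant term
    because W(0) = 0.  ``trig_truncation`` records the highest power of u
    retained when expanding the sine term of models D/F (0 for purely
    polynomial densities).
    """

    coeffs: tuple[float, ...]
    trig_truncation: int = 0

    def __call__(self, u):
        u = np.asarray(u, dtype=float)
        # poly coefficients in ascending powers, constant term 0
        return np.polynomial.polynomial.polyval(u, np.concatenate(([0.0], self.coeffs)))

    @property
    def total(self) -> float:
        """W(1): total weight relative to a uniform column of density rho0."""
        return float(sum(self.coeffs))


def _sine_weight_coeffs(n: float, trig_truncation: int) -> list[float]:
    """Coefficients of u - (n/pi) sin(pi u), the cumulative weight of model D.

    The Maclaurin series of sin gives
    u - (n/pi) sin(pi u) = (1 - n) u + n pi^2 u^3 / 3! - n pi^4 u^5 / 5! + ...
    truncated at power ``trig_truncation`` of u.
    """
    coeffs = [0.0] * trig_truncation
    coeffs[0] = 1.0 - n
    sign = 1.0
    for m in range(1, trig_truncation):
        power = 2 * m + 1  # odd powers only
        if power > trig_truncation:
            break
        coeffs[power - 1] = sign * n * math.pi ** (2 * m) / math.factorial(power)
        sign = -sign
    while len(coeffs) > 1 and coeffs[-1] == 0.0:
        coeffs.pop()
    return coeffs


def cumulative_weight_shape(
    model: DensityModel, trig_truncation: int = 25
) -> CumulativeWeightShape:
    """Integrate the density shape exactly into polynomial weight coefficients.

    ``trig_truncation`` (>= 5) is the highest power of u kept in the sine
    expansion for models D/F; it is ignored for the polynomial models.
    """
    n = model.n
    mid = model.model_id
    if mid in ("D", "F") and trig_truncation < 5:
        raise ValueError("trig_truncation must be >= 5 for models D and F")
    smin = float(np.min(model.density_shape(np.linspace(0.0, 1.0, 1001))))
    if smin < -1e-12:
        raise ValueError(
            f"density shape of model {mid} is negative (min {smin:.3g}) on [0, 1]"
        )
    if mid == "A":
        return CumulativeWeightShape((1.0, (n - 1.0) / 2.0))
    if mid == "B":
        return CumulativeWeightShape((n, (1.0 - n) / 2.0))
    if mid == "C":
        return CumulativeWeightShape((1.0 - n, n))
    if mid == "D":
        return CumulativeWeightShape(
            tuple(_sine_weight_coeffs(n, trig_truncation)), trig_truncation
        )
    # E/F: branch shape scaled by W_R plus the uniform trunk (weight u)
    base = cumulative_weight_shape(
        DensityModel("C" if mid == "E" else "D", n), trig_truncation
    )
    coeffs = [model.W_R * c for c in base.coeffs]
    coeffs[0] += 1.0
    return CumulativeWeightShape(tuple(coeffs), base.trig_truncation)
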