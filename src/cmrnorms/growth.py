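"""Pediatric normalization: LMS growth models, regression z-scores, centile tables.

The LMS (Box–Cox) model describes a positive measurement X at a covariate
value (age, height or BSA) by three smoothly varying parameters: L, the
Box–Cox skewness power; M, the median; and S, the coefficient of variation.
The standard deviation score of a measurement is

    z = ((X/M)^L − 1) / (L·S)          (L ≠ 0)
    z = ln(X/M) / S                    (L = 0, continuous limit)

and centile curves are recovered by inversion, X = M·(1 + L·S·z)^(1/L).
Published pediatric CMR tables equate the lower/upper reference limits with
z = ∓2 *and* with the 3rd/97th centile; by default this package follows
that convention (z = ±2 for the 3rd/97th columns, exact normal quantiles
for the inner centiles).  Pass ``extreme_z2=False`` to use the exact
quantiles Φ⁻¹(0.03)/Φ⁻¹(0.97) = ∓1.8808 instead.

Grid parameters are interpolated linearly, component by component, between
the bracketing rows; extrapolation outside the grid is refused because
growth models are not valid out of range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LMSModel", "RegressionZModel", "CentileTable",
    "lms_z", "lms_centile", "lms_interpolate", "regression_z", "centile_band",
]

_L_EPS = 1e-5  # below this the log-limit form is more accurate than the power form
#: centile-column -> z convention used by the printed pediatric tables
EXTREME_CENTILES = {3.0: -2.0, 97.0: 2.0}


def lms_z(x: float, L: float, M: float, S: float) -> float:
    """Standard deviation score of measurement ``x`` under LMS parameters."""
    if x <= 0 or M <= 0:
        raise ValueError(f"x and M must be positive (x={x}, M={M})")
    if S <= 0:
        raise ValueError(f"S must be positive, got {S}")
    if abs(L) < _L_EPS:
        return float(np.log(x / M) / S)
    return float(((x / M) ** L - 1.0) / (L * S))


def lms_centile(z_or_p: float, L: float, M: float, S: float, *,
                is_probability: bool = False,
                extreme_z2: bool = True) -> float:
    """Measurement value at a z-score or centile under LMS parameters.

    Parameters
    ----------
    z_or_p
        A z-score, or with ``is_probability=True`` a probability in (0,1)
        (e.g. 0.25 for the 25th centile) converted via the standard normal
        quantile function.
    extreme_z2
        Substitute z = ±2 for the 3rd/97th centiles, the convention the
        printed tables use for their outermost columns.
    """
    if M <= 0 or S <= 0:
        raise ValueError(f"M and S must be positive (M={M}, S={S})")
    if is_probability:
        p = z_or_p
        if not 0.0 < p < 1.0:
            raise ValueError(f"probability must be in (0, 1), got {p}")
        pct = 100.0 * p
        if extreme_z2 and any(abs(pct - c) < 1e-9 for c in EXTREME_CENTILES):
            z = EXTREME_CENTILES[min(EXTREME_CENTILES, key=lambda c: abs(pct - c))]
        else:
            z = float(stats.norm.ppf(p))
    else:
        z = float(z_or_p)
    if abs(L) < _L_EPS:
        return float(M * np.exp(S * z))
    base = 1.0 + L * S * z
    if base <= 0:
        raise ValueError(
            f"infeasible centile: 1 + L*S*z = {base:.4g} <= 0 "
            f"for (z={z:.4g}, L={L:.4g}, S={S:.4g})")
    return float(M * base ** (1.0 / L))


@dataclass(frozen=True)
class LMSModel:
    """A grid of (covariate, L, M, S) rows defining a pediatric growth model."""

    parameter_id: str
    covariate: str                      # age_years | height_cm | bsa_m2
    sex: str
    grid: np.ndarray                    # shape (k, 4): covariate, L, M, S
    citation: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2 or g.shape[1] != 4:
            raise ValueError("grid must be (k, 4): covariate, L, M, S")
        if np.any(np.diff(g[:, 0]) <= 0):
            raise ValueError("grid covariate values must be strictly increasing")
        if np.any(g[:, 2] <= 0) or np.any(g[:, 3] <= 0):
            raise ValueError("M and S must be positive everywhere on the grid")
        object.__setattr__(self, "grid", g)

    @property
    def covariate_range(self) -> tuple[float, float]:
        return float(self.grid[0, 0]), float(self.grid[-1, 0])

    def z(self, x: float, covariate_value: float) -> float:
        L, M, S = lms_interpolate(self, covariate_value)
        return lms_z(x, L, M, S)

    def centile_of(self, x: float, covariate_value: float) -> float:
        """Centile (0-100) of a measurement, exact normal quantile scale."""
        return float(100.0 * stats.norm.cdf(self.z(x, covariate_value)))

    def value_at(self, z_or_p: float, covariate_value: float, *,
                 is_probability: bool = False, extreme_z2: bool = True) -> float:
        L, M, S = lms_interpolate(self, covariate_value)
        return lms_centile(z_or_p, L, M, S, is_probability=is_probability,
                           extreme_z2=extreme_z2)


def lms_interpolate(model: LMSModel, covariate_value: float) -> tuple[float, float, float]:
    """Component-wise linear interpolation of (L, M, S) at a covariate value."""
    g = model.grid
    lo, hi = model.covariate_range
    if not lo <= covariate_value <= hi:
        raise ValueError(
            f"covariate {covariate_value} outside the model grid [{lo}, {hi}] "
            f"for {model.parameter_id} ({model.sex}); no extrapolation")
    L = float(np.interp(covariate_value, g[:, 0], g[:, 1]))
    M = float(np.interp(covariate_value, g[:, 0], g[:, 2]))
    S = float(np.interp(covariate_value, g[:, 0], g[:, 3]))
    return L, M, S


@dataclass(frozen=True)
class RegressionZModel:
    """Predicted value a + b·f(BSA) with a residual SD for z-scoring.

    ``transform`` is ``sqrt_bsa`` (predicted = a + b·√BSA) or ``bsa``
    (predicted = a + b·BSA).  ``sd_residuals`` may be None for published
    models that give only the prediction equation; such models cannot
    produce z-scores.
    """

    parameter_id: str
    intercept: float
    slope: float
    transform: str = "sqrt_bsa"
    sd_residuals: float | None = None
    site: str = ""
    citation: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if self.transform not in ("sqrt_bsa", "bsa"):
            raise ValueError(f"unknown transform: {self.transform!r}")
        if self.sd_residuals is not None and self.sd_residuals <= 0:
            raise ValueError("sd_residuals must be positive when given")

    def predict(self, bsa: float) -> float:
        if bsa <= 0:
            raise ValueError(f"BSA must be positive, got {bsa}")
        f = np.sqrt(bsa) if self.transform == "sqrt_bsa" else bsa
        return float(self.intercept + self.slope * f)


def regression_z(measured: float, bsa: float,
                 model: RegressionZModel) -> tuple[float, float]:
    """(z, predicted) for a measurement against a BSA regression model.

    z = (measured − predicted) / SD of residuals.
    """
    predicted = model.predict(bsa)
    if model.sd_residuals is None:
        raise ValueError(
            f"model {model.parameter_id}/{model.site} has no residual SD; "
            "only predicted values are available")
    return (measured - predicted) / model.sd_residuals, predicted


@dataclass(frozen=True)
class CentileTable:
    """Printed centile-by-covariate lookup table.

    ``centiles`` are the column probabilities in percent (e.g. 5, 10, 25,
    50, 75, 90, 95); ``rows`` is a (k, 1+len(centiles)) array whose first
    column is the covariate.
    """

    parameter_id: str
    covariate: str
    sex: str
    centiles: tuple[float, ...]
    rows: np.ndarray
    citation: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.rows, dtype=float)
        if r.shape[1] != 1 + len(self.centiles):
            raise ValueError("rows must have one column per centile plus covariate")
        if np.any(np.diff(r[:, 0]) <= 0):
            raise ValueError("covariate column must be strictly increasing")
        if np.any(np.diff(r[:, 1:], axis=1) < 0):
            raise ValueError("centile values must be monotone within each row")
        object.__setattr__(self, "rows", r)

    @property
    def covariate_range(self) -> tuple[float, float]:
        return float(self.rows[0, 0]), float(self.rows[-1, 0])

    def row_at(self, covariate_value: float) -> np.ndarray:
        lo, hi = self.covariate_range
        if not lo <= covariate_value <= hi:
            raise ValueError(
                f"covariate {covariate_value} outside table range [{lo}, {hi}]")
        return np.array([np.interp(covariate_value, self.rows[:, 0], self.rows[:, 1 + j])
                         for j in range(len(self.centiles))])


def centile_band(table: CentileTable, covariate_value: float,
                 x: float) -> tuple[str, float | None]:
    """Bracket a measurement between printed centile columns.

    Returns ``(band, approximate_centile)``.  The band is e.g. ``"50th"``
    when the value sits on an interpolated column, ``"25th-50th"`` between
    columns, ``"<5th"`` / ``">95th"`` outside the printed columns (the
    approximate centile is then None).  The approximate centile
    interpolates the probability linearly in the measurement between the
    bracketing columns.
    """
    vals = table.row_at(covariate_value)
    cents = table.centiles

    def name(c: float) -> str:
        c = int(c) if float(c).is_integer() else c
        suffix = {1: "st", 2: "nd", 3: "rd"}.get(c % 10 if c % 100 not in (11, 12, 13) else 0, "th")
        return f"{c}{suffix}"

    if x < vals[0]:
        return f"<{name(cents[0])}", None
    if x > vals[-1]:
        return f">{name(cents[-1])}", None
    for j in range(len(cents)):
        if np.isclose(x, vals[j]):
            return name(cents[j]), float(cents[j])
    j = int(np.searchsorted(vals, x)) - 1
    frac = (x - vals[j]) / (vals[j + 1] - vals[j])
    approx = cents[j] + frac * (cents[j + 1] - cents[j])
    return f"{name(cents[j])}-{name(cents[j + 1])}", float(approx)
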