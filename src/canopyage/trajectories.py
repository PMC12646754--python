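"""Recovery-trajectory models: metric ~ f1(stand age) + f2(rainfall) + f3(plot size).

Fits one additive smooth model per structural metric over the chronosequence
table, then extracts the quantities the analysis reports: the fitted curve at
reference covariates, its per-decade rate of change, peak/trough locations,
and the wet-minus-dry rainfall contrast (302 vs 260 mm/yr).  Tree density is
fitted on the log scale and back-transformed with the naive exponential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gam import AdditiveModelFit, fit_additive_model

__all__ = [
    "TrajectoryCurve", "PeakSummary", "fit_trajectory", "predict_curve",
    "rate_of_change", "find_extremum", "rainfall_contrast",
    "METRIC_COLUMNS", "LOG_RESPONSES", "PREDICTORS",
]

PREDICTORS = ["stand_age_yr", "rainfall_mm_yr", "plot_area_ha"]
METRIC_COLUMNS = ["h_max_m", "cover_5m_pct", "h_cv", "rumple_norm",
                  "basal_area_m2ha", "tree_density_ha"]
#: Responses fitted on the (natural) log scale.
LOG_RESPONSES = {"tree_density_ha"}


@dataclass(frozen=True)
class TrajectoryCurve:
    """A fitted response curve over an age grid at fixed reference covariates."""

    age: np.ndarray
    value: np.ndarray
    reference_rainfall: float
    reference_area: float
    response: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.age) <= 0):
            raise ValueError("age grid must be strictly increasing")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("curve values must be finite")


@dataclass(frozen=True)
class PeakSummary:
    peak_age: float
    peak_value: float
    kind: str                  # "maximum" | "minimum"
    mean_rate_before: float    # response units per decade, grid start → peak
    mean_rate_after: float     # peak → grid end
    at_boundary: bool = False


def fit_trajectory(table: pd.DataFrame, response: str, *, k: int = 10,
                   log_response: bool | None = None) -> AdditiveModelFit:
    """Fit the additive model for one metric on a plot table."""
    if log_response is None:
        log_response = response in LOG_RESPONSES
    data = {c: table[c].to_numpy(float) for c in PREDICTORS + [response]}
    return fit_additive_model(data, response, PREDICTORS, k=k,
                              log_response=log_response)


def _age_term(fit: AdditiveModelFit) -> "SmoothTerm":
    for t in fit.terms:
        if t.name == "stand_age_yr":
            return t
    raise ValueError("fit has no stand-age smooth")


def predict_curve(fit: AdditiveModelFit, age_grid: np.ndarray,
                  reference_rainfall: float, reference_area: float,
                  *, allow_extrapolation: bool = False) -> TrajectoryCurve:
    """Evaluate the fitted trajectory on an age grid at fixed covariates.

    Ages outside the fitted range raise unless ``allow_extrapolation`` (in
    which case the boundary value is carried, i.e. covariates are clipped).
    Log-fitted responses are back-transformed.
    """
    age_grid = np.asarray(age_grid, dtype=float)
    t = _age_term(fit)
    if not allow_extrapolation and (age_grid.min() < t.lo - 1e-9 or
                                    age_grid.max() > t.hi + 1e-9):
        raise ValueError(
            f"age grid [{age_grid.min()}, {age_grid.max()}] outside fitted "
            f"range [{t.lo:.1f}, {t.hi:.1f}]"
        )
    data = {
        "stand_age_yr": age_grid,
        "rainfall_mm_yr": np.full_like(age_grid, reference_rainfall),
        "plot_area_ha": np.full_like(age_grid, reference_area),
    }
    return TrajectoryCurve(age_grid, fit.predict_response(data),
                           reference_rainfall, reference_area, fit.response)


def rate_of_change(curve: TrajectoryCurve) -> np.ndarray:
    """Per-decade derivative of the fitted curve (central differences).

    Requires a grid no coarser than 5 yr so the finite difference tracks the
    smooth's true derivative.
    """
    steps = np.diff(curve.age)
    if steps.max() > 5.0:
        raise ValueError("age grid too coarse for derivative estimation (step > 5 yr)")
    return np.gradient(curve.value, curve.age) * 10.0


def find_extremum(curve: TrajectoryCurve, kind: str = "maximum") -> PeakSummary:
    """Arg-extremum on the grid with quadratic refinement between neighbours."""
    if kind not in {"maximum", "minimum"}:
        raise ValueError("kind must be 'maximum' or 'minimum'")
    v = curve.value if kind == "maximum" else -curve.value
    if np.allclose(v, v[0]):
        raise ValueError("curve is constant; extremum undefined")
    i = int(np.argmax(v))
    boundary = i in (0, len(v) - 1)
    if boundary:
        age_star, val_star = float(curve.age[i]), float(curve.value[i])
    else:
        # quadratic through the three points around the grid argmax
        xs, ys = curve.age[i - 1:i + 2], v[i - 1:i + 2]
        a, b, c = np.polyfit(xs - xs[1], ys, 2)  # shift for conditioning
        age_star = float(xs[1] - b / (2 * a)) if a < 0 else float(xs[1])
        age_star = float(np.clip(age_star, xs[0], xs[2]))
        u = age_star - xs[1]
        yq = a * u * u + b * u + c
        val_star = float(yq if kind == "maximum" else -yq)
    decades_before = (age_star - curve.age[0]) / 10.0
    decades_after = (curve.age[-1] - age_star) / 10.0
    rate_before = ((val_star - float(curve.value[0])) / decades_before
                   if decades_before > 0 else 0.0)
    rate_after = ((float(curve.value[-1]) - val_star) / decades_after
                  if decades_after > 0 else 0.0)
    return PeakSummary(age_star, val_star, kind, rate_before, rate_after, boundary)


def rainfall_contrast(fit: AdditiveModelFit, age_grid: np.ndarray,
                      r_lo: float = 260.0, r_hi: float = 302.0,
                      reference_area: float = 4.4, *,
                      allow_extrapolation: bool = False) -> tuple[np.ndarray, float]:
    """Wet-minus-dry difference of the fitted curve, per age and at the peak.

    Returns ``(difference series over age_grid, difference at the high-rain
    curve's extremum age)``.  Both rainfall values must lie inside the fitted
    rainfall range.
    """
    rt = next(t for t in fit.terms if t.name == "rainfall_mm_yr")
    for r in (r_lo, r_hi):
        if not rt.lo - 1e-9 <= r <= rt.hi + 1e-9:
            raise ValueError(f"rainfall {r} outside fitted range [{rt.lo:.1f}, {rt.hi:.1f}]")
    hi = predict_curve(fit, age_grid, r_hi, reference_area,
                       allow_extrapolation=allow_extrapolation)
    lo = predict_curve(fit, age_grid, r_lo, reference_area,
                       allow_extrapolation=allow_extrapolation)
    diff = hi.value - lo.value
    peak = find_extremum(hi, "maximum")
    i = int(np.argmin(np.abs(np.asarray(age_grid) - peak.peak_age)))
    return diff, float(diff[i])
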