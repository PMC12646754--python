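"""Parametric "truth" trajectories for the post-fire chronosequence generator.

Each canopy/stand attribute follows a smooth curve of stand age whose key
features (peak values and timing, plateau heights, endpoint values, rainfall
contrasts) are pinned to the study system's reported behaviour by root-finding
at construction time.  The functional forms themselves are package choices:

* ``cover`` and ``rumple`` — gamma-type humps ``peak·(t/t_p)^a·exp(a(1−t/t_p))``
  with the shape exponent solved so the curve passes through a stated
  late-chronosequence value;
* ``h_max`` — monomolecular (saturating) growth ``H∞·(1−exp(−t/τ))``;
* ``density`` — exponential self-thinning decay to a sparse old-growth floor;
* ``basal_area`` — lognormal hump with spread solved from an old-stand anchor;
* ``h_cv`` — a declining young-stand component (standing dead trees falling and
  the regenerating cohort evening out) plus a slowly rising old-growth
  component, with the young-component timescale solved so the minimum sits at
  a configured age.

Rainfall enters linearly (additively for heights/cover/rumple, multiplicatively
for ``h_cv``), scaled so the contrast between the wet and dry ends of the
gradient (302 vs 260 mm/yr) equals the configured effect.  Plot size enters as
``coefficient · ln(area / 4.4 ha)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = ["TruthParams", "TrajectoryTruth", "build_truth"]

# Rainfall interval over which per-metric contrasts are defined (mm/yr): the
# 5th and 95th percentiles of the study's rainfall gradient.
RAIN_LO = 260.0
RAIN_HI = 302.0
#: Rainfall (mm/yr) and plot area (ha) at which the base curves apply.
REFERENCE_RAINFALL = 290.0
REFERENCE_AREA = 4.4


@dataclass(frozen=True)
class TruthParams:
    """Constants defining the default truth curves.

    Anchor fields (``*_anchor``) are enforced exactly by solving for a free
    shape parameter; the remaining fields are direct curve constants.
    """

    age_min: float = 1.0
    age_max: float = 450.0

    # Cover_5m (%): gamma hump, peak `cover_peak` at `cover_peak_age`,
    # passing through `cover_end_anchor` at age_max.
    cover_peak: float = 48.0
    cover_peak_age: float = 120.0
    cover_end_anchor: float = 20.0

    # H_max (m): monomolecular rise toward `hmax_asymptote`.
    hmax_asymptote: float = 15.5
    hmax_timescale: float = 65.0

    # Tree density (trees/ha): exponential decay.
    density_floor: float = 20.0
    density_initial: float = 6000.0
    density_timescale: float = 45.0

    # Basal area (m²/ha): lognormal hump peaking at `basal_peak` at
    # `basal_peak_age`; sigma solved so B(basal_anchor_age) = basal_anchor.
    basal_peak: float = 15.0
    basal_peak_age: float = 160.0
    basal_anchor_age: float = 420.0
    basal_anchor: float = 10.0

    # H_cv (dimensionless): c0 + A_y·exp(−t/τ) + A_o·(t/age_max)^γ with τ
    # solved so the minimum sits at `hcv_min_age`.
    hcv_c0: float = 0.25
    hcv_young_amp: float = 0.45
    hcv_old_amp: float = 0.35
    hcv_gamma: float = 1.5
    hcv_min_age: float = 75.0

    # Rumple_norm (1/m): gamma hump, peak at `rumple_peak_age`, declining to
    # `rumple_end_anchor` at age_max.
    rumple_peak: float = 0.35
    rumple_peak_age: float = 60.0
    rumple_end_anchor: float = 0.15

    # Rainfall contrasts over RAIN_LO → RAIN_HI: additive unless noted.
    rain_effect_hmax: float = 1.2      # m
    rain_effect_cover: float = 7.0     # percentage points
    rain_effect_hcv_rel: float = -0.10  # relative (multiplicative)
    rain_effect_rumple: float = 0.02   # 1/m ("small positive")

    # Plot-size coefficients on ln(area / REFERENCE_AREA); only the metrics
    # the study found scale-dependent carry one.
    area_coef_hmax: float = 0.4
    area_coef_hcv: float = 0.02
    area_coef_rumple: float = 0.01


def _gamma_hump_exponent(peak: float, peak_age: float, end_age: float,
                         end_value: float) -> float:
    """Shape exponent a of peak·(t/t_p)^a·exp(a(1−t/t_p)) through an end anchor.

    Raises ``ValueError`` when the anchor is unreachable (end value not below
    the peak, or anchor age at the peak).
    """
    if not 0 < end_value < peak:
        raise ValueError(
            f"end anchor {end_value} must lie strictly between 0 and the peak {peak}"
        )
    r = end_age / peak_age
    if r <= 1.0:
        raise ValueError("end-anchor age must lie beyond the peak age")
    # peak·exp(a·(ln r + 1 − r)) = end_value; ln r + 1 − r < 0 for r > 1.
    def f(a: float) -> float:
        return math.log(end_value / peak) - a * (math.log(r) + 1.0 - r)
    return brentq(f, 1e-9, 50.0)


def _hcv_timescale(p: TruthParams) -> float:
    """Young-component timescale τ placing the H_cv minimum at p.hcv_min_age."""
    t0 = p.hcv_min_age
    # dH/dt = −(A_y/τ)e^{−t/τ} + A_o·γ/age_max·(t/age_max)^{γ−1} = 0 at t0.
    rise = (p.hcv_old_amp * p.hcv_gamma / p.age_max
            * (t0 / p.age_max) ** (p.hcv_gamma - 1.0))

    def f(tau: float) -> float:
        return p.hcv_young_amp / tau * math.exp(-t0 / tau) - rise

    try:
        return brentq(f, 1.0, t0)
    except ValueError as exc:  # pragma: no cover - degenerate parameter sets
        raise ValueError(
            f"cannot place the H_cv minimum at {t0} yr with the given amplitudes"
        ) from exc


@dataclass(frozen=True)
class TrajectoryTruth:
    """Calibrated truth curves; callables of (age, rainfall, area).

    Every metric accessor accepts scalar or array ages and optional rainfall
    (mm/yr) / plot area (ha); omitted covariates default to the reference
    conditions, under which the base age curves apply exactly.
    """

    params: TruthParams = field(default_factory=TruthParams)
    cover_exponent: float = 0.0
    rumple_exponent: float = 0.0
    basal_sigma: float = 0.0
    hcv_timescale: float = 0.0

    # -- base age curves at reference rainfall/area --------------------------

    def _cover_base(self, age):
        p = self.params
        t = np.asarray(age, dtype=float) / p.cover_peak_age
        a = self.cover_exponent
        return p.cover_peak * t ** a * np.exp(a * (1.0 - t))

    def _hmax_base(self, age):
        p = self.params
        return p.hmax_asymptote * (1.0 - np.exp(-np.asarray(age, float) / p.hmax_timescale))

    def _density_base(self, age):
        p = self.params
        return p.density_floor + (p.density_initial - p.density_floor) * np.exp(
            -np.asarray(age, float) / p.density_timescale
        )

    def _basal_base(self, age):
        p = self.params
        x = np.log(np.asarray(age, float) / p.basal_peak_age)
        return p.basal_peak * np.exp(-(x ** 2) / (2.0 * self.basal_sigma ** 2))

    def _hcv_base(self, age):
        p = self.params
        t = np.asarray(age, dtype=float)
        return (p.hcv_c0
                + p.hcv_young_amp * np.exp(-t / self.hcv_timescale)
                + p.hcv_old_amp * (t / p.age_max) ** p.hcv_gamma)

    def _rumple_base(self, age):
        p = self.params
        t = np.asarray(age, dtype=float) / p.rumple_peak_age
        a = self.rumple_exponent
        return p.rumple_peak * t ** a * np.exp(a * (1.0 - t))

    # -- covariate effects ---------------------------------------------------

    @staticmethod
    def _rain_add(rainfall, contrast: float):
        """Additive linear rainfall term, centred at the reference rainfall."""
        slope = contrast / (RAIN_HI - RAIN_LO)
        return slope * (np.asarray(rainfall, float) - REFERENCE_RAINFALL)

    def _rain_mult_hcv(self, rainfall):
        """Multiplier m(r), linear in r, with m(RAIN_HI)/m(RAIN_LO) = 1 + rel."""
        rel = self.params.rain_effect_hcv_rel
        # (1 + s·(hi−ref)) / (1 + s·(lo−ref)) = 1 + rel, solved for s:
        hi, lo, ref = RAIN_HI - REFERENCE_RAINFALL, RAIN_LO - REFERENCE_RAINFALL, 0.0
        s = rel / (hi - (1.0 + rel) * lo)
        return 1.0 + s * (np.asarray(rainfall, float) - REFERENCE_RAINFALL)

    @staticmethod
    def _area_term(area, coef: float):
        return coef * np.log(np.asarray(area, float) / REFERENCE_AREA)

    # -- public metric curves ------------------------------------------------

    def cover(self, age, rainfall=REFERENCE_RAINFALL, area=REFERENCE_AREA):
        """Cover_5m (%) clipped to [0, 100]."""
        v = self._cover_base(age) + self._rain_add(rainfall, self.params.rain_effect_cover)
        return np.clip(v, 0.0, 100.0)

    def h_max(self, age, rainfall=REFERENCE_RAINFALL, area=REFERENCE_AREA):
        """H_max (m), non-negative."""
        v = (self._hmax_base(age)
             + self._rain_add(rainfall, self.params.rain_effect_hmax)
             + self._area_term(area, self.params.area_coef_hmax))
        return np.maximum(v, 0.0)

    def h_cv(self, age, rainfall=REFERENCE_RAINFALL, area=REFERENCE_AREA):
        """H_cv (dimensionless), non-negative."""
        v = (self._hcv_base(age) * self._rain_mult_hcv(rainfall)
             + self._area_term(area, self.params.area_coef_hcv))
        return np.maximum(v, 0.0)

    def rumple(self, age, rainfall=REFERENCE_RAINFALL, area=REFERENCE_AREA):
        """Rumple_norm (1/m), non-negative."""
        v = (self._rumple_base(age)
             + self._rain_add(rainfall, self.params.rain_effect_rumple)
             + self._area_term(area, self.params.area_coef_rumple))
        return np.maximum(v, 0.0)

    def basal_area(self, age, rainfall=REFERENCE_RAINFALL, area=REFERENCE_AREA):
        """Basal area (m²/ha); no rainfall/plot-size effect by default."""
        return self._basal_base(age)

    def density(self, age, rainfall=REFERENCE_RAINFALL, area=REFERENCE_AREA):
        """Living-tree density (trees/ha); no rainfall/plot-size effect."""
        return self._density_base(age)

    def metric(self, name: str):
        """Curve accessor by metric column name."""
        table = {
            "cover_5m_pct": self.cover,
            "h_max_m": self.h_max,
            "h_cv": self.h_cv,
            "rumple_norm": self.rumple,
            "basal_area_m2ha": self.basal_area,
            "tree_density_ha": self.density,
        }
        try:
            return table[name]
        except KeyError:
            raise KeyError(f"unknown metric {name!r}; one of {sorted(table)}") from None

    def without_rainfall_effects(self) -> "TrajectoryTruth":
        """Copy with all rainfall effects switched off."""
        p = replace(self.params, rain_effect_hmax=0.0, rain_effect_cover=0.0,
                    rain_effect_hcv_rel=0.0, rain_effect_rumple=0.0)
        return build_truth(p)


def build_truth(params: TruthParams | None = None) -> TrajectoryTruth:
    """Solve the anchor constraints and return the calibrated truth curves.

    Raises ``ValueError`` for unsolvable anchors (e.g. an end value at or
    above the peak it is supposed to decline from).
    """
    p = params or TruthParams()
    if p.age_min <= 0 or p.age_max <= p.age_min:
        raise ValueError("age range must satisfy 0 < age_min < age_max")

    cover_a = _gamma_hump_exponent(p.cover_peak, p.cover_peak_age,
                                   p.age_max, p.cover_end_anchor)
    rumple_a = _gamma_hump_exponent(p.rumple_peak, p.rumple_peak_age,
                                    p.age_max, p.rumple_end_anchor)

    ratio = p.basal_anchor / p.basal_peak
    if not 0 < ratio < 1:
        raise ValueError("basal-area anchor must lie strictly below the peak")
    basal_sigma = abs(math.log(p.basal_anchor_age / p.basal_peak_age)) / math.sqrt(
        -2.0 * math.log(ratio)
    )

    return TrajectoryTruth(
        params=p,
        cover_exponent=cover_a,
        rumple_exponent=rumple_a,
        basal_sigma=basal_sigma,
        hcv_timescale=_hcv_timescale(p),
    )
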