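"""Synthetic chronosequence data at two tiers.

Tier A draws plot-level metric tables from the calibrated truth trajectories
plus per-metric Gaussian noise — the cheap route for exercising the trajectory
and age models at the study's scale (250 plots, ages 1–450 yr, rainfall
250–330 mm/yr, plot areas lognormal with mean 4.4 and sd 2.0 ha).

Tier B builds explicit tree-level stand scenes and rasterizes them into 1 m
canopy height models, so the raster metrics can be exercised end-to-end.
Live canopy trees are placed by a homogeneous Poisson process whose intensity
is calibrated through the Boolean model so the expected covered fraction
matches the truth cover at that age; standing dead trees (snags) are thin
tall spikes whose density decays exponentially with time since fire — the
mechanism behind high height-heterogeneity in recently burned stands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chm_io import CHMRaster
from .truth import REFERENCE_AREA, TrajectoryTruth, build_truth

__all__ = [
    "GeneratorConfig", "simulate_plot_table",
    "boolean_density_for_cover", "Tree", "StandScene",
    "simulate_stand_scene", "rasterize_scene",
]

#: Side of the square region (km) over which plot coordinates are scattered.
REGION_KM = 600.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Tier A sampling design and noise levels.

    Noise standard deviations are in each metric's own units; tree-density
    noise is applied on the log10 scale.  ``age_rainfall_correlation`` (in
    [−1, 0]) induces the study's confounding between stand age and rainfall
    through a Gaussian copula; the default 0 keeps them independent.
    """

    n_plots: int = 250
    age_range: tuple[float, float] = (1.0, 450.0)
    rainfall_range: tuple[float, float] = (250.0, 330.0)
    age_rainfall_correlation: float = 0.0
    plot_area_mean: float = 4.4
    plot_area_sd: float = 2.0
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "h_max_m": 1.2,
        "cover_5m_pct": 7.0,
        "h_cv": 0.07,
        "rumple_norm": 0.05,
        "basal_area_m2ha": 2.5,
        "log10_tree_density": 0.15,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 10:
            raise ValueError("n_plots must be at least 10")
        for name, (lo, hi) in [("age_range", self.age_range),
                               ("rainfall_range", self.rainfall_range)]:
            if not lo < hi:
                raise ValueError(f"{name} must be non-degenerate")
        if not -1.0 <= self.age_rainfall_correlation <= 0.0:
            raise ValueError("age_rainfall_correlation must be in [-1, 0]")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise sds must be non-negative")
        if self.plot_area_mean <= 0 or self.plot_area_sd < 0:
            raise ValueError("plot area moments must be positive")

    def zero_noise(self) -> "GeneratorConfig":
        return replace(self, noise_sd={k: 0.0 for k in self.noise_sd})


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def simulate_plot_table(truth: TrajectoryTruth | None = None,
                        config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Draw a Tier A plot table; fully reproducible from ``config.seed``."""
    truth = truth or build_truth()
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = cfg.n_plots

    rho = cfg.age_rainfall_correlation
    if rho == 0.0:
        u_age, u_rain = rng.random(n), rng.random(n)
    else:
        # Gaussian copula: latent correlation ~ realized rank correlation.
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        from scipy.stats import norm
        u_age, u_rain = norm.cdf(z[:, 0]), norm.cdf(z[:, 1])
    ages = cfg.age_range[0] + u_age * (cfg.age_range[1] - cfg.age_range[0])
    rain = cfg.rainfall_range[0] + u_rain * (cfg.rainfall_range[1] - cfg.rainfall_range[0])

    mu, sigma = _lognormal_params(cfg.plot_area_mean, cfg.plot_area_sd)
    areas = np.exp(rng.normal(mu, sigma, size=n)) if sigma > 0 else np.full(n, cfg.plot_area_mean)
    xy = rng.uniform(0.0, REGION_KM, size=(2, n))

    sd = cfg.noise_sd
    def noisy(values: np.ndarray, key: str) -> np.ndarray:
        return values + rng.normal(0.0, sd.get(key, 0.0), size=n)

    hmax = np.maximum(noisy(truth.h_max(ages, rain, areas), "h_max_m"), 0.0)
    cover = np.clip(noisy(truth.cover(ages, rain, areas), "cover_5m_pct"), 0.0, 100.0)
    hcv = np.maximum(noisy(truth.h_cv(ages, rain, areas), "h_cv"), 0.0)
    rumple = np.maximum(noisy(truth.rumple(ages, rain, areas), "rumple_norm"), 0.0)
    basal = np.maximum(noisy(truth.basal_area(ages, rain, areas), "basal_area_m2ha"), 0.0)
    density = 10.0 ** noisy(np.log10(truth.density(ages, rain, areas)),
                            "log10_tree_density")

    return pd.DataFrame({
        "plot_id": [f"P{i:04d}" for i in range(n)],
        "stand_age_yr": ages,
        "rainfall_mm_yr": rain,
        "plot_area_ha": areas,
        "x_km": xy[0],
        "y_km": xy[1],
        "h_max_m": hmax,
        "cover_5m_pct": cover,
        "h_cv": hcv,
        "rumple_norm": rumple,
        "basal_area_m2ha": basal,
        "tree_density_ha": density,
    })


# ---------------------------------------------------------------------------
# Tier B: explicit stands

def boolean_density_for_cover(target_cover: float, mean_crown_area: float) -> float:
    """Poisson intensity (trees/m²) whose Boolean-model coverage hits a target.

    For a Boolean model of random disks with mean area ``A`` and intensity λ,
    the covered fraction is 1 − exp(−λA); inverting gives
    λ = −ln(1 − c) / A.  ``target_cover`` is a fraction in [0, 1).
    """
    if not 0.0 <= target_cover < 1.0:
        raise ValueError("target cover must be in [0, 1); full cover is unreachable")
    if mean_crown_area <= 0:
        raise ValueError("mean crown area must be positive")
    return -math.log1p(-target_cover) / mean_crown_area


@dataclass(frozen=True)
class Tree:
    x: float
    y: float
    height: float
    crown_radius: float
    crown_form: str = "spherical-cap"  # or "cone"
    is_snag: bool = False


@dataclass(frozen=True)
class StandScene:
    trees: tuple[Tree, ...]
    extent: tuple[float, float]  # metres
    age: float

    def __post_init__(self) -> None:
        w, h = self.extent
        for t in self.trees:
            if not (0 <= t.x <= w and 0 <= t.y <= h):
                raise ValueError("tree outside scene extent")
            if t.height <= 0 or t.crown_radius < 0:
                raise ValueError("tree heights must be positive, crown radii non-negative")
            if t.is_snag and t.crown_radius > 0.5:
                raise ValueError("snag crown radius must be <= 0.5 m")


#: Minimum live canopy-tree height (m); matches the cover threshold so that a
#: calibrated stand's crowns sit (mostly) above it.
CANOPY_FLOOR = 5.0


#: Stand age (yr) at which the regenerating cohort first forms canopy above
#: the 5 m cover threshold; younger scenes render only low regrowth.
CANOPY_ESTABLISHMENT_AGE = 5.0


def _height_quantile_grid(mu: float, sd: float, n: int = 41) -> np.ndarray:
    """Mid-quantile heights of the >CANOPY_FLOOR truncated normal."""
    from scipy.stats import norm
    lo = norm.cdf((CANOPY_FLOOR - mu) / sd)
    u = lo + (np.arange(n) + 0.5) / n * (1.0 - lo)
    return np.clip(mu + sd * norm.ppf(u), CANOPY_FLOOR + 1e-6, None)


def _area_above(x: float, heights: np.ndarray, crown_ratio: float,
                crown_form: str) -> np.ndarray:
    """Per-tree crown area (m²) whose surface exceeds height x."""
    h = np.asarray(heights, float)
    r = crown_ratio * h
    if crown_form == "cone":
        frac = np.clip(1.0 - x / np.maximum(h, 1e-12), 0.0, 1.0)
        return math.pi * (r * frac) ** 2
    # spherical cap: surface at distance d is h − r + sqrt(r² − d²)
    t = np.clip(x - (h - r), 0.0, r)  # 0 → full disk, r → empty
    return math.pi * np.maximum(r ** 2 - t ** 2, 0.0)


def _calibrate_height_center(target_top: float, target_cover: float,
                             height_sd: float, crown_ratio: float,
                             crown_form: str, p: float = 0.98) -> float:
    """Center of the tree-height distribution such that the Boolean model's
    pixel-height quantile ``p`` equals ``target_top``.

    For a Boolean stand the fraction of ground not covered above height x is
    exp(−λ·E[a_above(x)]); the implied CHM p98 is therefore solvable from the
    same expectation used for the cover calibration.  When the target top
    height is unreachable (it lies at or below the canopy floor, which any
    >5 m canopy exceeds), the lowest admissible center is used.
    """
    from scipy.optimize import brentq

    if not 0.0 < target_cover < 0.995:
        return max(target_top, CANOPY_FLOOR + 0.5)
    # P(pixel ≤ x) = exp(−λ·E a(x)) reaches p when λ·E a(x) = −ln p
    tail = -math.log(min(p, 1.0 - 1e-9))

    def implied_top(mu: float) -> float:
        hq = _height_quantile_grid(mu, height_sd)
        lam = -math.log1p(-min(target_cover, 0.99)) / float(
            np.mean(_area_above(CANOPY_FLOOR, hq, crown_ratio, crown_form)))
        # exceedance cover 1−exp(−λ·E a(x)) falls below 1−p at the implied top
        def excess(x: float) -> float:
            return lam * float(np.mean(_area_above(x, hq, crown_ratio, crown_form))) - tail
        hi = float(hq[-1])
        if excess(CANOPY_FLOOR) <= 0:  # cover too sparse: p98 below canopy
            return CANOPY_FLOOR
        return brentq(excess, CANOPY_FLOOR, hi)

    lo_mu = CANOPY_FLOOR + 0.05
    if implied_top(lo_mu) >= target_top:
        return lo_mu
    hi_mu = max(target_top + 3.0 * height_sd, lo_mu + 1.0)
    if implied_top(hi_mu) <= target_top:
        return hi_mu
    return brentq(lambda m: implied_top(m) - target_top, lo_mu, hi_mu, xtol=1e-3)


def simulate_stand_scene(age: float, rainfall: float, area_ha: float,
                         truth: TrajectoryTruth | None = None,
                         seed: int = 0, *,
                         height_sd: float = 1.5,
                         crown_ratio: float = 0.18,
                         crown_form: str = "spherical-cap",
                         snag_initial_density: float = 200.0,
                         snag_half_life: float = 20.0) -> StandScene:
    """Place live trees and snags for one plot.

    For ages past ``CANOPY_ESTABLISHMENT_AGE``, live canopy trees follow a
    homogeneous Poisson process at the Boolean-calibrated intensity for the
    truth cover at this age, with heights Normal around the truth top height
    truncated above ``CANOPY_FLOOR`` and crown radius ``crown_ratio``·height.
    Younger stands carry only sub-5 m regrowth (density from the truth
    tree-density curve).  Snags: density
    ``snag_initial_density · 2^(−age/snag_half_life)`` per ha, heights drawn
    around the pre-fire (old-stand) top height, near-zero crowns.  Set
    ``snag_initial_density=0`` to disable snags.
    """
    if not 1.0 <= age <= 450.0:
        raise ValueError("age must be within [1, 450]")
    from scipy.stats import norm, truncnorm

    truth = truth or build_truth()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(age * 1000)]))
    side = math.sqrt(area_ha * 1e4)
    mean_h = float(truth.h_max(age, rainfall, area_ha))
    trees: list[Tree] = []

    if age >= CANOPY_ESTABLISHMENT_AGE:
        target_cover = float(truth.cover(age, rainfall, area_ha)) / 100.0
        mu = _calibrate_height_center(mean_h, target_cover, height_sd,
                                      crown_ratio, crown_form)
        a = (CANOPY_FLOOR - mu) / height_sd
        hq = _height_quantile_grid(mu, height_sd)
        lam = boolean_density_for_cover(
            min(target_cover, 0.99),
            float(np.mean(_area_above(CANOPY_FLOOR, hq, crown_ratio, crown_form))),
        )
        n_live = rng.poisson(lam * side * side)
        if n_live:
            xy = rng.uniform(0.0, side, size=(n_live, 2))
            # inverse-CDF draw from the >5 m truncated normal
            lo = norm.cdf(a)
            h = mu + height_sd * norm.ppf(lo + rng.random(n_live) * (1.0 - lo))
            h = np.clip(h, CANOPY_FLOOR + 1e-6, None)
            for (x, y), hi in zip(xy, h):
                trees.append(Tree(x, y, float(hi), crown_ratio * float(hi), crown_form))
    else:
        # low regrowth: density from the self-thinning curve, heights < 5 m
        n_low = rng.poisson(float(truth.density(age)) / 1e4 * side * side)
        if n_low:
            xy = rng.uniform(0.0, side, size=(n_low, 2))
            h = np.clip(rng.normal(max(mean_h, 0.3), 0.3 * max(mean_h, 0.3), size=n_low),
                        0.05, CANOPY_FLOOR - 0.05)
            for (x, y), hi in zip(xy, h):
                trees.append(Tree(x, y, float(hi), 0.3 * float(hi), "cone"))

    if snag_initial_density > 0:
        snag_density = snag_initial_density * 2.0 ** (-age / snag_half_life)
        n_snag = rng.poisson(snag_density / 1e4 * side * side)
        if n_snag:
            prefire_h = float(truth.h_max(truth.params.age_max, rainfall, area_ha))
            xy = rng.uniform(0.0, side, size=(n_snag, 2))
            h = np.maximum(rng.normal(prefire_h, height_sd, size=n_snag), 1.0)
            for (x, y), hi in zip(xy, h):
                trees.append(Tree(x, y, float(hi), 0.25, "cone", is_snag=True))

    return StandScene(tuple(trees), (side, side), age)


def rasterize_scene(scene: StandScene, resolution: float = 1.0) -> CHMRaster:
    """Max-composite the crown surfaces onto a regular grid.

    Each pixel takes the maximum height of any crown surface covering its
    center (cones drop linearly from apex to zero at the crown edge;
    spherical caps drop by one crown radius at the edge); pixels under no
    crown are ground (0 m).  Deterministic given the scene.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    w, hgt = scene.extent
    ncols, nrows = max(int(round(w / resolution)), 1), max(int(round(hgt / resolution)), 1)
    grid = np.zeros((nrows, ncols))
    for t in scene.trees:
        r = max(t.crown_radius, resolution / 2.0)  # a spike still owns its pixel
        c0 = max(int((t.x - r) / resolution), 0)
        c1 = min(int((t.x + r) / resolution) + 1, ncols)
        r0 = max(int((hgt - t.y - r) / resolution), 0)
        r1 = min(int((hgt - t.y + r) / resolution) + 1, nrows)
        if c0 >= c1 or r0 >= r1:
            continue
        xs = (np.arange(c0, c1) + 0.5) * resolution
        ys = hgt - (np.arange(r0, r1) + 0.5) * resolution
        d = np.hypot(xs[None, :] - t.x, ys[:, None] - t.y)
        if t.crown_form == "cone":
            z = np.where(d <= r, t.height * (1.0 - d / r), 0.0)
        else:  # spherical cap: depth at the edge equals the crown radius
            with np.errstate(invalid="ignore"):
                z = np.where(d <= r, t.height - r + np.sqrt(np.maximum(r * r - d * d, 0.0)), 0.0)
        if t.crown_radius < resolution / 2.0:
            # sub-pixel crown (snag spike): only the center pixel, full height
            z = np.where(d <= resolution / 2.0 * math.sqrt(2.0), t.height, 0.0)
        np.maximum(grid[r0:r1, c0:c1], z, out=grid[r0:r1, c0:c1])
    return CHMRaster(grid, resolution=resolution, origin=(0.0, float(nrows) * resolution))
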