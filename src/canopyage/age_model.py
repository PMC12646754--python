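"""Predicting stand age from canopy structure: model suite and validation.

The structure–age relationship is inverted by fitting stand age as an
additive smooth function of a subset of the four canopy metrics, always
together with rainfall and plot area.  The suite comprises the four
single-metric models, the six two-metric models, and the full four-metric
model (11 in all).  Predictive skill is measured by stratified repeated
hold-out: the observed age range is cut into equal-length classes (default
11), 10% of each class is held out, the model is fitted on the rest, and
RMSE / R² on the hold-out are accumulated over repetitions.  Per-age-class
prediction bias (predicted − observed) and an empirical semivariogram of the
residuals complete the diagnostics.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam import AdditiveModelFit, fit_additive_model

__all__ = [
    "AgeModelSpec", "ValidationResult", "enumerate_model_suite",
    "stratified_split", "fit_age_model", "predict_age", "repeated_validation",
    "bias_by_age_class", "semivariogram", "validation_stats",
]

log = logging.getLogger(__name__)

ALL_METRICS = ("h_max_m", "cover_5m_pct", "h_cv", "rumple_norm")
AGE_COLUMN = "stand_age_yr"
COVARIATES = ("rainfall_mm_yr", "plot_area_ha")


@dataclass(frozen=True)
class AgeModelSpec:
    """A metric subset; rainfall and plot area are always included."""

    metrics: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.metrics:
            raise ValueError("metric subset must be non-empty")
        unknown = set(self.metrics) - set(ALL_METRICS)
        if unknown:
            raise ValueError(f"unknown metric(s) {sorted(unknown)}")

    @property
    def name(self) -> str:
        return "+".join(self.metrics)

    @property
    def predictors(self) -> list[str]:
        return list(self.metrics) + list(COVARIATES)


def enumerate_model_suite() -> list[AgeModelSpec]:
    """The 11-model suite: 4 singles, 6 pairs, 1 full set."""
    suite = [AgeModelSpec((m,)) for m in ALL_METRICS]
    suite += [AgeModelSpec(pair) for pair in itertools.combinations(ALL_METRICS, 2)]
    suite.append(AgeModelSpec(ALL_METRICS))
    return suite


# ---------------------------------------------------------------------------
# stratified hold-out

def age_class_edges(ages: np.ndarray, n_classes: int = 11) -> np.ndarray:
    """Equal-length class edges spanning the observed age range."""
    if n_classes < 2:
        raise ValueError("need at least 2 age classes")
    return np.linspace(float(np.min(ages)), float(np.max(ages)), n_classes + 1)


def assign_age_class(ages: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, len(edges) - 2)
    return idx


def stratified_split(table: pd.DataFrame, n_classes: int = 11,
                     holdout_fraction: float = 0.1,
                     seed: int | np.random.Generator = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Row indices (train, validation), stratified over equal-length age classes.

    Within each non-empty class, ``ceil(holdout_fraction · n_class)`` rows go
    to validation (at least one when the class has ≥ 2 members; singleton
    classes stay in training).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(np.random.SeedSequence(seed)))
    ages = table[AGE_COLUMN].to_numpy(float)
    edges = age_class_edges(ages, n_classes)
    classes = assign_age_class(ages, edges)
    val: list[int] = []
    for c in np.unique(classes):
        members = np.flatnonzero(classes == c)
        if members.size < 2:
            continue
        n_hold = max(int(np.ceil(holdout_fraction * members.size)), 1)
        val.extend(rng.choice(members, size=n_hold, replace=False))
    val_idx = np.sort(np.array(val, dtype=int))
    train_idx = np.setdiff1d(np.arange(len(table)), val_idx)
    return train_idx, val_idx


def fit_age_model(train: pd.DataFrame, spec: AgeModelSpec, *,
                  k: int = 10) -> AdditiveModelFit:
    """Fit stand age ~ Σ f(metric) + f(rainfall) + f(plot area)."""
    cols = spec.predictors + [AGE_COLUMN]
    data = {c: train[c].to_numpy(float) for c in cols}
    return fit_additive_model(data, AGE_COLUMN, spec.predictors, k=k)


def predict_age(fit: AdditiveModelFit, table: pd.DataFrame) -> np.ndarray:
    """Predict stand age, clamped to the training age range.

    Clamping prevents wild spline extrapolation when a validation plot's
    structure lies outside the training hull.
    """
    data = {t.name: table[t.name].to_numpy(float) for t in fit.terms}
    pred = fit.predict(data)
    # fitted + residuals reconstructs the training response exactly
    y = fit.fitted + fit.residuals
    return np.clip(pred, float(np.min(y)), float(np.max(y)))


# ---------------------------------------------------------------------------
# repeated validation

def validation_stats(predicted: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    """(RMSE, R²) with R² = 1 − SSE/SST about the validation mean."""
    predicted, observed = np.asarray(predicted, float), np.asarray(observed, float)
    err = predicted - observed
    rmse = float(np.sqrt(np.mean(err ** 2)))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err ** 2)) / sst if sst > 0 else float("nan")
    return rmse, r2


@dataclass
class ValidationResult:
    spec: AgeModelSpec
    rmse: np.ndarray              # per successful repetition
    r2: np.ndarray
    predictions: pd.DataFrame     # pooled: observed, predicted, repetition
    n_repetitions: int
    n_failed: int
    n_classes: int
    holdout_fraction: float
    seed: int

    @property
    def rmse_mean(self) -> float:
        return float(np.mean(self.rmse))

    @property
    def rmse_sd(self) -> float:
        return float(np.std(self.rmse, ddof=1)) if len(self.rmse) > 1 else 0.0

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.r2))

    def summary(self) -> dict[str, float | str | int]:
        return {
            "model": "+".join(self.spec.metrics),
            "rmse_mean": self.rmse_mean, "rmse_sd": self.rmse_sd,
            "r2_mean": self.r2_mean,
            "r2_sd": float(np.std(self.r2, ddof=1)) if len(self.r2) > 1 else 0.0,
            "n_repetitions": self.n_repetitions, "n_failed": self.n_failed,
        }


def repeated_validation(table: pd.DataFrame, spec: AgeModelSpec,
                        n_repetitions: int = 500, seed: int = 0, *,
                        n_classes: int = 11, holdout_fraction: float = 0.1,
                        k: int = 10) -> ValidationResult:
    """Stratified repeated hold-out validation of one age-model spec.

    Each repetition draws its own substream from ``seed`` (so the first
    repetition of a 1-repetition and a 500-repetition run coincide).  A
    failed fit is logged and skipped; more than 10% failures is an error.
    """
    rmses, r2s, rows = [], [], []
    n_failed = 0
    for rep in range(n_repetitions):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))
        train_idx, val_idx = stratified_split(table, n_classes, holdout_fraction, rng)
        train, val = table.iloc[train_idx], table.iloc[val_idx]
        try:
            fit = fit_age_model(train, spec, k=k)
            pred = predict_age(fit, val)
        except (ValueError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            log.warning("repetition %d failed: %s", rep, exc)
            continue
        obs = val[AGE_COLUMN].to_numpy(float)
        rmse, r2 = validation_stats(pred, obs)
        rmses.append(rmse)
        r2s.append(r2)
        rows.append(pd.DataFrame({"observed": obs, "predicted": pred,
                                  "repetition": rep}))
    if n_failed > 0.1 * n_repetitions:
        raise RuntimeError(f"{n_failed}/{n_repetitions} validation fits failed")
    return ValidationResult(
        spec=spec, rmse=np.array(rmses), r2=np.array(r2s),
        predictions=pd.concat(rows, ignore_index=True),
        n_repetitions=n_repetitions, n_failed=n_failed,
        n_classes=n_classes, holdout_fraction=holdout_fraction, seed=seed,
    )


def bias_by_age_class(predictions: pd.DataFrame, n_classes: int = 11,
                      edges: np.ndarray | None = None) -> pd.DataFrame:
    """Per-age-class error summary (predicted − observed) of pooled predictions.

    Classes are equal-length intervals over the pooled observed range unless
    explicit ``edges`` are given.  Returns one row per non-empty class with
    mean, median, and interquartile range of the error.
    """
    obs = predictions["observed"].to_numpy(float)
    err = predictions["predicted"].to_numpy(float) - obs
    if edges is None:
        edges = age_class_edges(obs, n_classes)
    classes = assign_age_class(obs, edges)
    out = []
    for c in np.unique(classes):
        e = err[classes == c]
        q1, med, q3 = np.percentile(e, [25, 50, 75])
        out.append({
            "age_class": int(c),
            "age_lo": float(edges[c]), "age_hi": float(edges[c + 1]),
            "n": int(e.size), "mean_error": float(e.mean()),
            "median_error": float(med), "iqr_lo": float(q1), "iqr_hi": float(q3),
        })
    return pd.DataFrame(out)


def semivariogram(residuals: np.ndarray, coordinates: np.ndarray,
                  bin_edges: np.ndarray) -> pd.DataFrame:
    """Empirical semivariogram γ(h) = Σ(rᵢ−rⱼ)² / (2·N(h)) over distance bins.

    ``coordinates`` is (n, 2); bins with no pairs are reported with NaN γ.
    Requires at least 10 points.
    """
    residuals = np.asarray(residuals, float)
    coords = np.asarray(coordinates, float)
    if residuals.size < 10:
        raise ValueError("need at least 10 points for a semivariogram")
    from scipy.spatial.distance import pdist
    d = pdist(coords)
    sq = pdist(residuals[:, None], metric="sqeuclidean")
    bin_edges = np.asarray(bin_edges, float)
    idx = np.digitize(d, bin_edges) - 1
    rows = []
    for b in range(len(bin_edges) - 1):
        m = idx == b
        npairs = int(np.count_nonzero(m))
        gamma = float(sq[m].sum() / (2.0 * npairs)) if npairs else float("nan")
        rows.append({"bin_center": float((bin_edges[b] + bin_edges[b + 1]) / 2),
                     "gamma": gamma, "n_pairs": npairs})
    return pd.DataFrame(rows)
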