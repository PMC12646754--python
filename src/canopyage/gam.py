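"""Penalized additive smooth models (P-splines).

Each predictor gets a cubic B-spline basis (default dimension 10, equally
spaced knots over the training range) with a second-order difference penalty
on its coefficients; an intercept is always included and each smooth is
centred over the training data for identifiability.  Smoothing parameters are
chosen by minimizing the generalized cross-validation score

    GCV(λ) = n · RSS(λ) / (n − γ·edf(λ))²

jointly over all smooths (coarse common-λ grid to locate the basin, then
Nelder–Mead on log10 λ).  The degrees-of-freedom inflation γ = 1.4 counters
GCV's well-known tendency to undersmooth when its profile is flat.  The effective degrees of
freedom are the trace of the hat matrix.  This is the standard penalized
regression-spline construction; it deliberately contains polynomials up to
degree one unpenalized, so a linear signal is recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.interpolate import BSpline
from scipy.optimize import minimize

__all__ = ["SmoothTerm", "AdditiveModelFit", "fit_additive_model"]

_LOG_LAMBDA_BOUNDS = (-5.0, 9.0)


def _basis_d2(knots: np.ndarray, degree: int, k: int, x: float) -> np.ndarray:
    """Second derivatives of all k basis splines at a point."""
    out = np.empty(k)
    for i in range(k):
        c = np.zeros(k)
        c[i] = 1.0
        out[i] = BSpline(knots, c, degree)(x, nu=2)
    return out


@dataclass(frozen=True)
class SmoothTerm:
    """One smooth f(x): basis dimension and the training-range knots."""

    name: str
    k: int = 10
    degree: int = 3
    lo: float = 0.0
    hi: float = 1.0
    knots: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    center: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @staticmethod
    def from_data(name: str, x: np.ndarray, k: int = 10, degree: int = 3) -> "SmoothTerm":
        lo, hi = float(np.min(x)), float(np.max(x))
        if not hi > lo:
            raise ValueError(f"predictor {name!r} does not vary")
        if k < degree + 1:
            raise ValueError("basis dimension too small for the spline degree")
        n_interior = k - degree - 1
        # quantile placement keeps every basis column supported by data even
        # for skewed predictors; fall back to even spacing on heavy ties
        interior = np.quantile(np.unique(x), np.linspace(0, 1, n_interior + 2)[1:-1])
        if np.any(np.diff(interior) <= 0) or interior[0] <= lo or interior[-1] >= hi:
            interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
        return SmoothTerm(name, k, degree, lo, hi, knots, None)

    def basis(self, x: np.ndarray, clip: bool = True) -> np.ndarray:
        """Design matrix of the (uncentred) basis at x; x is clipped to the
        training range when ``clip`` (evaluation outside the knots is not
        defined for B-splines)."""
        x = np.asarray(x, dtype=float)
        if clip:
            x = np.clip(x, self.lo, self.hi)
        B = BSpline.design_matrix(x, self.knots, self.degree).toarray()
        return B

    def penalty(self) -> np.ndarray:
        """Curvature penalty ∫ f''(x)² dx as a k × k Gram matrix.

        For cubic B-splines the second derivatives are piecewise linear, so
        two-point Gauss–Legendre per knot span integrates the products
        exactly.  The null space is exactly the linear-in-x functions, also
        for unevenly spaced knots.
        """
        spans = np.unique(self.knots)
        # scale x to [0, 1] so λ is comparable across predictor units
        width = spans[-1] - spans[0]
        P = np.zeros((self.k, self.k))
        gl_nodes = np.array([-1.0, 1.0]) / np.sqrt(3.0)
        for a, b in zip(spans[:-1], spans[1:]):
            half = (b - a) / 2.0
            for node in gl_nodes:
                x = (a + b) / 2.0 + half * node
                d2 = _basis_d2(self.knots, self.degree, self.k, x) * width ** 2
                P += half / width * np.outer(d2, d2)
        return P


@dataclass
class AdditiveModelFit:
    """A fitted additive smooth model y ~ intercept + Σ f_j(x_j)."""

    response: str
    terms: list[SmoothTerm]
    coef: np.ndarray
    lambdas: np.ndarray
    edf: float
    gcv: float
    fitted: np.ndarray
    residuals: np.ndarray
    n: int
    log_response: bool = False
    y_mean: float = 0.0
    y_var: float = 0.0

    @property
    def term_slices(self) -> list[slice]:
        out, start = [], 1
        for t in self.terms:
            out.append(slice(start, start + t.k))
            start += t.k
        return out

    def _design(self, data: dict[str, np.ndarray]) -> np.ndarray:
        cols = [np.ones(len(next(iter(data.values()))))[:, None]]
        for t in self.terms:
            cols.append(t.basis(np.asarray(data[t.name], float)) - t.center)
        return np.hstack(cols)

    def predict(self, data: dict[str, np.ndarray]) -> np.ndarray:
        """Additive predictor at new covariate values (link scale).

        Covariates are clipped to their training ranges; back-transformation
        of a log response is the caller's concern (see ``predict_response``).
        """
        return self._design(data) @ self.coef

    def predict_response(self, data: dict[str, np.ndarray]) -> np.ndarray:
        """Prediction on the response's original scale (naive exp for log fits)."""
        eta = self.predict(data)
        return np.exp(eta) if self.log_response else eta

    @property
    def r2(self) -> float:
        sse = float(self.residuals @ self.residuals)
        sst = float(self.y_var) * self.n
        return 1.0 - sse / sst if sst > 0 else 0.0

    @property
    def r2_adjusted(self) -> float:
        """1 − (1 − R²)(n − 1)/(n − edf − 1), edf counting the intercept."""
        denom = self.n - self.edf - 1.0
        if denom <= 0:
            raise ValueError("adjusted R² undefined: n <= edf + 1")
        return 1.0 - (1.0 - self.r2) * (self.n - 1.0) / denom


def _assemble(data: dict[str, np.ndarray], predictors: list[str],
              k: int | dict[str, int], degree: int) -> tuple[np.ndarray, list[SmoothTerm]]:
    terms = []
    n = len(next(iter(data.values())))
    cols = [np.ones((n, 1))]
    for name in predictors:
        kk = k[name] if isinstance(k, dict) else k
        t = SmoothTerm.from_data(name, np.asarray(data[name], float), k=kk, degree=degree)
        B = t.basis(np.asarray(data[name], float))
        center = B.mean(axis=0)
        t = SmoothTerm(t.name, t.k, t.degree, t.lo, t.hi, t.knots, center)
        terms.append(t)
        cols.append(B - center)
    return np.hstack(cols), terms


def fit_additive_model(data: dict[str, np.ndarray], response: str,
                       predictors: list[str], *, k: int | dict[str, int] = 10,
                       degree: int = 3, log_response: bool = False,
                       lambdas: np.ndarray | None = None,
                       gcv_gamma: float = 1.4) -> AdditiveModelFit:
    """Fit y ~ 1 + Σ f_j(x_j) by penalized least squares with GCV-chosen λ.

    ``data`` maps column names to 1-D arrays; ``lambdas`` fixes the smoothing
    parameters instead of optimizing them (one per predictor).
    """
    y = np.asarray(data[response], dtype=float)
    n = y.size
    if n < 30:
        raise ValueError("need at least 30 rows to fit an additive smooth model")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite response values")
    if log_response:
        if np.any(y <= 0):
            raise ValueError("log-transformed response requires positive values")
        y = np.log(y)

    X, terms = _assemble(data, predictors, k, degree)
    p = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y

    penalties = np.zeros((len(terms), p, p))
    start = 1
    for j, t in enumerate(terms):
        penalties[j, start:start + t.k, start:start + t.k] = t.penalty()
        start += t.k

    ridge = 1e-9 * np.trace(XtX) / p * np.eye(p)

    def solve(lam: np.ndarray):
        A = XtX + np.tensordot(lam, penalties, axes=1) + ridge
        try:
            cf = linalg.cho_factor(A, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError("rank-deficient penalized design") from exc
        beta = linalg.cho_solve(cf, Xty)
        edf = float(np.trace(linalg.cho_solve(cf, XtX)))
        return beta, edf

    def gcv_score(log_lam: np.ndarray) -> float:
        lam = 10.0 ** np.clip(log_lam, *_LOG_LAMBDA_BOUNDS)
        try:
            beta, edf = solve(lam)
        except ValueError:
            return float("inf")
        rss = float(np.sum((y - X @ beta) ** 2))
        denom = max(n - gcv_gamma * edf, 1e-6)
        return n * rss / denom ** 2

    if lambdas is None:
        starts = [np.full(len(terms), v) for v in (-2.0, 0.0, 2.0, 4.0, 6.0)]
        x0 = min(starts, key=gcv_score)
        res = minimize(gcv_score, x0, method="Nelder-Mead",
                       options={"maxfev": 60 * len(terms) + 120, "xatol": 0.05,
                                "fatol": 1e-8})
        best = np.clip(res.x, *_LOG_LAMBDA_BOUNDS)
        lam = 10.0 ** best
        gcv = float(res.fun)
    else:
        lam = np.asarray(lambdas, dtype=float)
        gcv = gcv_score(np.log10(lam))

    beta, edf = solve(lam)
    fitted = X @ beta
    return AdditiveModelFit(
        response=response, terms=terms, coef=beta, lambdas=lam, edf=edf,
        gcv=gcv, fitted=fitted, residuals=y - fitted, n=n,
        log_response=log_response, y_mean=float(y.mean()), y_var=float(y.var()),
    )
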