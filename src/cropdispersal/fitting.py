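"""Goodness-of-fit machinery.

* ``quantile_fit`` — weighted linear quantile regression solved as a linear
  program, scored with the Koenker-Machado pseudo-R^2 (R1): one minus the
  ratio of the achieved check-loss to that of the best intercept-only fit.
* ``spatial_weights`` — down-weighting of spatially clustered observations
  (1 / number of observations within a radius).
* ``distance_regression`` — OLS of a vectorized distance matrix on predictor
  matrices with a permutation test that permutes whole rows/columns of the
  response (unit of exchangeability = sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .geodesy import great_circle_matrix


@dataclass
class FitResult:
    """A goodness-of-fit record.

    ``tau`` is the quantile level (None for least squares); ``goodness`` is
    R1 for quantile fits and R^2 for least squares; ``permutation_p`` is set
    only by permutational regressions.
    """

    coefficients: np.ndarray
    goodness: float
    tau: float | None = None
    permutation_p: float | None = None
    weights_used: bool = False
    predictor_names: tuple = ()

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slope(self) -> float:
        return float(self.coefficients[1])


def check_loss(residuals: np.ndarray, tau: float, weights: np.ndarray) -> float:
    """Weighted quantile check (pinball) loss sum_i w_i rho_tau(r_i)."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(weights * r * (tau - (r < 0))))


def _weighted_quantile_loss(y: np.ndarray, tau: float, w: np.ndarray) -> float:
    """Minimum check-loss of an intercept-only model: achieved at the
    weighted tau-quantile of y."""
    order = np.argsort(y)
    ys, ws = y[order], w[order]
    cum = np.cumsum(ws)
    # any c with cumulative weight fraction crossing tau minimizes the loss
    k = int(np.searchsorted(cum, tau * cum[-1]))
    c = ys[min(k, len(ys) - 1)]
    return check_loss(y - c, tau, w)


def quantile_fit(x, y, tau: float = 0.8, weights=None) -> FitResult:
    """Weighted linear quantile regression y ~ b0 + b1 x at quantile ``tau``.

    Minimizes sum_i w_i rho_tau(y_i - b0 - b1 x_i) as a linear program
    (HiGHS).  Returns coefficients and R1 = 1 - V_model / V_intercept where
    V is the achieved weighted check-loss.  A constant predictor yields
    slope 0 and R1 = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    if weights is None:
        w = np.ones(n)
        weights_used = False
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match x")
        weights_used = True

    v0 = _weighted_quantile_loss(y, tau, w)
    if np.ptp(x) == 0.0:
        return FitResult(
            coefficients=np.array([_intercept_only(y, tau, w), 0.0]),
            goodness=0.0,
            tau=tau,
            weights_used=weights_used,
        )

    # LP variables: [b0+, b1+, b0-, b1-, u+ (n), u- (n)], all >= 0
    c = np.concatenate([[0.0, 0.0, 0.0, 0.0], tau * w, (1.0 - tau) * w])
    design = np.column_stack([np.ones(n), x])
    a_eq = sp.hstack(
        [sp.csr_matrix(design), sp.csr_matrix(-design), sp.identity(n), -sp.identity(n)]
    ).tocsr()
    res = linprog(c, A_eq=a_eq, b_eq=y, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - HiGHS is reliable on feasible LPs
        raise RuntimeError(f"quantile regression LP failed: {res.message}")
    b0 = res.x[0] - res.x[2]
    b1 = res.x[1] - res.x[3]
    v = check_loss(y - b0 - b1 * x, tau, w)
    r1 = 0.0 if v0 == 0.0 else 1.0 - v / v0
    return FitResult(
        coefficients=np.array([b0, b1]), goodness=r1, tau=tau, weights_used=weights_used
    )


def _intercept_only(y: np.ndarray, tau: float, w: np.ndarray) -> float:
    order = np.argsort(y)
    cum = np.cumsum(w[order])
    k = int(np.searchsorted(cum, tau * cum[-1]))
    return float(y[order][min(k, len(y) - 1)])


def spatial_weights(lons, lats, radius_km: float = 100.0) -> np.ndarray:
    """w_i = 1 / number of observations within ``radius_km`` of i (self included).

    An isolated observation gets weight 1; one with a single neighbour 0.5;
    k co-located duplicates get 1/k each.
    """
    d = great_circle_matrix(lons, lats)
    counts = (d <= radius_km).sum(axis=1)
    return 1.0 / counts


def predict_quantile_surface(fit: FitResult, x_grid) -> np.ndarray:
    """Evaluate the fitted quantile line b0 + b1 x over a grid of distances."""
    if fit.coefficients is None or len(fit.coefficients) < 2:
        raise ValueError("model not fitted")
    x = np.asarray(x_grid, dtype=float)
    return fit.intercept + fit.slope * x


def lower_triangle(m: np.ndarray) -> np.ndarray:
    """Vectorize the strict lower triangle of a square matrix."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def _ols_r2(yv: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
    fitted = design @ beta
    ss_res = float(np.sum((yv - fitted) ** 2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return beta, r2


def distance_regression(
    y: np.ndarray,
    overlap: np.ndarray,
    divergence: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> FitResult:
    """Permutational OLS of a genetic distance matrix on path overlap and
    path divergence matrices.

    Fits y ~ intercept + overlap + divergence on the vectorized lower
    triangles; significance is assessed by jointly permuting the row/column
    order of the response matrix (Mantel-style), with
    p = (1 + #{perm R^2 >= observed}) / (n_perm + 1).
    Collinear predictors are dropped with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if y.shape != (n, n) or n < 4:
        raise ValueError("response must be a square matrix of dimension >= 4")
    for name, m in (("overlap", overlap), ("divergence", divergence)):
        if np.asarray(m).shape != (n, n):
            raise ValueError(f"{name} matrix dimension mismatch")

    yv = lower_triangle(y)
    predictors = [("overlap", lower_triangle(overlap)), ("divergence", lower_triangle(divergence))]
    design_cols = [np.ones_like(yv)]
    names: list[str] = []
    for name, col in predictors:
        trial = np.column_stack(design_cols + [col])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            warnings.warn(f"predictor {name!r} is collinear; dropped from the model")
            continue
        design_cols.append(col)
        names.append(name)
    design = np.column_stack(design_cols)
    beta, r2_obs = _ols_r2(yv, design)

    rng = np.random.default_rng(seed)
    i, j = np.tril_indices(n, k=-1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = y[np.ix_(perm, perm)][i, j]
        _, r2_perm = _ols_r2(yp, design)
        if r2_perm >= r2_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return FitResult(
        coefficients=beta,
        goodness=r2_obs,
        permutation_p=p,
        predictor_names=tuple(names),
    )


def ols_matrix_regression(
    y: np.ndarray, x: np.ndarray, n_perm: int = 0, seed: int | None = None
) -> FitResult:
    """OLS of one distance matrix on another (e.g. isolation by distance:
    genetic distance ~ great-circle distance), optional permutation test."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    yv = lower_triangle(y)
    xv = lower_triangle(x)
    design = np.column_stack([np.ones_like(yv), xv])
    beta, r2 = _ols_r2(yv, design)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        i, j = np.tril_indices(n, k=-1)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            _, r2p = _ols_r2(y[np.ix_(perm, perm)][i, j], design)
            if r2p >= r2:
                count += 1
        p = (1 + count) / (n_perm + 1)
    return FitResult(coefficients=beta, goodness=r2, permutation_p=p,
                     predictor_names=("distance",))
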