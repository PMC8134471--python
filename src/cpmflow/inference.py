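"""Performance metrics, permutation significance, and model comparison.

Cross-validated predictions in different folds are not independent, so
parametric p-values for the predicted-vs-actual correlation overstate the
degrees of freedom.  Significance is therefore assessed by permutation: the
behavior-to-connectome correspondence is shuffled, the full cross-validated
analysis is re-run on each shuffle, and the one-tailed p-value is

    p = (#{rho_null > rho_observed} + 1) / (n_perm + 1)

with strict inequality — ties count toward the null not exceeding.  Two
models evaluated against the same behavior vector yield dependent
correlations; they are compared with Steiger's z-test for correlated
correlations sharing one variable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cpm import CPMConfig, run_cv

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerformanceMetrics:
    rho: float
    rmse: float
    n: int


@dataclass
class PermutationNull:
    """Null distribution of prediction correlations and the derived p-value."""

    rho_null: np.ndarray
    rho_observed: float
    p: float
    n_perm: int


@dataclass(frozen=True)
class ModelComparison:
    """Steiger comparison of two correlations sharing the behavior vector."""

    rho_a: float
    rho_b: float
    r_ab: float
    n: int
    z: float
    p: float


def rmse(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Root mean square error, sqrt(mean((actual - predicted)^2))."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError(
            f"length mismatch: predicted {predicted.shape}, actual {actual.shape}")
    if predicted.size < 1:
        raise ValueError("need at least one value")
    return float(np.sqrt(np.mean((actual - predicted) ** 2)))


def spearman_rho(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties).

    Chosen over Pearson for evaluation to avoid distributional assumptions on
    the behavior score.  Returns NaN with a warning when either vector is
    constant (rank correlation undefined).
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("length mismatch between predicted and actual")
    if predicted.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(predicted) == 0.0 or np.ptp(actual) == 0.0:
        warnings.warn("constant vector: Spearman correlation undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(predicted, actual).statistic)


def performance(predicted: np.ndarray, actual: np.ndarray) -> PerformanceMetrics:
    return PerformanceMetrics(spearman_rho(predicted, actual),
                              rmse(predicted, actual), len(np.asarray(actual)))


def permutation_p(rho_null: np.ndarray, rho_observed: float) -> float:
    """One-tailed permutation p: (#{null > observed} + 1) / (n_perm + 1)."""
    rho_null = np.asarray(rho_null, dtype=float)
    return float((np.sum(rho_null > rho_observed) + 1) / (rho_null.size + 1))


def permutation_test(edge_matrix: np.ndarray, behavior: np.ndarray,
                     config: CPMConfig, rho_observed: float,
                     n_perm: int = 1000, perm_seed: int = 0,
                     covariate_matrix: np.ndarray | None = None,
                     iterations_per_perm: int = 1,
                     reuse_folds: bool = False) -> PermutationNull:
    """Permutation null for a cross-validated prediction correlation.

    Each permutation shuffles the behavior vector across subjects (covariates
    stay attached to their subjects, so the adjustment structure is
    preserved), re-runs the cross-validated analysis, and records its
    predicted-vs-actual Spearman rho.  By default each permutation runs one
    cross-validation pass with fresh fold assignments; ``iterations_per_perm``
    raises that, and ``reuse_folds`` pins every permutation to the fold
    assignment seeded by ``config.seed + 1``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(edge_matrix, dtype=float)
    y = np.asarray(behavior, dtype=float)
    root = np.random.SeedSequence(perm_seed)
    null = np.empty(n_perm)
    for i, child in enumerate(root.spawn(n_perm)):
        rng = np.random.default_rng(child)
        y_perm = y[rng.permutation(len(y))]
        fold_seed = (config.seed + 1 if reuse_folds
                     else int(rng.integers(0, 2**31 - 1)))
        rhos = []
        for j in range(iterations_per_perm):
            seed_j = fold_seed if reuse_folds or j == 0 else int(
                rng.integers(0, 2**31 - 1))
            run = run_cv(x, y_perm, config, seed_j, covariate_matrix,
                         store_models=False)
            rhos.append(run.rho)
        null[i] = float(np.median(rhos))
    return PermutationNull(null, float(rho_observed),
                           permutation_p(null, rho_observed), n_perm)


def steiger_compare(rho_a: float, rho_b: float, r_ab: float,
                    n: int) -> ModelComparison:
    """Steiger's z for two dependent correlations sharing one variable.

    ``rho_a`` and ``rho_b`` each correlate a prediction vector with the same
    observed behavior; ``r_ab`` is the correlation between the two prediction
    vectors.  The statistic compares the Fisher-transformed correlations with
    the covariance correction for the shared variable (Steiger 1980, the
    pooled-correlation variant); the p-value is two-tailed normal.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for name, r in (("rho_a", rho_a), ("rho_b", rho_b)):
        if not -1.0 < r < 1.0:
            raise ValueError(
                f"{name}={r}: Fisher transform undefined outside (-1, 1)")
    if not -1.0 <= r_ab <= 1.0:
        raise ValueError(f"r_ab={r_ab} is not a correlation")
    za, zb = np.arctanh(rho_a), np.arctanh(rho_b)
    rbar = (rho_a + rho_b) / 2.0
    psi = (r_ab * (1.0 - 2.0 * rbar**2)
           - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r_ab**2))
    sbar = psi / (1.0 - rbar**2) ** 2
    z = (za - zb) * np.sqrt((n - 3) / (2.0 - 2.0 * sbar))
    p = 2.0 * stats.norm.sf(abs(z))
    return ModelComparison(float(rho_a), float(rho_b), float(r_ab), int(n),
                           float(z), float(p))


def compare_predictions(pred_a: np.ndarray, pred_b: np.ndarray,
                        actual: np.ndarray) -> ModelComparison:
    """Steiger comparison of two prediction vectors for the same behavior.

    All three correlations are Spearman (the evaluation metric), so the
    comparison is performed on the rank scale throughout.
    """
    rho_a = spearman_rho(pred_a, actual)
    rho_b = spearman_rho(pred_b, actual)
    r_ab = spearman_rho(pred_a, pred_b)
    return steiger_compare(rho_a, rho_b, r_ab, len(np.asarray(actual)))


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray | None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Equals the correlation of the least-squares residuals of x and y on the
    covariates (plus intercept); the p-value uses a t reference with
    n - n_covariates - 2 degrees of freedom.  An empty covariate set reduces
    to the plain correlation.  Returns (nan, nan) with a warning when a
    residual vector has zero variance (e.g. y is exactly a covariate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.shape[0]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        k = 0
        rx, ry = x, y
    else:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != n:
            c = c.T
        k = c.shape[1]
        design = np.column_stack([np.ones(n), c])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient covariate matrix")
        coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
        coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
        rx, ry = x - design @ coef_x, y - design @ coef_y
    df = n - k - 2
    if df < 1:
        raise ValueError(f"need n > n_covariates + 2, got n={n}, k={k}")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    nx, ny = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    # relative floor: a residual this small means the vector lay in the
    # covariate span and the partial correlation is undefined
    tol_x = 1e-10 * max(1.0, float(np.sqrt(x @ x)))
    tol_y = 1e-10 * max(1.0, float(np.sqrt(y @ y)))
    if nx <= tol_x or ny <= tol_y:
        warnings.warn("zero-variance residual: partial correlation undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan")
    r = float(np.clip((rx @ ry) / (nx * ny), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df))
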