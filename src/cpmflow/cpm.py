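"""Connectome-based predictive modeling (CPM).

CPM predicts a behavior score from functional connectivity in three steps,
repeated within k-fold cross-validation so every prediction comes from a
model whose training set excluded that subject:

1. *Edge selection* — correlate every edge with the behavior across training
   subjects; edges positively correlated with behavior at ``p < alpha`` form
   the positive network, negatively correlated edges the negative network.
2. *Network strength* — sum each subject's edge values over each selected
   network, reducing the connectome to one scalar per network.
3. *Linear model* — fit behavior on the strength score(s) by least squares in
   the training fold and apply the line to held-out subjects.

The whole procedure is repeated over many cross-validation iterations with
fresh fold assignments; the run with the median predicted-vs-actual Spearman
correlation is the reported model, and the edges its folds agree on form the
consensus networks passed to localization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .atlas import ConnectivityMatrix, vectorize

logger = logging.getLogger(__name__)

SELECTION_STATISTICS = ("pearson", "spearman", "partial_pearson")
MODEL_FORMS = ("combined", "positive_only", "negative_only")
COVARIATE_MODES = ("partial", "residualize_behavior")


@dataclass(frozen=True)
class CPMConfig:
    """Parameters of a CPM analysis.

    ``selection_alpha`` is the per-edge two-tailed p threshold for entering a
    network.  ``consensus_fraction`` is the fraction of a run's folds an edge
    must be selected in to enter the consensus network (1.0 = every fold).
    ``covariates`` names phenotype columns partialled out of the edge-behavior
    correlations during selection (``covariate_mode="partial"``) or regressed
    out of the behavior before the whole analysis
    (``covariate_mode="residualize_behavior"``); covariate values of held-out
    subjects are never used in training either way.
    """

    n_folds: int = 10
    n_iterations: int = 100
    selection_alpha: float = 0.01
    selection_statistic: str = "pearson"
    model_form: str = "combined"
    consensus_fraction: float = 1.0
    covariates: tuple[str, ...] = ()
    covariate_mode: str = "partial"
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_folds < 2:
            problems.append("n_folds must be >= 2")
        if self.n_iterations < 1:
            problems.append("n_iterations must be >= 1")
        if not 0.0 < self.selection_alpha < 1.0:
            problems.append("selection_alpha must be in (0, 1)")
        if self.selection_statistic not in SELECTION_STATISTICS:
            problems.append(
                f"selection_statistic must be one of {SELECTION_STATISTICS}")
        if self.model_form not in MODEL_FORMS:
            problems.append(f"model_form must be one of {MODEL_FORMS}")
        if not 0.0 < self.consensus_fraction <= 1.0:
            problems.append("consensus_fraction must be in (0, 1]")
        if self.covariate_mode not in COVARIATE_MODES:
            problems.append(f"covariate_mode must be one of {COVARIATE_MODES}")
        if problems:
            raise ValueError("; ".join(problems))
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass
class FoldModel:
    """Selected networks and fitted coefficients of one training fold."""

    fold_id: int
    pos_mask: np.ndarray
    neg_mask: np.ndarray
    intercept: float
    pos_coef: float | None  # None when the predictor was absent/dropped
    neg_coef: float | None

    def __post_init__(self) -> None:
        if np.any(self.pos_mask & self.neg_mask):
            raise ValueError("an edge cannot be in both networks")


@dataclass
class CVRun:
    """One complete cross-validation pass over all subjects."""

    fold_assignment: np.ndarray
    predictions: np.ndarray
    rho: float
    rmse: float
    seed: int
    fold_models: list[FoldModel] | None = None
    degenerate: bool = False  # all folds selected no edges


@dataclass
class CPMResult:
    """All cross-validation runs plus the reported median-performing model."""

    runs: list[CVRun]
    median_run_index: int
    consensus_pos: np.ndarray
    consensus_neg: np.ndarray
    config: CPMConfig
    subject_ids: list[str] | None = None
    n_dropped: int = 0
    behavior: np.ndarray | None = None

    @property
    def median_run(self) -> CVRun:
        return self.runs[self.median_run_index]

    @property
    def rho_median(self) -> float:
        return self.median_run.rho

    @property
    def rmse_median(self) -> float:
        return self.median_run.rmse


# ---------------------------------------------------------------------------
# Building blocks


def assign_folds(n_subjects: int, n_folds: int,
                 seed: int | np.random.Generator) -> np.ndarray:
    """Random fold labels 0..n_folds-1 with sizes differing by at most one."""
    if n_folds > n_subjects:
        raise ValueError(
            f"n_folds={n_folds} exceeds n_subjects={n_subjects}")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.empty(n_subjects, dtype=np.int64)
    labels[rng.permutation(n_subjects)] = np.arange(n_subjects) % n_folds
    return labels


def _correlation_and_p(x: np.ndarray, y: np.ndarray,
                       df: int) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r of x (n x E) against y, with t-test p-values.

    Zero-variance columns get r = NaN and p = 1 (never selected).
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    xn = np.sqrt(np.einsum("ij,ij->j", xc, xc))
    yn = np.sqrt(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (xn * yn)
    np.clip(r, -1.0, 1.0, out=r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = np.ones_like(r)
    finite = np.isfinite(t)
    p[finite] = 2.0 * special.stdtr(df, -np.abs(t[finite]))
    p[np.isinf(t)] = 0.0  # |r| == 1 exactly
    p[np.isnan(r)] = 1.0
    return r, p


def _rank(a: np.ndarray) -> np.ndarray:
    """Average ranks along axis 0 (columns), matching scipy.stats.rankdata."""
    from scipy.stats import rankdata

    return rankdata(a, axis=0, method="average")


def _residualize(a: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each column of ``a`` on ``design``."""
    coef, *_ = np.linalg.lstsq(design, a, rcond=None)
    return a - design @ coef


def select_edges(train_edges: np.ndarray, train_behavior: np.ndarray,
                 alpha: float = 0.01, statistic: str = "pearson",
                 train_covariates: np.ndarray | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Edge-wise feature selection against the behavior.

    Returns boolean (pos_mask, neg_mask) over the edge feature space: an edge
    is positive when its correlation with behavior across training subjects
    is > 0 with p < alpha, negative when < 0 with p < alpha.  With
    ``statistic="partial_pearson"`` the correlations and p-values are partial
    with respect to ``train_covariates`` (n x c).
    """
    x = np.asarray(train_edges, dtype=float)
    y = np.asarray(train_behavior, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("train_edges must be n_subjects x n_edges, aligned with behavior")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 training subjects")
    if np.ptp(y) == 0.0:
        raise ValueError("behavior is constant in the training fold")
    if statistic not in SELECTION_STATISTICS:
        raise ValueError(f"unknown selection statistic {statistic!r}")

    if statistic == "partial_pearson":
        if train_covariates is None or train_covariates.shape[1] == 0:
            raise ValueError("partial_pearson requires covariates")
        c = np.asarray(train_covariates, dtype=float)
        design = np.column_stack([np.ones(n), c])
        x = _residualize(x, design)
        y = _residualize(y, design)
        df = n - c.shape[1] - 2
    else:
        if statistic == "spearman":
            x = _rank(x)
            y = _rank(y[:, None])[:, 0]
        df = n - 2
    if df < 1:
        raise ValueError("not enough subjects for the requested adjustment")
    r, p = _correlation_and_p(x, y, df)
    sig = p < alpha
    return (r > 0) & sig, (r < 0) & sig


def network_strength(edges: np.ndarray, mask: np.ndarray) -> np.ndarray | float:
    """Sum of edge values over a selected network; empty mask gives 0.

    ``edges`` may be a single edge vector (returns a scalar) or an
    n_subjects x E matrix (returns a vector).
    """
    edges = np.asarray(edges, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if edges.shape[-1] != mask.shape[0]:
        raise ValueError(
            f"edge vector length {edges.shape[-1]} != mask length {mask.shape[0]}")
    s = edges[..., mask].sum(axis=-1)
    return float(s) if s.ndim == 0 else s


def fit_fold_model(train_pos: np.ndarray, train_neg: np.ndarray,
                   train_behavior: np.ndarray, model_form: str = "combined",
                   fold_id: int = 0, pos_mask: np.ndarray | None = None,
                   neg_mask: np.ndarray | None = None) -> FoldModel:
    """Least-squares behavior model on network strength scores.

    ``combined`` fits behavior ~ b0 + b1*pos + b2*neg; the single-network
    forms fit one predictor.  Constant (or absent: empty-mask) predictors are
    dropped with a logged warning; with no usable predictor the model
    degrades to the training mean.
    """
    y = np.asarray(train_behavior, dtype=float)
    use_pos = model_form in ("combined", "positive_only")
    use_neg = model_form in ("combined", "negative_only")
    cols, which = [], []
    for use, s, name in ((use_pos, train_pos, "pos"), (use_neg, train_neg, "neg")):
        if not use:
            continue
        s = np.asarray(s, dtype=float)
        if np.ptp(s) == 0.0:
            if np.any(s != 0.0):  # nonempty but constant network
                logger.warning("fold %d: constant %s strength, predictor dropped",
                               fold_id, name)
            continue
        cols.append(s)
        which.append(name)
    e = pos_mask.shape[0] if pos_mask is not None else 0
    pm = pos_mask if pos_mask is not None else np.zeros(e, dtype=bool)
    nm = neg_mask if neg_mask is not None else np.zeros(e, dtype=bool)
    if not cols:
        return FoldModel(fold_id, pm, nm, float(y.mean()), None, None)
    design = np.column_stack([np.ones(len(y))] + cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        logger.warning("fold %d: collinear strength predictors, dropping %s",
                       fold_id, which[-1])
        design = design[:, :-1]
        which = which[:-1]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    pos_coef = coef[1 + which.index("pos")] if "pos" in which else None
    neg_coef = coef[1 + which.index("neg")] if "neg" in which else None
    return FoldModel(fold_id, pm, nm, float(coef[0]),
                     None if pos_coef is None else float(pos_coef),
                     None if neg_coef is None else float(neg_coef))


def predict(model: FoldModel, test_pos: np.ndarray,
            test_neg: np.ndarray) -> np.ndarray:
    """Apply a fold model's line to held-out strength scores."""
    test_pos = np.atleast_1d(np.asarray(test_pos, dtype=float))
    out = np.full(test_pos.shape, model.intercept)
    if model.pos_coef is not None:
        out = out + model.pos_coef * test_pos
    if model.neg_coef is not None:
        out = out + model.neg_coef * np.atleast_1d(np.asarray(test_neg, dtype=float))
    return out


# ---------------------------------------------------------------------------
# Cross-validation


def run_cv(edge_matrix: np.ndarray, behavior: np.ndarray, config: CPMConfig,
           iteration_seed: int, covariate_matrix: np.ndarray | None = None,
           store_models: bool = True) -> CVRun:
    """One cross-validation pass: selection and fitting happen strictly within
    each training fold, so nothing about a held-out subject influences the
    model that predicts them.
    """
    from .inference import rmse as _rmse, spearman_rho

    x = np.asarray(edge_matrix, dtype=float)
    y = np.asarray(behavior, dtype=float)
    n = x.shape[0]
    c = covariate_matrix
    if config.covariates and c is None:
        raise ValueError("config names covariates but no covariate matrix given")
    folds = assign_folds(n, config.n_folds, iteration_seed)

    y_fit = y
    if config.covariates and config.covariate_mode == "residualize_behavior":
        # behavior residualized on covariates within each training fold below
        pass
    preds = np.empty(n)
    models: list[FoldModel] = []
    any_selected = False
    for f in range(config.n_folds):
        tr = folds != f
        te = ~tr
        y_tr = y_fit[tr]
        c_tr = c[tr] if c is not None else None
        if config.covariates and config.covariate_mode == "residualize_behavior":
            design = np.column_stack([np.ones(tr.sum()), c_tr])
            coef, *_ = np.linalg.lstsq(design, y_tr, rcond=None)
            y_tr = y_tr - design @ coef
            stat = config.selection_statistic
            if stat == "partial_pearson":
                stat = "pearson"
        else:
            stat = ("partial_pearson" if config.covariates
                    and config.covariate_mode == "partial"
                    else config.selection_statistic)
        pos, neg = select_edges(x[tr], y_tr, config.selection_alpha, stat,
                                c_tr if stat == "partial_pearson" else None)
        any_selected = any_selected or pos.any() or neg.any()
        model = fit_fold_model(
            x[tr][:, pos].sum(axis=1), x[tr][:, neg].sum(axis=1),
            y[tr] if not (config.covariates and config.covariate_mode == "residualize_behavior") else y_tr,
            config.model_form, fold_id=f, pos_mask=pos, neg_mask=neg)
        preds[te] = predict(model, x[te][:, pos].sum(axis=1),
                            x[te][:, neg].sum(axis=1))
        if store_models:
            models.append(model)

    degenerate = not any_selected
    if degenerate:
        logger.warning("cross-validation run (seed %d): no edges selected in any fold",
                       iteration_seed)
    y_eval = y
    if config.covariates and config.covariate_mode == "residualize_behavior":
        design = np.column_stack([np.ones(n), c])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        y_eval = y - design @ coef
    rho = spearman_rho(preds, y_eval)
    if math.isnan(rho):
        rho = 0.0  # constant predictions: no rank association
        degenerate = True
    return CVRun(folds, preds, float(rho), float(_rmse(preds, y_eval)),
                 iteration_seed, models if store_models else None, degenerate)


def _prepare_inputs(matrices, behavior, config, covariate_table=None,
                    subject_ids=None):
    """Vectorize matrices if needed; drop subjects missing the behavior."""
    if isinstance(matrices, np.ndarray):
        x = np.asarray(matrices, dtype=float)
        subject_ids = list(subject_ids) if subject_ids is not None else None
    else:
        x = np.stack([vectorize(m) for m in matrices])
        subject_ids = [m.subject_id for m in matrices]
    y = np.asarray(behavior, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("behavior length does not match number of subjects")
    c = None
    if config.covariates:
        if covariate_table is None:
            raise ValueError(
                f"config names covariates {config.covariates} but none supplied")
        if isinstance(covariate_table, pd.DataFrame):
            missing = [v for v in config.covariates if v not in covariate_table.columns]
            if missing:
                raise ValueError(f"covariates absent from table: {missing}")
            c = covariate_table[list(config.covariates)].to_numpy(dtype=float)
        else:
            c = np.asarray(covariate_table, dtype=float)
        if c.shape[0] != x.shape[0]:
            raise ValueError("covariate rows do not match number of subjects")

    keep = np.isfinite(y)
    if c is not None:
        keep &= np.all(np.isfinite(c), axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d subject(s) with missing behavior/covariates", n_dropped)
        x, y = x[keep], y[keep]
        c = c[keep] if c is not None else None
        subject_ids = ([s for s, k in zip(subject_ids, keep) if k]
                       if subject_ids is not None else None)
    if x.shape[0] < config.n_folds:
        raise ValueError(
            f"only {x.shape[0]} analyzable subjects for {config.n_folds} folds")
    return x, y, c, subject_ids, n_dropped


def median_run_index(rhos: np.ndarray) -> int:
    """Index of the run holding the lower-middle order statistic of rho.

    For an even number of runs this picks the ceil(n/2)-th smallest value, so
    a concrete run (with concrete fold networks) always exists to localize.
    """
    order = np.argsort(rhos, kind="stable")
    return int(order[(len(rhos) - 1) // 2])


def run_cpm(matrices, behavior, config: CPMConfig,
            covariate_table: pd.DataFrame | np.ndarray | None = None,
            subject_ids: list[str] | None = None) -> CPMResult:
    """Repeated cross-validated CPM.

    Runs ``config.n_iterations`` cross-validation passes with iteration seeds
    ``seed+1 .. seed+n_iterations``, reports the median-performing run, and
    extracts consensus networks as the edges selected in at least
    ``consensus_fraction`` of that run's folds.

    ``matrices`` may be a list of :class:`ConnectivityMatrix` or a
    pre-vectorized n_subjects x E array (rows aligned with ``behavior``).
    """
    x, y, c, subject_ids, n_dropped = _prepare_inputs(
        matrices, behavior, config, covariate_table, subject_ids)

    runs = [run_cv(x, y, config, config.seed + 1 + i, c, store_models=False)
            for i in range(config.n_iterations)]
    idx = median_run_index(np.array([r.rho for r in runs]))
    # recompute the median run with fold models kept (bit-identical: same seed)
    runs[idx] = run_cv(x, y, config, runs[idx].seed, c, store_models=True)

    k = config.n_folds
    need = config.consensus_fraction * k - 1e-9
    pos_counts = np.sum([m.pos_mask for m in runs[idx].fold_models], axis=0)
    neg_counts = np.sum([m.neg_mask for m in runs[idx].fold_models], axis=0)
    return CPMResult(runs, idx, pos_counts >= need, neg_counts >= need,
                     config, subject_ids, n_dropped, behavior=y)


def predictions_table(result: CPMResult) -> pd.DataFrame:
    """Out-of-fold predictions of the median run as a tidy table."""
    run = result.median_run
    n = len(run.predictions)
    ids = result.subject_ids if result.subject_ids is not None else [
        str(i) for i in range(n)]
    table = pd.DataFrame({
        "subject_id": ids,
        "predicted": run.predictions,
        "fold": run.fold_assignment,
        "iteration": result.median_run_index,
    })
    if result.behavior is not None:
        table.insert(1, "actual", result.behavior)
    return table
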