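"""Decentralized hinge-discordance training of linear survival signatures.

The loss on one cohort with feature matrix X (d x n), coefficients w and
comparable pairs E is

    L(w) = sum over (j, i) in E of max(0, 1 + w.x_i - w.x_j)

i.e. the longer survivor j is pushed to a higher survival score w.x_j with
margin 1.  The joint loss sums L over cohorts — no pair ever crosses a
cohort boundary — plus a ridge penalty lambda * ||w||^2.  The subgradient of
one cohort's loss is computed in O(m + n d) by accumulating a per-sample
selection-count vector u over the violated pairs and forming X @ u.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from . import __version__ as _pkg_version
from .cohort_io import Cohort, CohortCollection, DataError, TrainedSignature
from .meta_prioritize import build_priority_table, select_genes
from .preprocess import intersect_genes, percentile_rank_transform, rank_transform_collection
from .survival_metrics import ComparablePairList, comparable_pairs

log = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = np.logspace(-4, 2, 13)


@dataclass
class LossGradient:
    loss: float
    gradient: np.ndarray
    pair_count: int

    def __post_init__(self) -> None:
        self.gradient = np.asarray(self.gradient, dtype=float)
        if self.loss < -1e-12:
            raise DataError("hinge loss cannot be negative")


@dataclass
class FitConfig:
    """Solver settings for the ridge-penalized joint hinge loss."""

    lam: float = 0.0
    init: np.ndarray | None = None
    tol: float = 1e-6
    max_iter: int = 1000
    optimizer: str = "L-BFGS-B"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise DataError("tol must be positive")
        if self.max_iter < 1:
            raise DataError("max_iter must be >= 1")
        if self.lam < 0:
            raise DataError("lambda must be nonnegative")


@dataclass
class CVReport:
    """Leave-one-dataset-out penalty selection report."""

    lambda_grid: np.ndarray
    fold_names: list[str]
    heldout_loss: np.ndarray  # len(grid) x K
    cumulated_loss: np.ndarray
    best_lambda: float

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.heldout_loss = np.asarray(self.heldout_loss, dtype=float)
        self.cumulated_loss = np.asarray(self.cumulated_loss, dtype=float)
        if not np.allclose(self.cumulated_loss, self.heldout_loss.sum(axis=1)):
            raise DataError("cumulated_loss must equal the per-fold sums")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.heldout_loss,
                          columns=[f"heldout_{n}" for n in self.fold_names])
        df.insert(0, "lambda", self.lambda_grid)
        df["cumulated_loss"] = self.cumulated_loss
        df["selected"] = self.lambda_grid == self.best_lambda
        return df


def hinge_loss_subgradient(X: np.ndarray, w: np.ndarray,
                           pairs: ComparablePairList) -> LossGradient:
    """One cohort's hinge loss and subgradient in O(m + n d).

    ``X`` is d x n (features x samples), ``w`` length d.  For each pair
    (j, i) with b_j - b_i < 1 (b = X'w): loss += 1 + b_i - b_j, u_i += 1,
    u_j -= 1; the subgradient is X @ u.
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    if X.ndim != 2 or w.shape != (X.shape[0],):
        raise DataError(f"dimension mismatch: X {X.shape}, w {w.shape}")
    n = X.shape[1]
    if pairs.m and (pairs.i.max() >= n or pairs.j.max() >= n):
        raise DataError("pair index exceeds sample count")
    b = X.T @ w
    delta = b[pairs.j] - b[pairs.i]
    viol = delta < 1.0
    loss = float(np.sum(1.0 - delta[viol]))
    u = np.zeros(n)
    np.add.at(u, pairs.i[viol], 1.0)
    np.add.at(u, pairs.j[viol], -1.0)
    return LossGradient(loss, X @ u, pairs.m)


def _cohort_problems(collection: CohortCollection) -> list[tuple[np.ndarray, ComparablePairList]]:
    problems = []
    for cohort in collection:
        pairs = comparable_pairs(cohort.clinical.time, cohort.clinical.event)
        if pairs.m == 0:
            warnings.warn(
                f"cohort {cohort.name!r} has no comparable pairs and contributes "
                "zero loss", stacklevel=2,
            )
        problems.append((cohort.expression.values, pairs))
    return problems


def _joint(problems, w: np.ndarray, lam: float) -> LossGradient:
    d = problems[0][0].shape[0]
    total = 0.0
    grad = np.zeros(d)
    m = 0
    for X, pairs in problems:
        lg = hinge_loss_subgradient(X, w, pairs)
        total += lg.loss
        grad += lg.gradient
        m += pairs.m
    total += lam * float(w @ w)
    grad += 2.0 * lam * w
    return LossGradient(total, grad, m)


def joint_loss(collection: CohortCollection, w, lam: float = 0.0) -> LossGradient:
    """Ridge-penalized joint loss over all cohorts (no cross-cohort pairs)."""
    return _joint(_cohort_problems(collection), np.asarray(w, dtype=float), lam)


def _minimize(problems, config: FitConfig) -> tuple[np.ndarray, bool, int, float]:
    d = problems[0][0].shape[0]
    w0 = np.zeros(d) if config.init is None else np.asarray(config.init, dtype=float)

    def objective(w):
        lg = _joint(problems, w, config.lam)
        return lg.loss, lg.gradient

    res = minimize(objective, w0, jac=True, method=config.optimizer,
                   options={"maxiter": config.max_iter, "gtol": config.tol,
                            "ftol": 1e-12})
    return res.x, bool(res.success), int(res.nit), float(res.fun)


def fit(collection: CohortCollection, config: FitConfig | None = None) -> TrainedSignature:
    """Minimize the ridge-penalized joint hinge loss on a rank-space
    collection already restricted to the signature genes.

    Deterministic: zero initialization and a fixed quasi-Newton solver.  A
    non-converged fit (iteration cap) is still returned, flagged in
    provenance.
    """
    config = config or FitConfig()
    problems = _cohort_problems(collection)
    w, ok, nit, fun = _minimize(problems, config)
    if not ok:
        log.warning("fit did not converge within %d iterations", config.max_iter)
    return TrainedSignature(
        gene_ids=collection.gene_universe,
        coefficients=w,
        lam=config.lam,
        provenance={
            "cohorts": collection.names,
            "optimizer": config.optimizer,
            "tol": config.tol,
            "max_iter": config.max_iter,
            "converged": ok,
            "n_iter": nit,
            "final_loss": fun,
            "package_version": _pkg_version,
        },
    )


def lodo_select_lambda(collection: CohortCollection, lambda_grid=None,
                       config: FitConfig | None = None,
                       normalize_heldout: bool = False) -> CVReport:
    """Leave-one-dataset-out selection of the ridge penalty.

    For each lambda and each held-out cohort, a model is trained on the other
    K-1 cohorts and the *unpenalized* hinge loss on the held-out cohort is
    recorded; losses are cumulated across folds and the lambda with the
    minimum cumulated loss wins (ties go to the larger lambda).  With
    ``normalize_heldout`` each fold's loss is divided by its pair count so
    large cohorts do not dominate.
    """
    if len(collection) < 2:
        raise DataError(
            "leave-one-dataset-out selection needs at least 2 cohorts; "
            "fix lambda manually for a single cohort"
        )
    grid = np.sort(np.asarray(
        DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, dtype=float))
    if grid.size == 0 or (grid <= 0).any():
        raise DataError("lambda grid must be positive")
    config = config or FitConfig()
    problems = _cohort_problems(collection)
    K = len(collection)
    heldout = np.zeros((grid.size, K))
    for fold in range(K):
        train = [problems[k] for k in range(K) if k != fold]
        X_out, pairs_out = problems[fold]
        for li, lam in enumerate(grid):
            w, _, _, _ = _minimize(train, replace(config, lam=float(lam)))
            lg = hinge_loss_subgradient(X_out, w, pairs_out)
            loss = lg.loss / pairs_out.m if (normalize_heldout and pairs_out.m) else lg.loss
            heldout[li, fold] = loss
    cumulated = heldout.sum(axis=1)
    best_idx = np.nonzero(cumulated == cumulated.min())[0].max()  # tie -> larger lambda
    return CVReport(grid, collection.names, heldout, cumulated, float(grid[best_idx]))


@dataclass
class TrainingResult:
    """Bundle of every artifact the full training pipeline produces."""

    signature: TrainedSignature
    priority_table: object  # pandas DataFrame
    cv_report: CVReport | None


def train_signature(cohorts, alpha: float = 0.05, lambda_grid=None,
                    config: FitConfig | None = None, lam: float | None = None,
                    min_genes: int = 0, rank_before_intersection: bool = False,
                    denominator: str = "sqrt_k") -> TrainingResult:
    """End-to-end training on gene-level cohorts.

    Pipeline: intersect genes -> percentile ranks -> prioritize (meta-z, BH
    at ``alpha``) -> restrict to the selected genes -> leave-one-dataset-out
    lambda selection (skipped when ``lam`` is given) -> final fit on all
    cohorts.  Provenance for every stage is recorded in the signature.
    """
    config = config or FitConfig()
    cohorts = list(cohorts)
    if rank_before_intersection:
        cohorts = [c.with_expression(percentile_rank_transform(c.expression))
                   for c in cohorts]
        ranked = intersect_genes(cohorts)
    else:
        ranked = rank_transform_collection(intersect_genes(cohorts))
    table = build_priority_table(ranked, alpha=alpha, denominator=denominator)
    genes = select_genes(table, alpha=alpha, min_genes=min_genes)
    restricted = ranked.subset_genes(genes)
    cv_report = None
    if lam is None:
        if len(restricted) < 2:
            raise DataError(
                "cannot run leave-one-dataset-out selection with one cohort; "
                "pass an explicit lam"
            )
        cv_report = lodo_select_lambda(restricted, lambda_grid, config)
        lam = cv_report.best_lambda
    sig = fit(restricted, replace(config, lam=float(lam)))
    sig.provenance.update({
        "alpha": alpha,
        "n_common_genes": len(ranked.gene_universe),
        "n_selected_genes": len(genes),
        "lambda_grid": None if cv_report is None else cv_report.lambda_grid.tolist(),
        "rank_before_intersection": rank_before_intersection,
        "stouffer_denominator": denominator,
        "rank_convention": "ascending midranks / p, applied per sample",
        "score_convention": "w.x is a survival score; risk = -(w.x)",
    })
    return TrainingResult(sig, table, cv_report)


def score(sig: TrainedSignature, cohort: Cohort) -> np.ndarray:
    """Per-sample risk scores of a signature on a gene-level cohort.

    The cohort is percentile-rank transformed with the training convention,
    restricted to the signature genes, and scored as risk = -(w . x).
    Missing signature genes are an error (no imputation), as is a sample
    with constant expression (its ranks are all tied midranks).
    """
    missing = sorted(set(sig.gene_ids) - set(cohort.feature_ids))
    if missing:
        raise DataError(
            f"cohort {cohort.name!r} lacks signature gene(s): {missing[:5]}"
        )
    expr = cohort.expression
    if expr.n_features > 1:
        flat = np.ptp(expr.values, axis=0) == 0.0
        if flat.any():
            bad = [expr.sample_ids[c] for c in np.nonzero(flat)[0]]
            raise DataError(f"constant expression for sample(s) {bad[:5]}")
    ranked = percentile_rank_transform(expr).subset_features(sig.gene_ids)
    return -(sig.coefficients @ ranked.values)


# ---------------------------------------------------------------------------
# Pooled (merged-data) baseline — for heterogeneity-contrast experiments only
# ---------------------------------------------------------------------------

def _pooled_problem(collection: CohortCollection):
    """Concatenate all cohorts and form pairs across the pooled samples,
    deliberately comparing survival times across cohorts."""
    X = np.concatenate([c.expression.values for c in collection], axis=1)
    times = np.concatenate([c.clinical.time for c in collection])
    events = np.concatenate([c.clinical.event for c in collection])
    return X, comparable_pairs(times, events)


def pooled_loss_subgradient(collection: CohortCollection, w,
                            lam: float = 0.0) -> LossGradient:
    """Hinge loss of a naively merged dataset (cross-cohort pairs included).

    This is the baseline the decentralized loss is designed to avoid: it is
    NOT invariant to per-cohort survival-time rescaling.
    """
    X, pairs = _pooled_problem(collection)
    return _joint([(X, pairs)], np.asarray(w, dtype=float), lam)


def fit_pooled(collection: CohortCollection,
               config: FitConfig | None = None) -> TrainedSignature:
    """Fit the merged-data baseline model (same solver, pooled pairs)."""
    config = config or FitConfig()
    problem = [_pooled_problem(collection)]
    w, ok, nit, fun = _minimize(problem, config)
    return TrainedSignature(
        gene_ids=collection.gene_universe, coefficients=w, lam=config.lam,
        provenance={"model": "pooled_baseline", "converged": ok,
                    "n_iter": nit, "final_loss": fun},
    )


def train_merged_baseline(cohorts, alpha: float = 0.05, lambda_grid=None,
                          config: FitConfig | None = None, n_folds: int = 4,
                          seed: int = 0, min_genes: int = 0) -> TrainedSignature:
    """Naive single-dataset pipeline on the concatenated cohorts.

    Every stage treats the merged samples as one study: gene prioritization
    uses concordance z-scores over the pooled pair set (cross-cohort pairs
    included), the penalty is selected by ordinary sample-level k-fold CV on
    the merged data, and the final fit minimizes the pooled hinge loss.
    Exists only as the contrast arm for heterogeneity experiments.
    """
    from scipy.stats import norm

    from .meta_prioritize import bh_adjust
    from .survival_metrics import cindex_ztest_from_pairs

    config = config or FitConfig()
    grid = np.sort(np.asarray(
        DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, dtype=float))
    ranked = rank_transform_collection(intersect_genes(list(cohorts)))
    gene_ids = ranked.gene_universe
    X, pairs = _pooled_problem(ranked)
    times = np.concatenate([c.clinical.time for c in ranked])
    events = np.concatenate([c.clinical.event for c in ranked])

    z = np.array([
        cindex_ztest_from_pairs(X[g], pairs).z if np.ptp(X[g]) > 0 else 0.0
        for g in range(len(gene_ids))
    ])
    adj = bh_adjust(2.0 * norm.sf(np.abs(z)))
    d = int((adj < alpha).sum())
    if d == 0 and min_genes <= 0:
        raise DataError("merged baseline: no gene passes the BH threshold")
    d = max(d, min_genes)
    order = np.lexsort((gene_ids, -np.abs(z)))
    genes = sorted(np.asarray(gene_ids)[order][:d].tolist())
    rows = [gene_ids.index(g) for g in genes]
    Xs = X[rows]

    rng = np.random.default_rng(seed)
    fold = rng.integers(0, n_folds, size=Xs.shape[1])
    best_lam, best_loss = float(grid[-1]), np.inf
    for lam in grid:
        total = 0.0
        for f in range(n_folds):
            tr, te = fold != f, fold == f
            pairs_tr = comparable_pairs(times[tr], events[tr])
            w, _, _, _ = _minimize([(Xs[:, tr], pairs_tr)],
                                   replace(config, lam=float(lam)))
            pairs_te = comparable_pairs(times[te], events[te])
            total += hinge_loss_subgradient(Xs[:, te], w, pairs_te).loss
        if total <= best_loss:
            best_loss, best_lam = total, float(lam)
    w, ok, nit, fun = _minimize([(Xs, pairs)], replace(config, lam=best_lam))
    return TrainedSignature(
        gene_ids=genes, coefficients=w, lam=best_lam,
        provenance={"model": "merged_baseline", "converged": ok,
                    "n_iter": nit, "final_loss": fun, "n_selected_genes": d},
    )
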