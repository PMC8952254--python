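"""Sparse-representation feature selection and sequential forward search.

Feature importance is the coefficient magnitude of the L0-penalized
least-squares regression of the +/-1 labels on the (standardized) feature
columns,

    w_hat = argmin_w ||y - F w||_2^2 + gamma ||w||_0 ,

an NP-hard problem solved here by greedy orthogonal forward pursuit: atoms
enter by largest residual correlation with full least-squares refitting,
and the solver halts when admitting another atom no longer lowers the
penalized objective. On small problems a deletion/swap refinement pass
follows, which makes the greedy solution agree with exhaustive enumeration
on well-posed small instances. Features are then ranked by |w| descending
and a cumulative forward search over ranking prefixes (default sizes
5..100) picks the subset with the best cross-validated accuracy of the
dictionary-pair classifier.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

# refinement is O(|support| * n_features) least-squares refits per pass;
# only run it where that is cheap
_REFINE_BUDGET = 20_000


@dataclass
class SelectionModel:
    """Fitted Eq.-style sparse weights and the induced feature ranking."""

    w: np.ndarray
    gamma: float
    ranking: np.ndarray
    objective: float
    solver_trace: list = field(default_factory=list)
    feature_names: list[str] | None = None
    excluded: list[int] = field(default_factory=list)
    fit_case_ids: list[str] | None = None


@dataclass
class SubsetSearchTrace:
    """Accuracy-vs-subset-size trace of the cumulative forward search."""

    subset_sizes: np.ndarray
    cv_accuracy: np.ndarray
    best_size: int
    best_subset: np.ndarray

    def __post_init__(self) -> None:
        assert len(self.subset_sizes) == len(self.cv_accuracy)


def standardize_columns(X: np.ndarray, mean=None, scale=None):
    """Column z-scoring; zero-variance columns get scale 1 (stay constant 0)."""
    X = np.asarray(X, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def _ls_objective(F: np.ndarray, y: np.ndarray, support: Sequence[int], gamma: float):
    """Least-squares refit on a support; returns (objective, coefficients)."""
    support = list(support)
    if not support:
        return float(y @ y), np.zeros(0)
    coef, *_ = np.linalg.lstsq(F[:, support], y, rcond=None)
    resid = y - F[:, support] @ coef
    return float(resid @ resid + gamma * len(support)), coef


def fit_sparse_weights(
    F: np.ndarray,
    y: np.ndarray,
    gamma: float = 0.1,
    max_support: int | None = None,
    feature_names: Sequence[str] | None = None,
    fit_case_ids: Sequence[str] | None = None,
) -> SelectionModel:
    """Approximate the L0-penalized least-squares minimizer.

    ``F`` should have standardized columns and ``y`` be +/-1 encoded.
    Zero-variance columns are excluded from candidacy (weight 0) with a
    warning.
    """
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m, p = F.shape
    if y.size != m:
        raise ValueError("y length does not match number of rows of F")
    if max_support is None:
        max_support = min(m, p)
    max_support = min(max_support, m, p)

    col_norms = np.linalg.norm(F, axis=0)
    excluded = np.flatnonzero(col_norms < 1e-12)
    if excluded.size:
        warnings.warn(
            f"{excluded.size} zero-variance feature column(s) excluded from selection",
            stacklevel=2,
        )
    candidates = np.flatnonzero(col_norms >= 1e-12)

    # Greedy pursuit along the full path: atoms enter by residual
    # correlation with least-squares refitting; the returned support is the
    # penalized-objective argmin over path prefixes (the solver halts once
    # no prefix extension can lower the penalized objective any further).
    path: list[int] = []
    trace = []
    obj0, _ = _ls_objective(F, y, [], gamma)
    best_len, best_obj = 0, obj0
    resid = y.copy()
    while len(path) < max_support:
        free = np.setdiff1d(candidates, path, assume_unique=False)
        if free.size == 0:
            break
        corr = np.abs(F[:, free].T @ resid) / col_norms[free]
        j = int(free[np.argmax(corr)])
        path.append(j)
        new_obj, new_coef = _ls_objective(F, y, path, gamma)
        resid = y - F[:, path] @ new_coef
        rss = float(resid @ resid)
        trace.append({"atom": j, "objective": new_obj, "rss": rss})
        if new_obj < best_obj - 1e-12:
            best_len, best_obj = len(path), new_obj
        if rss < 1e-14:
            break

    support = path[:best_len]
    obj, coef = _ls_objective(F, y, support, gamma)

    if len(support) * p <= _REFINE_BUDGET:
        support, obj, coef = _refine_support(F, y, support, gamma, candidates, obj, coef)

    w = np.zeros(p)
    if support:
        w[support] = coef
    ranking = rank_order(w)
    return SelectionModel(
        w=w,
        gamma=float(gamma),
        ranking=ranking,
        objective=obj,
        solver_trace=trace,
        feature_names=list(feature_names) if feature_names is not None else None,
        excluded=excluded.tolist(),
        fit_case_ids=list(fit_case_ids) if fit_case_ids is not None else None,
    )


def _refine_support(F, y, support, gamma, candidates, obj, coef):
    """Add / delete / swap local search on the penalized objective."""
    m = F.shape[0]
    improved = True
    while improved:
        improved = False
        # deletions
        for a in list(support):
            trial = [s for s in support if s != a]
            t_obj, t_coef = _ls_objective(F, y, trial, gamma)
            if t_obj < obj - 1e-12:
                support, obj, coef = trial, t_obj, t_coef
                improved = True
        # additions
        outside = np.setdiff1d(candidates, support, assume_unique=False)
        if len(support) < m:
            for j in outside:
                t_obj, t_coef = _ls_objective(F, y, support + [int(j)], gamma)
                if t_obj < obj - 1e-12:
                    support, obj, coef = support + [int(j)], t_obj, t_coef
                    improved = True
                    break
        if improved:
            continue
        # swaps
        for a in list(support):
            base = [s for s in support if s != a]
            for j in outside:
                t_obj, t_coef = _ls_objective(F, y, base + [int(j)], gamma)
                if t_obj < obj - 1e-12:
                    support, obj, coef = base + [int(j)], t_obj, t_coef
                    improved = True
                    break
            if improved:
                break
    return support, obj, coef


def rank_order(w: np.ndarray) -> np.ndarray:
    """Indices sorted by |w| descending; ties broken by lower column index."""
    w = np.asarray(w, dtype=float)
    # stable sort on -|w| keeps index order within ties
    return np.argsort(-np.abs(w), kind="stable")


def rank_features(model: SelectionModel) -> np.ndarray:
    """The fitted model's feature ranking (a permutation of all columns)."""
    return model.ranking


def forward_search(
    F: np.ndarray,
    y: np.ndarray,
    ranking: np.ndarray,
    size_range: tuple[int, int] = (5, 100),
    cv_folds: int = 5,
    seed: int = 0,
    classifier_factory: Callable | None = None,
) -> SubsetSearchTrace:
    """Cumulative sequential forward search over ranking prefixes.

    For each prefix size (default 5..100) the stratified k-fold
    cross-validated accuracy of the dictionary-pair classifier on those
    features is recorded; the best-accuracy subset wins, smallest size on
    ties. Standardization parameters are learned on the training folds
    only.
    """
    from .dpl import classify, train  # local import: dpl depends on nothing here

    F = np.asarray(F, dtype=float)
    y = np.asarray(y)
    ranking = np.asarray(ranking)
    lo, hi = size_range
    if hi > ranking.size:
        raise ValueError("size_range upper bound exceeds the number of ranked features")
    if ranking.size < lo:
        warnings.warn(
            f"only {ranking.size} features available; searching sizes 1..{ranking.size}",
            stacklevel=2,
        )
        sizes = np.arange(1, ranking.size + 1)
    else:
        sizes = np.arange(lo, hi + 1)

    if classifier_factory is None:
        def classifier_factory(Xtr, ytr, fold_seed):
            return train(Xtr, ytr, seed=fold_seed, n_iter=25, standardize=False)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(F, y))

    accs = np.zeros(sizes.size)
    for si, k in enumerate(sizes):
        cols = ranking[:k]
        correct = 0
        for fold_i, (tr, va) in enumerate(splits):
            Xtr, mean, scale = standardize_columns(F[np.ix_(tr, cols)])
            Xva, _, _ = standardize_columns(F[np.ix_(va, cols)], mean, scale)
            model = classifier_factory(Xtr, y[tr], seed + fold_i)
            pred = classify(model, Xva).labels
            correct += int((pred == y[va]).sum())
        accs[si] = correct / F.shape[0]

    best_idx = int(np.argmax(accs))  # argmax returns the first (smallest) maximizer
    best_size = int(sizes[best_idx])
    return SubsetSearchTrace(
        subset_sizes=sizes,
        cv_accuracy=accs,
        best_size=best_size,
        best_subset=ranking[:best_size].copy(),
    )
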