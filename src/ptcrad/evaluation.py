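"""Model evaluation: metric panel with 95% CIs, DeLong AUC comparison,
univariate t-test screening with unsupervised-clustering check, and the
stratified cohort split.

Conventions: proportion CIs are exact Clopper-Pearson; the AUC CI uses the
DeLong variance with a normal interval on the logit scale; AUC itself is
the trapezoidal / Mann-Whitney value with ties counted as 1/2.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering

from .containers import AGGRESSIVE, FeatureMatrix


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI for a proportion k/n."""
    if n == 0:
        return (0.0, 1.0)
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


# ---------------------------------------------------------------------------
# DeLong machinery (structural components via midranks)
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = x.size
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def _delong_components(y_true: np.ndarray, scores: np.ndarray, positive) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the V10 (positives) and V01 (negatives) structural components."""
    pos = scores[y_true == positive]
    neg = scores[y_true != positive]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present to compute an AUC")
    allv = np.concatenate([pos, neg])
    r_all = _midrank(allv)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return float(auc), v10, v01


def auc_delong_ci(y_true, scores, positive=AGGRESSIVE, alpha: float = 0.05):
    """(auc, (lo, hi)) with the DeLong variance, normal on the logit scale."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    auc, v10, v01 = _delong_components(y_true, scores, positive)
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0 or auc <= 0.0 or auc >= 1.0:
        return auc, (auc, auc)
    z = stats.norm.ppf(1 - alpha / 2)
    logit = np.log(auc / (1 - auc))
    se_logit = se / (auc * (1 - auc))
    lo = 1.0 / (1.0 + np.exp(-(logit - z * se_logit)))
    hi = 1.0 / (1.0 + np.exp(-(logit + z * se_logit)))
    return auc, (float(lo), float(hi))


def delong_compare(y_true, scores_a, scores_b, positive=AGGRESSIVE):
    """Two-sided paired DeLong test; returns (p_value, auc_a - auc_b).

    Identical ROC curves (e.g. equal or rank-equivalent scorings) have
    zero estimated variance of the difference; the documented convention
    returns p = 1.0 rather than 0/0.
    """
    y_true = np.asarray(y_true)
    auc_a, v10a, v01a = _delong_components(y_true, np.asarray(scores_a, float), positive)
    auc_b, v10b, v01b = _delong_components(y_true, np.asarray(scores_b, float), positive)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 1e-15:
        return 1.0, float(diff)
    z = diff / np.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return min(p, 1.0), float(diff)


# ---------------------------------------------------------------------------
# metric panel
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """One table row: AUC/ACC/SEN/SPE/PPV/NPV with 95% CIs and counts."""

    model_name: str
    n_cases: int
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    auc_ci: tuple[float, float]
    acc: float
    acc_ci: tuple[float, float]
    sen: float
    sen_ci: tuple[float, float]
    spe: float
    spe_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]

    def to_row(self) -> dict:
        """The Table-2/3 column layout: '0.917 [0.827,1.000]' strings."""
        def fmt(v, ci):
            return f"{v:.3f} [{ci[0]:.3f},{ci[1]:.3f}]"

        return {
            "Models": self.model_name,
            "AUC": fmt(self.auc, self.auc_ci),
            "ACC": fmt(self.acc, self.acc_ci),
            "SEN": fmt(self.sen, self.sen_ci),
            "SPE": fmt(self.spe, self.spe_ci),
            "PPV": fmt(self.ppv, self.ppv_ci),
            "NPV": fmt(self.npv, self.npv_ci),
        }

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "n": self.n_cases,
            "confusion": {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn},
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "acc": self.acc,
            "acc_ci": list(self.acc_ci),
            "sen": self.sen,
            "sen_ci": list(self.sen_ci),
            "spe": self.spe,
            "spe_ci": list(self.spe_ci),
            "ppv": self.ppv,
            "ppv_ci": list(self.ppv_ci),
            "npv": self.npv,
            "npv_ci": list(self.npv_ci),
        }


def metric_panel(
    labels,
    scores,
    predicted_labels,
    positive=AGGRESSIVE,
    model_name: str = "model",
) -> MetricsReport:
    """Compute the full metric panel from truth, scores and hard labels."""
    labels = np.asarray(labels)
    predicted = np.asarray(predicted_labels)
    if labels.size != predicted.size or labels.size != len(scores):
        raise ValueError("labels, scores and predictions must have equal length")
    if np.unique(labels).size < 2:
        raise ValueError("AUC is undefined for a single-class label vector")

    pos_t = labels == positive
    pos_p = predicted == positive
    tp = int((pos_t & pos_p).sum())
    fp = int((~pos_t & pos_p).sum())
    tn = int((~pos_t & ~pos_p).sum())
    fn = int((pos_t & ~pos_p).sum())
    n = labels.size

    auc, auc_ci = auc_delong_ci(labels, scores, positive)

    def prop(k, d):
        return (k / d if d else 0.0), clopper_pearson(k, d)

    acc, acc_ci = prop(tp + tn, n)
    sen, sen_ci = prop(tp, tp + fn)
    spe, spe_ci = prop(tn, tn + fp)
    ppv, ppv_ci = prop(tp, tp + fp)
    npv, npv_ci = prop(tn, tn + fn)
    return MetricsReport(
        model_name=model_name,
        n_cases=n,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        auc=auc,
        auc_ci=auc_ci,
        acc=acc,
        acc_ci=acc_ci,
        sen=sen,
        sen_ci=sen_ci,
        spe=spe,
        spe_ci=spe_ci,
        ppv=ppv,
        ppv_ci=ppv_ci,
        npv=npv,
        npv_ci=npv_ci,
    )


# ---------------------------------------------------------------------------
# univariate screening + unsupervised clustering
# ---------------------------------------------------------------------------

def ttest_screen(F: FeatureMatrix, alpha: float = 0.001, positive=AGGRESSIVE):
    """Per-column Welch t-tests; returns (names with P < alpha, P-value table).

    Columns with zero variance in both classes get P = 1 by convention.
    """
    y = F.labels.to_numpy() == positive
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    X = F.values
    a, b = X[y], X[~y]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant columns trigger a harmless precision warning; their P is
        # set to 1 below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    table = pd.Series(pvals, index=F.feature_names, name="p_value")
    selected = [name for name, p in table.items() if p < alpha]
    return selected, table


@dataclass
class ClusterScreenResult:
    """Unsupervised 2-cluster check of the screened feature set."""

    selected_feature_names: list[str]
    cluster_assignment: np.ndarray
    confusion: np.ndarray  # 2x2, rows = true class (neg, pos), cols = mapped cluster
    fraction_correct: float


def cluster_screen(
    F: FeatureMatrix,
    k: int = 2,
    seed: int = 0,
    positive=AGGRESSIVE,
) -> ClusterScreenResult:
    """Ward agglomerative clustering of cases on standardized screened features.

    Clusters are mapped to labels by the better of the two permutations;
    the fraction of correctly assigned cases is reported (the analog of the
    clustering confusion-matrix check).
    """
    if F.n_features == 0:
        raise ValueError("no screened features to cluster on; use a larger alpha")
    if k != 2:
        raise ValueError("only the two-cluster case is supported")
    X = F.values
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    clust = AgglomerativeClustering(n_clusters=2, linkage="ward").fit_predict(X)
    y = (F.labels.to_numpy() == positive).astype(int)

    best_frac, best_map = -1.0, 0
    for flip in (0, 1):
        mapped = clust ^ flip
        frac = float((mapped == y).mean())
        if frac > best_frac:
            best_frac, best_map = frac, flip
    mapped = clust ^ best_map
    confusion = np.zeros((2, 2), dtype=int)
    for t, m in zip(y, mapped):
        confusion[t, m] += 1
    return ClusterScreenResult(
        selected_feature_names=F.feature_names,
        cluster_assignment=mapped,
        confusion=confusion,
        fraction_correct=best_frac,
    )


# ---------------------------------------------------------------------------
# stratified cohort split
# ---------------------------------------------------------------------------

def split_indices(labels: Sequence, fraction: float, seed: int):
    """Stratified random split into (train, test) index arrays.

    ``fraction`` is the train (cross-validation) share; the total train
    size is round(n * fraction), allocated per label by largest remainder
    so per-label proportions differ between the splits by at most one case.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    labels = np.asarray(labels)
    n = labels.size
    n_train = int(round(n * fraction))
    classes, counts = np.unique(labels, return_counts=True)
    exact = counts * fraction
    base = np.floor(exact).astype(int)
    remainder = exact - base
    short = n_train - base.sum()
    order = np.argsort(-remainder, kind="stable")
    for i in range(int(short)):
        base[order[i]] += 1

    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c, k in zip(classes, base):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        train_idx.extend(idx[:k].tolist())
        test_idx.extend(idx[k:].tolist())
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def split_cohort(cases: Sequence, fraction: float = 2.0 / 3.0, seed: int = 0):
    """Stratified split of a case list (objects with a ``label`` attribute)."""
    labels = [c.label for c in cases]
    tr, te = split_indices(labels, fraction, seed)
    return [cases[i] for i in tr], [cases[i] for i in te]
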