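"""Projective dictionary-pair learning (DPL) classification.

Each class c gets a synthesis dictionary Psi_c (feature-dim x n_atoms) and
an analysis dictionary Phi_c (n_atoms x feature-dim) trained so that
Psi_c Phi_c reconstructs own-class samples while Phi_c annihilates the
other classes:

    min sum_c ||F_c - Psi_c A_c||_F^2 + tau ||A_c - Phi_c F_c||_F^2
              + lambda ||Phi_c Fbar_c||_F^2        s.t. ||psi_q||_2^2 <= 1,

where A_c is the auxiliary coding matrix of the standard relaxation,
Fbar_c the complement of class c's samples, and the unit-norm constraint
applies to the columns (atoms) of Psi_c. Alternating minimization: A_c and
Phi_c have closed-form ridge solutions; Psi_c is updated by projected
proximal-gradient steps, so the tracked objective is non-increasing by
construction. A test sample is assigned to the class with the smallest
reconstruction residual ||f - Psi_c Phi_c f||_2.

One practical subtlety: the residual is even in f, so two classes whose
(standardized) means are antipodal around the origin produce identical
residual distributions under any linear reconstruction. Training therefore
appends a constant bias component to every sample by default
(homogeneous-coordinate convention), which breaks the sign symmetry and
lets the dictionaries encode class means; disable with ``add_bias=False``
for data whose classes are separated by their span rather than their mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_RIDGE = 1e-8  # tiny Tikhonov term on Phi, included in the tracked objective
_TIE_TOL = 1e-12


@dataclass
class DictionaryPairModel:
    """Per-class dictionary pairs plus the training-time standardization."""

    classes: np.ndarray
    psi: dict
    phi: dict
    lam: float
    tau: float
    n_atoms: int
    training_objective_trace: list[float] = field(default_factory=list)
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None
    add_bias: bool = True
    class_counts: dict | None = None
    feature_names: list[str] | None = None
    fit_case_ids: list[str] | None = None


@dataclass
class ClassificationResult:
    """Predicted labels plus per-class residuals and decision margins."""

    labels: np.ndarray
    residuals: np.ndarray  # n_cases x n_classes, column order = model.classes
    classes: np.ndarray

    @property
    def margin(self) -> np.ndarray:
        """Second-smallest minus smallest residual per case (>= 0)."""
        part = np.sort(self.residuals, axis=1)
        return part[:, 1] - part[:, 0]


def _objective(Fc, Fbar, psi, phi, A, tau, lam):
    obj = np.linalg.norm(Fc - psi @ A) ** 2
    obj += tau * np.linalg.norm(A - phi @ Fc) ** 2
    if Fbar.shape[1]:
        obj += lam * np.linalg.norm(phi @ Fbar) ** 2
    obj += _RIDGE * np.linalg.norm(phi) ** 2
    return obj


def train(
    X: np.ndarray,
    y: np.ndarray,
    lam: float = 0.01,
    n_atoms: int | None = None,
    n_iter: int = 40,
    tau: float = 1.0,
    seed: int = 0,
    tol: float = 1e-6,
    standardize: bool = True,
    add_bias: bool = True,
    feature_names: Sequence[str] | None = None,
    fit_case_ids: Sequence[str] | None = None,
) -> DictionaryPairModel:
    """Fit per-class dictionary pairs on rows of ``X`` labelled by ``y``.

    ``n_atoms`` defaults to min(15, smallest class size, feature
    dimension). Initialization is a seeded random draw of unit-norm atoms;
    sample order within a class does not affect the fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain fewer than two classes")
    counts = {c: int((y == c).sum()) for c in classes}
    if n_atoms is None:
        n_atoms = min(15, min(counts.values()), X.shape[1])
    if n_atoms > min(counts.values()):
        raise ValueError(
            f"n_atoms={n_atoms} exceeds the smallest class size {min(counts.values())}"
        )

    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        Xs = (X - mean) / scale
    else:
        mean = scale = None
        Xs = X
    if add_bias:
        Xs = np.hstack([Xs, np.ones((Xs.shape[0], 1))])

    p = Xs.shape[1]
    rng = np.random.default_rng(seed)
    psi, phi, A = {}, {}, {}
    Fc, Fbar = {}, {}
    for c in classes:
        rows = y == c
        Fc[c] = Xs[rows].T  # p x n_c
        Fbar[c] = Xs[~rows].T
        P = rng.standard_normal((p, n_atoms))
        P /= np.maximum(np.linalg.norm(P, axis=0), 1e-12)
        psi[c] = P
        phi[c] = 0.01 * rng.standard_normal((n_atoms, p))
        A[c] = phi[c] @ Fc[c]

    trace = []
    eye_k = np.eye(n_atoms)
    for it in range(n_iter):
        for c in classes:
            # coding matrix: exact minimizer given Psi, Phi
            A[c] = np.linalg.solve(
                psi[c].T @ psi[c] + tau * eye_k,
                psi[c].T @ Fc[c] + tau * phi[c] @ Fc[c],
            )
            # analysis dictionary: ridge-regularized least squares
            G = tau * Fc[c] @ Fc[c].T + lam * Fbar[c] @ Fbar[c].T + _RIDGE * np.eye(p)
            phi[c] = np.linalg.solve(G.T, (tau * A[c] @ Fc[c].T).T).T
            # synthesis dictionary: projected proximal gradient (monotone)
            AAt = A[c] @ A[c].T
            L = max(float(np.linalg.norm(AAt, 2)), 1e-12)
            FAt = Fc[c] @ A[c].T
            P = psi[c]
            for _ in range(5):
                P = P - (P @ AAt - FAt) / L
                norms = np.maximum(np.linalg.norm(P, axis=0), 1.0)
                P = P / norms
            psi[c] = P
        obj = sum(_objective(Fc[c], Fbar[c], psi[c], phi[c], A[c], tau, lam) for c in classes)
        trace.append(float(obj))
        if it > 0 and abs(trace[-2] - trace[-1]) <= tol * max(trace[-2], 1e-12):
            break

    return DictionaryPairModel(
        classes=classes,
        psi=psi,
        phi=phi,
        lam=float(lam),
        tau=float(tau),
        n_atoms=int(n_atoms),
        training_objective_trace=trace,
        mean=mean,
        scale=scale,
        add_bias=add_bias,
        class_counts=counts,
        feature_names=list(feature_names) if feature_names is not None else None,
        fit_case_ids=list(fit_case_ids) if fit_case_ids is not None else None,
    )


def classify(model: DictionaryPairModel, X: np.ndarray, feature_names=None) -> ClassificationResult:
    """Minimal-reconstruction-residual classification of rows of ``X``.

    Residual ties (|dr| < 1e-12) go to the class with more training
    samples, then to the lower class index — a deterministic rule that only
    matters for degenerate inputs such as the zero vector.
    """
    X = np.asarray(X, dtype=float)
    if feature_names is not None and model.feature_names is not None:
        if list(feature_names) != list(model.feature_names):
            missing = set(model.feature_names) - set(feature_names)
            extra = set(feature_names) - set(model.feature_names)
            raise ValueError(
                f"feature names do not match training: missing={sorted(missing)[:5]}, "
                f"extra={sorted(extra)[:5]}"
            )
    if model.mean is not None:
        X = (X - model.mean) / model.scale
    if model.add_bias:
        X = np.hstack([X, np.ones((X.shape[0], 1))])

    res = np.empty((X.shape[0], model.classes.size))
    for ci, c in enumerate(model.classes):
        recon = X @ (model.psi[c] @ model.phi[c]).T
        res[:, ci] = np.linalg.norm(X - recon, axis=1)

    # argmin with the documented tie rule
    counts = np.array([model.class_counts[c] for c in model.classes])
    order = np.lexsort((np.arange(model.classes.size), -counts))  # preference order
    best = np.zeros(X.shape[0], dtype=int)
    best_r = np.full(X.shape[0], np.inf)
    for ci in order:
        better = res[:, ci] < best_r - _TIE_TOL
        best[better] = ci
        best_r[better] = res[better, ci]
    labels = model.classes[best]
    return ClassificationResult(labels=labels, residuals=res, classes=model.classes)


def decision_score(result: ClassificationResult, positive_class) -> np.ndarray:
    """Continuous score for ROC analysis: r(negative) - r(positive).

    Positive values correspond to the positive class being predicted;
    thresholding at 0 reproduces the residual-argmin labels (up to ties).
    """
    classes = list(result.classes)
    if len(classes) != 2:
        raise ValueError("decision_score is defined for two-class results")
    if positive_class not in classes:
        raise ValueError(f"unknown positive class {positive_class!r}")
    pos = classes.index(positive_class)
    neg = 1 - pos
    return result.residuals[:, neg] - result.residuals[:, pos]
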