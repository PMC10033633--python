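"""Discriminant classifiers, a small polynomial-kernel SVM, performance
metrics and the 3 × 3 reduction/classifier model grid.

LDA and QDA assign a sample x_i to the class k minimizing a
Mahalanobis-based score,

    L_ik = (x_i - x̄_k)' C_pooled^{-1} (x_i - x̄_k) - 2 ln π_k        (LDA)
    Q_ik = (x_i - x̄_k)' C_k^{-1} (x_i - x̄_k) + ln|C_k| - 2 ln π_k   (QDA)

with x̄_k the class mean, C_pooled the pooled within-class covariance,
C_k the per-class covariance and π_k the class prior.  The SVM solves
the soft-margin dual by sequential minimal optimization and decides by

    F(x) = sign( Σ_j α_j y_j K(x, z_j) + b )

over the support vectors z_j with a polynomial kernel
K(x, z) = (γ x'z + c0)^d.  Performance on the held-out test set is
summarized as sensitivity, specificity and accuracy percentages with
fibromyalgia (FG) as the positive class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CASE, CONTROL, SpectralMatrix
from .partition import SplitIndices
from .reduce import CostSpec, ReductionResult, ga_select, pca_fit, pca_transform, spa_select

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierModel",
    "ConfusionCounts",
    "PerformanceReport",
    "GridConfig",
    "PolyKernel",
    "lda_fit",
    "qda_fit",
    "svm_fit",
    "predict",
    "decision_scores",
    "evaluate",
    "run_grid",
    "GRID_ORDER",
]

#: Row order of the model grid: reductions nested within classifiers.
GRID_ORDER = [
    ("PCA", "LDA"), ("SPA", "LDA"), ("GA", "LDA"),
    ("PCA", "QDA"), ("SPA", "QDA"), ("GA", "QDA"),
    ("PCA", "SVM"), ("SPA", "SVM"), ("GA", "SVM"),
]

_RIDGE_EPS = 1e-8


@dataclass
class PolyKernel:
    """Polynomial kernel K(x, z) = (gamma * x'z + coef0) ** degree."""

    degree: int = 2
    gamma: float | None = None  # None -> 1 / (p * Var(X_train))
    coef0: float = 1.0

    def resolve_gamma(self, X: np.ndarray) -> float:
        if self.gamma is not None:
            return self.gamma
        v = float(np.asarray(X).var())
        return 1.0 / (X.shape[1] * v) if v > 0 else 1.0 / X.shape[1]

    def matrix(self, A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
        return (gamma * (A @ B.T) + self.coef0) ** self.degree


@dataclass
class ClassifierModel:
    kind: str  # LDA | QDA | SVM
    classes: list[str]
    # discriminant parameters
    means: np.ndarray | None = None            # K × p
    pooled_cov: np.ndarray | None = None       # LDA
    covs: np.ndarray | None = None             # QDA, K × p × p
    cov_inv: np.ndarray | None = None
    covs_inv: np.ndarray | None = None
    logdets: np.ndarray | None = None
    priors: np.ndarray | None = None
    ridge_used: float | None = None
    # SVM parameters
    support_vectors: np.ndarray | None = None
    alphas: np.ndarray | None = None           # multipliers of support vectors
    sv_y: np.ndarray | None = None             # class memberships in {-1, +1}
    bias: float | None = None
    kernel: PolyKernel | None = None
    gamma_: float | None = None
    C_box: float | None = None
    n_sv: int | None = None
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


# ---------------------------------------------------------------------------
# discriminant fits
# ---------------------------------------------------------------------------

def _resolve_priors(priors: str | Sequence[float], counts: np.ndarray) -> np.ndarray:
    if isinstance(priors, str):
        if priors == "equal":
            return np.full(counts.size, 1.0 / counts.size)
        if priors == "empirical":
            return counts / counts.sum()
        raise ValueError("priors must be 'equal', 'empirical' or a vector")
    pr = np.asarray(priors, dtype=float)
    if pr.size != counts.size or not np.isclose(pr.sum(), 1.0):
        raise ValueError("prior vector must match classes and sum to 1")
    return pr


def _ridge_invert(cov: np.ndarray, label: str) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Return (regularized cov, inverse, logdet, ridge used); escalate the
    ridge by decades until the matrix is positive definite."""
    p = cov.shape[0]
    scale = np.trace(cov) / p
    if scale <= 0:
        scale = 1.0
    eps = _RIDGE_EPS
    while True:
        reg = cov + eps * scale * np.eye(p)
        try:
            chol = np.linalg.cholesky(reg)
            inv = np.linalg.inv(reg)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            if eps > _RIDGE_EPS:
                logger.warning(
                    "%s covariance singular at ridge %.0e; used %.0e",
                    label, _RIDGE_EPS, eps,
                )
            return reg, inv, logdet, eps
        except np.linalg.LinAlgError:
            if eps > 1.0:
                raise
            eps *= 10.0


def _class_stats(X: np.ndarray, y: np.ndarray, min_per_class: int):
    classes = sorted(np.unique(y).tolist())
    means, scatters, counts = [], [], []
    for c in classes:
        Xi = X[y == c]
        if Xi.shape[0] < min_per_class:
            raise ValueError(f"class {c!r} has fewer than {min_per_class} samples")
        mu = Xi.mean(axis=0)
        d = Xi - mu
        means.append(mu)
        scatters.append(d.T @ d)
        counts.append(Xi.shape[0])
    return classes, np.asarray(means), scatters, np.asarray(counts, float)


def lda_fit(
    X_train: np.ndarray, y_train: np.ndarray, priors: str | Sequence[float] = "equal"
) -> ClassifierModel:
    """Fit the pooled-covariance Mahalanobis discriminant."""
    X = np.atleast_2d(np.asarray(X_train, float))
    y = np.asarray(y_train)
    classes, means, scatters, counts = _class_stats(X, y, min_per_class=2)
    pooled = sum(scatters) / (counts.sum() - len(classes))
    pooled, inv, _, ridge = _ridge_invert(pooled, "pooled")
    return ClassifierModel(
        kind="LDA",
        classes=classes,
        means=means,
        pooled_cov=pooled,
        cov_inv=inv,
        priors=_resolve_priors(priors, counts),
        ridge_used=ridge,
    )


def qda_fit(
    X_train: np.ndarray, y_train: np.ndarray, priors: str | Sequence[float] = "equal"
) -> ClassifierModel:
    """Fit the per-class-covariance (quadratic) Mahalanobis discriminant."""
    X = np.atleast_2d(np.asarray(X_train, float))
    y = np.asarray(y_train)
    classes, means, scatters, counts = _class_stats(X, y, min_per_class=2)
    covs, invs, logdets, ridges = [], [], [], []
    for c, S, n_k in zip(classes, scatters, counts):
        cov = S / max(n_k - 1, 1)
        cov, inv, logdet, ridge = _ridge_invert(cov, f"class {c}")
        covs.append(cov)
        invs.append(inv)
        logdets.append(logdet)
        ridges.append(ridge)
    return ClassifierModel(
        kind="QDA",
        classes=classes,
        means=means,
        covs=np.asarray(covs),
        covs_inv=np.asarray(invs),
        logdets=np.asarray(logdets),
        priors=_resolve_priors(priors, counts),
        ridge_used=max(ridges),
    )


# ---------------------------------------------------------------------------
# SVM (SMO on the soft-margin dual)
# ---------------------------------------------------------------------------

def _to_pm1(y: np.ndarray, classes: list[str]) -> np.ndarray:
    # positive class is FG when present, else the second sorted class
    pos = CASE if CASE in classes else classes[-1]
    return np.where(y == pos, 1.0, -1.0)


def svm_fit(
    X_train: np.ndarray,
    y_train: np.ndarray,
    kernel: PolyKernel | None = None,
    C_box: float = 1.0,
    tol: float = 1e-4,
    max_passes: int = 10,
    max_iter: int = 20_000,
) -> ClassifierModel:
    """Soft-margin kernel SVM trained by sequential minimal optimization.

    Labels may be CG/FG strings or ±1.  The second-choice multiplier is
    picked by the maximal |E_i − E_j| heuristic, making training
    deterministic.  Non-convergence at the iteration cap returns the
    current iterate with a warning carrying the attained KKT violation.
    """
    X = np.atleast_2d(np.asarray(X_train, float))
    y_raw = np.asarray(y_train)
    if y_raw.dtype.kind in "ifu":
        classes = [CONTROL, CASE]
        y = np.where(np.asarray(y_raw, float) > 0, 1.0, -1.0)
    else:
        classes = sorted(np.unique(y_raw).tolist())
        if len(classes) != 2:
            raise ValueError("SVM requires exactly two classes")
        y = _to_pm1(y_raw, classes)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    kernel = kernel or PolyKernel()
    gamma = kernel.resolve_gamma(X)
    n = X.shape[0]
    K = kernel.matrix(X, X, gamma)

    alpha = np.zeros(n)
    b = 0.0

    def take_step(i: int, j: int, Ei: float, Ej: float) -> bool:
        nonlocal b
        if i == j:
            return False
        ai_old, aj_old = alpha[i], alpha[j]
        if y[i] != y[j]:
            L, H = max(0.0, aj_old - ai_old), min(C_box, C_box + aj_old - ai_old)
        else:
            L, H = max(0.0, ai_old + aj_old - C_box), min(C_box, ai_old + aj_old)
        if L >= H:
            return False
        eta = 2.0 * K[i, j] - K[i, i] - K[j, j]
        if eta >= 0:
            return False
        aj = float(np.clip(aj_old - y[j] * (Ei - Ej) / eta, L, H))
        if abs(aj - aj_old) < 1e-7 * (aj + aj_old + 1e-7):
            return False
        ai = ai_old + y[i] * y[j] * (aj_old - aj)
        b1 = b - Ei - y[i] * (ai - ai_old) * K[i, i] - y[j] * (aj - aj_old) * K[i, j]
        b2 = b - Ej - y[i] * (ai - ai_old) * K[i, j] - y[j] * (aj - aj_old) * K[j, j]
        alpha[i], alpha[j] = ai, aj
        if 0 < ai < C_box:
            b = b1
        elif 0 < aj < C_box:
            b = b2
        else:
            b = 0.5 * (b1 + b2)
        return True

    def dual_objective() -> float:
        ay = alpha * y
        return float(alpha.sum() - 0.5 * ay @ K @ ay)

    passes = iters = stalled = 0
    prev_obj = dual_objective()
    while passes < max_passes and iters < max_iter and stalled < 3:
        num_changed = 0
        for i in range(n):
            iters += 1
            E = (alpha * y) @ K + b - y
            Ei = float(E[i])
            if not ((y[i] * Ei < -tol and alpha[i] < C_box) or (y[i] * Ei > tol and alpha[i] > 0)):
                continue
            # second choice: maximal |Ei - Ej| heuristic, then a
            # deterministic scan over the rest until a step succeeds
            order = np.argsort(-np.abs(E - Ei), kind="stable")
            for j in order:
                if take_step(i, int(j), Ei, float(E[j])):
                    num_changed += 1
                    break
        passes = passes + 1 if num_changed == 0 else 0
        obj = dual_objective()
        stalled = stalled + 1 if obj - prev_obj <= 1e-10 * (abs(prev_obj) + 1.0) else 0
        prev_obj = obj

    # recompute the bias from the non-bound support vectors (KKT: their
    # functional margin is exactly 1); fall back to the incremental b
    nonbound = (alpha > 1e-10) & (alpha < C_box - 1e-10)
    if nonbound.any():
        f_nob = ((alpha * y) @ K)[nonbound]
        b = float(np.mean(y[nonbound] - f_nob))

    f = (alpha * y) @ K + b
    kkt = np.maximum(0.0, 1.0 - y * f)
    kkt[alpha >= C_box - 1e-12] = 0.0  # bound SVs may violate the margin
    if (iters >= max_iter or stalled >= 3) and kkt.max() > 10 * tol:
        warnings.warn(
            f"SVM did not fully converge ({iters} iterations); "
            f"max KKT margin violation {kkt.max():.3g}"
        )
    sv = alpha > 1e-10
    return ClassifierModel(
        kind="SVM",
        classes=classes,
        support_vectors=X[sv],
        alphas=alpha[sv],
        sv_y=y[sv],
        bias=float(b),
        kernel=kernel,
        gamma_=gamma,
        C_box=C_box,
        n_sv=int(sv.sum()),
        diagnostics={
            "dual_constraint": float((alpha * y).sum()),
            "train_margins": y * f,
            "all_alphas": alpha,
            "train_y": y,
        },
    )


# ---------------------------------------------------------------------------
# prediction and metrics
# ---------------------------------------------------------------------------

def decision_scores(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    """Per-class discriminant scores (LDA/QDA; lower = closer) or the
    signed SVM decision value."""
    X = np.atleast_2d(np.asarray(X, float))
    if model.kind == "LDA":
        out = np.empty((X.shape[0], len(model.classes)))
        for k, mu in enumerate(model.means):
            d = X - mu
            out[:, k] = np.einsum(
                "ij,jk,ik->i", d, model.cov_inv, d
            ) - 2.0 * np.log(model.priors[k])
        return out
    if model.kind == "QDA":
        out = np.empty((X.shape[0], len(model.classes)))
        for k, mu in enumerate(model.means):
            d = X - mu
            out[:, k] = (
                np.einsum("ij,jk,ik->i", d, model.covs_inv[k], d)
                + model.logdets[k]
                - 2.0 * np.log(model.priors[k])
            )
        return out
    if model.kind == "SVM":
        Kx = model.kernel.matrix(X, model.support_vectors, model.gamma_)
        return Kx @ (model.alphas * model.sv_y) + model.bias
    raise ValueError(f"unknown model kind {model.kind!r}")


def predict(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    scores = decision_scores(model, X)
    if model.kind == "SVM":
        pos = CASE if CASE in model.classes else model.classes[-1]
        neg = [c for c in model.classes if c != pos][0]
        return np.where(scores >= 0, pos, neg).astype(object)
    idx = np.argmin(scores, axis=1)
    return np.asarray([model.classes[k] for k in idx], dtype=object)


def evaluate(
    predictions: Sequence[str], truth: Sequence[str], positive: str = CASE
) -> tuple[ConfusionCounts, float, float, float]:
    """Confusion counts and SENS/SPEC/AC percentages (FG positive).

    SENS = 100·TP/(TP+FN), SPEC = 100·TN/(TN+FP),
    AC = 100·(TP+TN)/(TP+FP+TN+FN).  A zero denominator yields NaN with
    a warning rather than an error.
    """
    pred = np.asarray(predictions, dtype=object)
    true = np.asarray(truth, dtype=object)
    if pred.size != true.size:
        raise ValueError("predictions and truth must have equal length")
    legal = {CONTROL, CASE}
    bad = set(pred.tolist()) | set(true.tolist())
    if not bad <= legal:
        raise ValueError(f"labels outside {sorted(legal)}: {sorted(bad - legal)}")
    tp = int(((pred == positive) & (true == positive)).sum())
    tn = int(((pred != positive) & (true != positive)).sum())
    fp = int(((pred == positive) & (true != positive)).sum())
    fn = int(((pred != positive) & (true == positive)).sum())
    counts = ConfusionCounts(tp, tn, fp, fn)

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)")
            return float("nan")
        return 100.0 * num / den

    sens = ratio(tp, tp + fn, "SENS")
    spec = ratio(tn, tn + fp, "SPEC")
    ac = ratio(tp + tn, counts.total, "AC")
    return counts, sens, spec, ac


# ---------------------------------------------------------------------------
# the 9-combination model grid
# ---------------------------------------------------------------------------

@dataclass
class GridConfig:
    n_pc: int = 5
    max_vars: int = 10
    ga_generations: int = 10
    ga_pop: int = 10
    ga_seed: int = 1
    cost: CostSpec = field(default_factory=CostSpec)
    priors: str = "equal"
    svm_kernel: PolyKernel = field(default_factory=PolyKernel)
    svm_C: float = 1.0


@dataclass
class GridRow:
    reduction: str
    classifier: str
    status: str = "ok"
    counts: ConfusionCounts | None = None
    sens: float = float("nan")
    spec: float = float("nan")
    accuracy: float = float("nan")
    selected_mz: list[int] | None = None
    detail: str = ""
    best: bool = False

    @property
    def model_name(self) -> str:
        return f"{self.reduction}-{self.classifier}"


@dataclass
class PerformanceReport:
    rows: list[GridRow]
    dataset: str = ""
    n_train: int = 0
    n_test: int = 0
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def best_row(self) -> GridRow | None:
        for row in self.rows:
            if row.best:
                return row
        return None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "dataset": self.dataset,
                    "model": r.model_name,
                    "status": r.status,
                    "Sens_pct": r.sens,
                    "Spec_pct": r.spec,
                    "AC_pct": r.accuracy,
                    "TP": r.counts.TP if r.counts else None,
                    "TN": r.counts.TN if r.counts else None,
                    "FP": r.counts.FP if r.counts else None,
                    "FN": r.counts.FN if r.counts else None,
                    "selected_mz": (
                        ";".join(map(str, r.selected_mz)) if r.selected_mz else ""
                    ),
                    "best": r.best,
                }
                for r in self.rows
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _flag_best(rows: list[GridRow]) -> None:
    ok = [r for r in rows if r.status == "ok" and np.isfinite(r.accuracy)]
    if not ok:
        return
    best = max(
        ok,
        key=lambda r: (
            r.accuracy,
            r.sens if np.isfinite(r.sens) else -1.0,
            r.spec if np.isfinite(r.spec) else -1.0,
        ),
    )
    best.best = True


def run_grid(
    dataset: SpectralMatrix, split: SplitIndices, config: GridConfig | None = None
) -> PerformanceReport:
    """Train all nine reduction × classifier combinations and score them
    on the held-out test rows.

    Each reduction (PCA scores, SPA subset, GA subset) is fitted once on
    the training rows and shared by its three classifiers.  A failing
    combination is reported with its error and the grid continues.  The
    best model maximizes accuracy, ties broken by sensitivity then
    specificity.
    """
    config = config or GridConfig()
    y = dataset.labels.astype(object)
    ytr, yte = y[split.train_idx], y[split.test_idx]
    if np.unique(ytr.astype(str)).size < 2:
        raise ValueError("both classes must be present in the training set")
    Xtr, Xte = dataset.X[split.train_idx], dataset.X[split.test_idx]

    # fit each reduction once
    features: dict[str, tuple[np.ndarray, np.ndarray, list[int] | None, str]] = {}
    try:
        pca = pca_fit(Xtr, n_pc=min(config.n_pc, min(Xtr.shape[0] - 1, Xtr.shape[1])))
        features["PCA"] = (pca.scores_train, pca_transform(pca, Xte), None, "")
    except Exception as exc:  # noqa: BLE001 - grid must continue
        features["PCA"] = (None, None, None, str(exc))
    try:
        spa = spa_select(Xtr, ytr, dataset.mz_axis, config.max_vars, config.cost)
        features["SPA"] = (
            Xtr[:, spa.selected_idx], Xte[:, spa.selected_idx], spa.selected_mz, "",
        )
    except Exception as exc:  # noqa: BLE001
        features["SPA"] = (None, None, None, str(exc))
    try:
        ga = ga_select(
            Xtr, ytr, dataset.mz_axis, config.max_vars,
            config.ga_generations, config.ga_pop, config.cost, seed=config.ga_seed,
        )
        features["GA"] = (
            Xtr[:, ga.selected_idx], Xte[:, ga.selected_idx], ga.selected_mz, "",
        )
    except Exception as exc:  # noqa: BLE001
        features["GA"] = (None, None, None, str(exc))

    rows: list[GridRow] = []
    for reduction, clf in GRID_ORDER:
        ftr, fte, mz_sel, err = features[reduction]
        row = GridRow(reduction=reduction, classifier=clf, selected_mz=mz_sel)
        if ftr is None:
            row.status, row.detail = "failed", err
            rows.append(row)
            continue
        try:
            if clf == "LDA":
                model = lda_fit(ftr, ytr, priors=config.priors)
            elif clf == "QDA":
                model = qda_fit(ftr, ytr, priors=config.priors)
            else:
                model = svm_fit(ftr, ytr, kernel=config.svm_kernel, C_box=config.svm_C)
            pred = predict(model, fte)
            row.counts, row.sens, row.spec, row.accuracy = evaluate(pred, yte)
        except Exception as exc:  # noqa: BLE001
            row.status, row.detail = "failed", str(exc)
        rows.append(row)
    _flag_best(rows)
    report = PerformanceReport(
        rows=rows,
        dataset="; ".join(dataset.provenance[-1:]),
        n_train=len(split.train_idx),
        n_test=len(split.test_idx),
        class_counts=dataset.class_counts(),
    )
    return report
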