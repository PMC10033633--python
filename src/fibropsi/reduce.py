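"""Dimensionality reduction: PCA, successive projections (SPA) and
genetic-algorithm (GA) variable selection.

All three feed any downstream classifier.  SPA and GA share a cost
function — by default the leave-one-out misclassification fraction of an
LDA restricted to the candidate variables, computed on training data
only (no validation set is held out; model selection reuses the training
set, so an internal cross-validated risk is the natural fitness).
Defaults follow the modeling grid this pipeline targets: five principal
components, a ten-variable cap for SPA/GA, and a small GA of ten
generations with population ten, run in triplicate because of its
stochastic nature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ReductionResult",
    "CostSpec",
    "pca_fit",
    "pca_transform",
    "subset_cost",
    "spa_select",
    "ga_select",
    "run_triplicate_ga",
]


@dataclass
class ReductionResult:
    """Outcome of one reduction: PCA axes or a selected variable set."""

    method: str  # PCA | SPA | GA
    # PCA fields
    mean_: np.ndarray | None = None
    loadings: np.ndarray | None = None  # p × n_pc, orthonormal columns
    explained_variance_ratio: np.ndarray | None = None
    scores_train: np.ndarray | None = None
    # SPA / GA fields
    selected_mz: list[int] | None = None
    selected_idx: list[int] | None = None
    cost: float | None = None
    diagnostics: dict = field(default_factory=dict)
    seed: int | None = None


@dataclass
class CostSpec:
    """Risk used as SPA/GA selection cost: LOO (or k-fold) LDA error."""

    classifier: str = "lda"
    scheme: str = "loo"  # "loo" or "kfold"
    folds: int | None = None
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if self.classifier != "lda":
            raise ValueError("only an LDA cost is supported")
        if self.scheme == "kfold" and (self.folds is None or self.folds < 2):
            raise ValueError("kfold scheme needs folds >= 2")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_fit(X_train: np.ndarray, n_pc: int = 5) -> ReductionResult:
    """Mean-centred PCA by singular value decomposition.

    Loadings columns are orthonormal; explained-variance fractions are
    relative to the total variance.  Test data must be projected with
    :func:`pca_transform`, which reuses the training mean.
    """
    X = np.asarray(X_train, dtype=float)
    n, p = X.shape
    if not 1 <= n_pc <= min(n - 1, p):
        raise ValueError(f"n_pc={n_pc} must satisfy 1 <= n_pc <= min(n-1, p) = {min(n - 1, p)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = (s**2).sum()
    if total == 0:
        raise ValueError("matrix is constant; PCA undefined (no variance)")
    loadings = Vt[:n_pc].T
    return ReductionResult(
        method="PCA",
        mean_=mean,
        loadings=loadings,
        explained_variance_ratio=(s[:n_pc] ** 2) / total,
        scores_train=Xc @ loadings,
    )


def pca_transform(result: ReductionResult, X: np.ndarray) -> np.ndarray:
    """Project rows of ``X`` onto fitted PCA axes using the training mean."""
    if result.method != "PCA" or result.loadings is None:
        raise ValueError("pca_transform needs a fitted PCA result")
    return (np.asarray(X, float) - result.mean_) @ result.loadings


# ---------------------------------------------------------------------------
# selection cost: cross-validated LDA risk on the training set
# ---------------------------------------------------------------------------

def _lda_predict_binary(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, ridge: float
) -> np.ndarray:
    """Minimal pooled-covariance Mahalanobis LDA (equal priors)."""
    classes = np.unique(ytr)
    p = Xtr.shape[1]
    means, scatters, dof = [], np.zeros((p, p)), 0
    for c in classes:
        Xi = Xtr[ytr == c]
        mu = Xi.mean(axis=0)
        means.append(mu)
        d = Xi - mu
        scatters += d.T @ d
        dof += Xi.shape[0] - 1
    pooled = scatters / max(dof, 1)
    pooled = pooled + ridge * (np.trace(pooled) / p + 1e-300) * np.eye(p)
    try:
        Ci = np.linalg.inv(pooled)
    except np.linalg.LinAlgError:
        Ci = np.linalg.pinv(pooled)
    dists = np.empty((Xte.shape[0], classes.size))
    for k, mu in enumerate(means):
        d = Xte - mu
        dists[:, k] = np.einsum("ij,jk,ik->i", d, Ci, d)
    return classes[np.argmin(dists, axis=1)]


def subset_cost(
    X: np.ndarray,
    y: np.ndarray,
    cols: Sequence[int],
    spec: CostSpec | None = None,
    _cache: dict | None = None,
) -> float:
    """Cross-validated LDA misclassification fraction on columns ``cols``.

    Leave-one-out by default.  Folds leaving a class with fewer than two
    members are skipped (their samples count as errors would bias small
    classes; they are simply excluded from the denominator).
    """
    spec = spec or CostSpec()
    key = tuple(sorted(cols))
    if _cache is not None and key in _cache:
        return _cache[key]
    X = np.asarray(X, float)[:, list(cols)]
    y = np.asarray(y)
    n = X.shape[0]
    if spec.scheme == "loo":
        folds = [[i] for i in range(n)]
    else:
        folds = [list(rng) for rng in np.array_split(np.arange(n), spec.folds)]
    errors = evaluated = 0
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        ytr = y[mask]
        vals, counts = np.unique(ytr, return_counts=True)
        if vals.size < 2 or counts.min() < 2:
            continue
        pred = _lda_predict_binary(X[mask], ytr, X[~mask], spec.ridge)
        errors += int((pred != y[~mask]).sum())
        evaluated += len(fold)
    cost = errors / evaluated if evaluated else 1.0
    if _cache is not None:
        _cache[key] = cost
    return cost


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def spa_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    mz_labels: Sequence[int] | None = None,
    max_vars: int = 10,
    cost: CostSpec | None = None,
) -> ReductionResult:
    """Successive projections algorithm with cross-validated LDA cost.

    For every starting variable a chain is grown by repeatedly adding the
    column of maximal norm after orthogonal projection onto the
    complement of the chain's span (the classical formulation, which
    minimizes collinearity within the chain).  Every prefix of every
    chain is scored; the minimum-cost subset wins, ties broken by fewer
    variables then by lexicographically smaller m/z set.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    n, p = X.shape
    if p < 1:
        raise ValueError("no variables to select from")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in y_train")
    mz = np.asarray(mz_labels if mz_labels is not None else np.arange(p), dtype=int)
    cost = cost or CostSpec()
    cache: dict = {}
    col_norms = np.linalg.norm(X, axis=0)
    tol = 1e-10 * (col_norms.max() + 1e-300)
    max_vars = min(max_vars, p, n - 2 if n > 3 else p)

    best: tuple[float, int, tuple[int, ...]] | None = None
    chain_costs: dict[int, list[float]] = {}
    chains: dict[int, list[int]] = {}
    for start in range(p):
        if col_norms[start] <= tol:
            continue
        chain = [start]
        # residuals of all columns orthogonal to the chain's span
        R = X.copy()
        q = X[:, start] / np.linalg.norm(X[:, start])
        R = R - np.outer(q, q @ R)
        costs = [subset_cost(X, y, chain, cost, cache)]
        while len(chain) < max_vars:
            norms = np.linalg.norm(R, axis=0)
            norms[chain] = -1.0
            nxt = int(np.argmax(norms))
            if norms[nxt] <= tol:
                break  # remaining columns lie in the chain's span
            chain.append(nxt)
            qn = R[:, nxt] / np.linalg.norm(R[:, nxt])
            R = R - np.outer(qn, qn @ R)
            costs.append(subset_cost(X, y, chain, cost, cache))
        chain_costs[start] = costs
        chains[start] = list(chain)
        for k, c in enumerate(costs, start=1):
            key = tuple(sorted(mz[chain[:k]].tolist()))
            cand = (c, k, key)
            if best is None or cand < best:
                best = cand
                best_idx = sorted(chain[:k])
    if best is None:
        raise ValueError("all columns have zero norm; SPA cannot select")
    return ReductionResult(
        method="SPA",
        selected_mz=sorted(mz[best_idx].tolist()),
        selected_idx=best_idx,
        cost=best[0],
        diagnostics={"chain_costs": chain_costs, "chains": chains},
    )


# ---------------------------------------------------------------------------
# GA
# ---------------------------------------------------------------------------

def _repair(mask: np.ndarray, max_vars: int, rng: np.random.Generator) -> np.ndarray:
    active = np.flatnonzero(mask)
    while active.size > max_vars:
        off = rng.choice(active)
        mask[off] = False
        active = np.flatnonzero(mask)
    return mask


def ga_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    mz_labels: Sequence[int] | None = None,
    max_vars: int = 10,
    generations: int = 10,
    pop_size: int = 10,
    cost: CostSpec | None = None,
    seed: int = 0,
    crossover_rate: float = 0.8,
    mutation_rate: float | None = None,
    initial_population: np.ndarray | None = None,
) -> ReductionResult:
    """Genetic-algorithm variable selection over binary m/z masks.

    A minimal fully seeded GA: tournament selection of size 2,
    single-point crossover, per-bit flip mutation (default rate ``1/p``),
    repair of over-cap masks by random deactivation, elitism of one.
    Fitness is the selection cost (lower is better); all-zero masks get
    worst fitness.  Deterministic for a fixed seed.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    n, p = X.shape
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in y_train")
    mz = np.asarray(mz_labels if mz_labels is not None else np.arange(p), dtype=int)
    cost = cost or CostSpec()
    rng = np.random.default_rng(seed)
    if mutation_rate is None:
        mutation_rate = 1.0 / p
    cache: dict = {}

    def fitness(mask: np.ndarray) -> float:
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return np.inf
        return subset_cost(X, y, idx.tolist(), cost, cache)

    if initial_population is not None:
        pop = np.asarray(initial_population, dtype=bool).copy()
        if pop.shape != (pop_size, p):
            raise ValueError("initial_population must have shape (pop_size, p)")
    else:
        pop = np.zeros((pop_size, p), dtype=bool)
        for i in range(pop_size):
            k = int(rng.integers(1, max_vars + 1))
            pop[i, rng.choice(p, size=min(k, p), replace=False)] = True
    fits = np.array([fitness(m) for m in pop])
    trace_best, trace_mean = [], []
    best_mask = pop[int(np.argmin(fits))].copy()
    best_fit = float(fits.min())

    for _ in range(generations):
        trace_best.append(best_fit)
        finite = fits[np.isfinite(fits)]
        trace_mean.append(float(finite.mean()) if finite.size else np.inf)
        children = [best_mask.copy()]  # elitism of 1
        while len(children) < pop_size:
            parents = []
            for _k in range(2):
                a, b = rng.integers(0, pop_size, size=2)
                parents.append(pop[a] if fits[a] <= fits[b] else pop[b])
            c1, c2 = parents[0].copy(), parents[1].copy()
            if rng.random() < crossover_rate and p > 1:
                point = int(rng.integers(1, p))
                c1[point:], c2[point:] = parents[1][point:], parents[0][point:]
            for child in (c1, c2):
                flips = rng.random(p) < mutation_rate
                child ^= flips
                _repair(child, max_vars, rng)
                if len(children) < pop_size:
                    children.append(child)
        pop = np.array(children)
        fits = np.array([fitness(m) for m in pop])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()
    trace_best.append(best_fit)

    idx = sorted(np.flatnonzero(best_mask).tolist())
    return ReductionResult(
        method="GA",
        selected_mz=sorted(mz[idx].tolist()),
        selected_idx=idx,
        cost=best_fit,
        diagnostics={"trace_best": trace_best, "trace_mean": trace_mean},
        seed=seed,
    )


def run_triplicate_ga(
    X_train: np.ndarray,
    y_train: np.ndarray,
    mz_labels: Sequence[int] | None = None,
    max_vars: int = 10,
    generations: int = 10,
    pop_size: int = 10,
    cost: CostSpec | None = None,
    seeds: Sequence[int] = (1, 2, 3),
) -> list[ReductionResult]:
    """Three independent GA runs (the GA is stochastic; variable tallies
    are built over its triplicate execution)."""
    if len(seeds) != 3:
        raise ValueError("run_triplicate_ga expects exactly three seeds")
    return [
        ga_select(
            X_train, y_train, mz_labels, max_vars, generations, pop_size, cost, seed=s
        )
        for s in seeds
    ]
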