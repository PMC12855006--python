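"""Embedding quality metrics: reconstruction R², latent coverage, total
correlation, downstream-ML evaluation with random-feature Z-scores, and
repetition robustness, plus PCA/UMAP baseline embeddings."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import r2_score, roc_auc_score
from sklearn.svm import SVC, SVR

from .datamodel import AnnotationTable, SplitAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "reconstruction_r2", "latent_coverage", "total_correlation",
    "EmbeddingEvalResult", "evaluate_embedding", "random_feature_baseline",
    "zscore_performance", "robustness", "RobustnessResult",
    "pca_embedding", "umap_embedding", "baseline_embeddings", "ALGORITHMS",
]


def reconstruction_r2(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean over samples of per-sample explained variance.

    R²_s = 1 − Var_f(x_s − x̂_s) / Var_f(x_s) with population variances over
    features; samples with zero input variance are excluded with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError("input and reconstruction shapes differ")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 features per sample")
    var_x = x.var(axis=1)
    ok = var_x > 0
    if not np.all(ok):
        warnings.warn(f"excluding {int((~ok).sum())} zero-variance samples "
                      "from reconstruction R2")
    if not np.any(ok):
        raise ValueError("all samples have zero input variance")
    resid_var = (x - x_hat).var(axis=1)
    return float(np.mean(1.0 - resid_var[ok] / var_x[ok]))


def latent_coverage(z: np.ndarray, mode: str = "grid") -> tuple[np.ndarray, float]:
    """Occupied-bin fraction of the latent space.

    ``b = floor(n^(1/L))`` bins per dimension span each dimension's observed
    min–max range (maxima fall in the last bin). In the default ``grid`` mode
    occupancy is counted on the L-dimensional grid cells and each
    non-degenerate dimension reports the grid-cell occupancy; a degenerate
    (min = max) dimension reports 1/b. ``marginal`` mode counts occupied bins
    per dimension independently. Returns (per-dimension coverage, mean).
    """
    z = np.asarray(z, dtype=np.float64)
    if z.ndim == 1:
        z = z[:, None]
    n, L = z.shape
    if n < 2:
        raise ValueError("coverage requires at least 2 samples")
    b = int(np.floor(n ** (1.0 / L)))
    b = max(b, 1)
    lo, hi = z.min(axis=0), z.max(axis=0)
    degenerate = hi == lo
    span = np.where(degenerate, 1.0, hi - lo)
    bins = np.clip(((z - lo) / span * b).astype(int), 0, b - 1)
    per_dim = np.empty(L)
    if mode == "grid":
        cells = {tuple(row) for row in bins}
        occupancy = len(cells) / float(b ** L)
        per_dim[:] = occupancy
        per_dim[degenerate] = 1.0 / b
    elif mode == "marginal":
        for j in range(L):
            per_dim[j] = (1.0 / b if degenerate[j]
                          else np.unique(bins[:, j]).size / float(b))
    else:
        raise ValueError(f"unknown coverage mode {mode!r}")
    return per_dim, float(per_dim.mean())


def total_correlation(z: np.ndarray) -> float:
    """Gaussian total correlation −½·log det of the correlation matrix.

    Nonnegative by construction (clamped at 0); returns ``inf`` when the
    correlation matrix is singular (e.g. duplicated dimensions).
    """
    z = np.asarray(z, dtype=np.float64)
    n, L = z.shape
    if n <= L:
        raise ValueError("need more samples than latent dimensions")
    if np.any(z.var(axis=0) == 0):
        raise ValueError("constant latent dimensions have undefined correlation")
    corr = np.corrcoef(z, rowvar=False)
    if L == 1:
        return 0.0
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0 or not np.isfinite(logdet):
        return float("inf")
    tc = max(-0.5 * logdet, 0.0)
    return 0.0 if tc < 1e-12 else float(tc)  # exact 0 at identity correlation


# ---------------------------------------------------------------- downstream

def _make_estimator(algorithm: str, task: str, seed: int = 0):
    if algorithm == "linear":
        return (LogisticRegression(max_iter=1000) if task == "classification"
                else LinearRegression())
    if algorithm == "svm":
        return (SVC(kernel="rbf", random_state=seed)
                if task == "classification" else SVR(kernel="rbf"))
    if algorithm == "rf":
        return (RandomForestClassifier(n_estimators=100, random_state=seed)
                if task == "classification"
                else RandomForestRegressor(n_estimators=100, random_state=seed))
    raise ValueError(f"unknown algorithm {algorithm!r}")


ALGORITHMS = ("linear", "svm", "rf")


@dataclass
class EmbeddingEvalResult:
    task: str
    task_kind: str
    algorithm: str
    performance: float  # AUROC for classification, R² for regression
    baselines: Optional[list[float]] = None
    zscore: Optional[float] = None


def _score(estimator, x_test, y_test, task: str) -> float:
    if task == "regression":
        return float(r2_score(y_test, estimator.predict(x_test)))
    classes = estimator.classes_
    if len(classes) == 2:
        if hasattr(estimator, "predict_proba"):
            scores = estimator.predict_proba(x_test)[:, 1]
        else:
            scores = estimator.decision_function(x_test)
        return float(roc_auc_score((y_test == classes[1]).astype(int), scores))
    if hasattr(estimator, "predict_proba"):
        proba = estimator.predict_proba(x_test)
    else:  # softmax decision values; AUROC only needs the per-class ranking
        d = estimator.decision_function(x_test)
        e = np.exp(d - d.max(axis=1, keepdims=True))
        proba = e / e.sum(axis=1, keepdims=True)
    return float(roc_auc_score(y_test, proba, multi_class="ovr",
                               average="macro", labels=classes))


def evaluate_embedding(z: np.ndarray, annotations: AnnotationTable,
                       split: SplitAssignment, sample_ids: list[str],
                       algorithms: tuple = ALGORITHMS,
                       seed: int = 0) -> list[EmbeddingEvalResult]:
    """Train each (task, algorithm) on train-split embeddings, score on test.

    Classification reports macro one-vs-rest AUROC; regression reports R².
    Tasks with fewer than two classes in the training split are skipped with
    a warning.
    """
    z = np.asarray(z, dtype=np.float64)
    idx_train = split.indices(sample_ids, "train")
    idx_test = split.indices(sample_ids, "test")
    results = []
    for column, task in annotations.task_specs:
        y = annotations.table[column].to_numpy()
        y_train, y_test = y[idx_train], y[idx_test]
        if task == "classification" and np.unique(y_train).size < 2:
            warnings.warn(f"task {column!r}: single class in train split, skipped")
            continue
        for algorithm in algorithms:
            est = _make_estimator(algorithm, task, seed)
            est.fit(z[idx_train], y_train)
            perf = _score(est, z[idx_test], y_test, task)
            results.append(EmbeddingEvalResult(task=column, task_kind=task,
                                               algorithm=algorithm,
                                               performance=perf))
    return results


def random_feature_baseline(x: np.ndarray, latent_dim: int,
                            annotations: AnnotationTable,
                            split: SplitAssignment, sample_ids: list[str],
                            task: str, task_kind: str, algorithm: str,
                            r: int = 5, seed: int = 0) -> np.ndarray:
    """Performance of ``r`` seeded draws of ``latent_dim`` input features.

    Uses the same train/test protocol as :func:`evaluate_embedding`; drawing
    is without replacement (all features when latent_dim >= n_features).
    """
    x = np.asarray(x, dtype=np.float64)
    rng = np.random.default_rng(seed)
    idx_train = split.indices(sample_ids, "train")
    idx_test = split.indices(sample_ids, "test")
    y = annotations.table[task].to_numpy()
    out = []
    for _ in range(r):
        cols = (np.arange(x.shape[1]) if latent_dim >= x.shape[1]
                else rng.choice(x.shape[1], size=latent_dim, replace=False))
        est = _make_estimator(algorithm, task_kind, seed)
        est.fit(x[np.ix_(idx_train, cols)], y[idx_train])
        out.append(_score(est, x[np.ix_(idx_test, cols)], y[idx_test], task_kind))
    return np.array(out)


def zscore_performance(theta: float, eta: np.ndarray) -> Optional[float]:
    """Z-score of an embedding performance against its random-feature cohort.

    Population standard deviation; returns None (with a warning) when the
    cohort is degenerate (s.d. < 1e-8).
    """
    eta = np.asarray(eta, dtype=np.float64)
    sd = eta.std()  # ddof=0
    if sd < 1e-8:
        warnings.warn("degenerate random-feature baseline (zero spread); "
                      "z-score reported as missing")
        return None
    return float((theta - eta.mean()) / sd)


# ---------------------------------------------------------------- robustness

@dataclass
class RobustnessResult:
    per_dim: np.ndarray  # mean |pearson r| over run pairs, per latent dim
    n_runs: int

    @property
    def mean(self) -> float:
        return float(self.per_dim.mean())


def robustness(latent_runs: list[np.ndarray]) -> RobustnessResult:
    """Mean absolute Pearson correlation per latent dimension across runs.

    All runs must embed the same samples in the same order with index-matched
    latent dimensions; each unordered run pair contributes |r| per dimension.
    Zero-variance dimensions contribute 0 with a warning.
    """
    if len(latent_runs) < 2:
        raise ValueError("robustness requires at least 2 runs")
    runs = [np.asarray(z, dtype=np.float64) for z in latent_runs]
    shape = runs[0].shape
    if any(z.shape != shape for z in runs):
        raise ValueError("all runs must share (n_samples, latent_dim)")
    L = shape[1]
    per_dim = np.zeros(L)
    n_pairs = 0
    for a in range(len(runs)):
        for b in range(a + 1, len(runs)):
            n_pairs += 1
            for dim in range(L):
                za, zb = runs[a][:, dim], runs[b][:, dim]
                if za.std() == 0 or zb.std() == 0:
                    warnings.warn(f"zero-variance latent dim {dim}; "
                                  "pair contributes 0")
                    continue
                per_dim[dim] += abs(stats.pearsonr(za, zb)[0])
    return RobustnessResult(per_dim=per_dim / n_pairs, n_runs=len(runs))


# ------------------------------------------------------------------ baselines

def pca_embedding(x: np.ndarray, latent_dim: int,
                  idx_train: Optional[np.ndarray] = None) -> np.ndarray:
    """PCA scores via SVD fitted on the training rows, applied to all rows."""
    x = np.asarray(x, dtype=np.float64)
    train = x if idx_train is None else x[idx_train]
    mean = train.mean(axis=0)
    _, _, vt = np.linalg.svd(train - mean, full_matrices=False)
    return (x - mean) @ vt[:latent_dim].T


def umap_embedding(x: np.ndarray, latent_dim: int, seed: int = 0) -> np.ndarray:
    import umap  # deferred: heavy numba compilation

    reducer = umap.UMAP(n_components=latent_dim, random_state=seed)
    return np.asarray(reducer.fit_transform(np.asarray(x, dtype=np.float64)))


def baseline_embeddings(x: np.ndarray, latent_dim: int, method: str,
                        idx_train: Optional[np.ndarray] = None,
                        seed: int = 0) -> np.ndarray:
    if method == "pca":
        return pca_embedding(x, latent_dim, idx_train)
    if method == "umap":
        return umap_embedding(x, latent_dim, seed)
    raise ValueError(f"unknown baseline method {method!r}")
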