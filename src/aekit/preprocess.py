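"""Feature filtering, scaling, encoding, splitting, mutation scoring, images.

Filters rank with population-denominator statistics and break ties by feature
id order. Scalers are fitted on training rows only; degenerate (zero-scale)
features map to exactly 0 under every method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image
from sklearn.preprocessing import (MaxAbsScaler, MinMaxScaler, RobustScaler,
                                   StandardScaler)

from .datamodel import SplitAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "filter_top_variance", "filter_top_mad", "filter_correlation_medoid",
    "ScalerState", "fit_scaler", "apply_scaler", "inverse_scaler",
    "OneHotState", "fit_one_hot", "apply_one_hot",
    "split_dataset", "mutation_score", "image_preprocess", "kmedoids",
]

_SCALERS = {
    "standard": StandardScaler,
    "minmax": MinMaxScaler,
    "robust": RobustScaler,
    "maxabs": MaxAbsScaler,
}


# -------------------------------------------------------------------- filters

def _top_k(scores: np.ndarray, feature_ids: list[str], k: int):
    """Indices of the k largest scores; ties broken by feature id order."""
    if k > len(feature_ids):
        raise ValueError(f"k={k} exceeds n_features={len(feature_ids)}")
    order = sorted(range(len(feature_ids)),
                   key=lambda i: (-scores[i], feature_ids[i]))
    keep = sorted(order[:k])  # preserve input column order
    return keep


def filter_top_variance(matrix: np.ndarray, feature_ids: list[str], k: int):
    """Keep the k features of largest (population) sample variance."""
    matrix = np.asarray(matrix, dtype=np.float64)
    scores = matrix.var(axis=0)  # ddof=0
    keep = _top_k(scores, feature_ids, k)
    return matrix[:, keep], [feature_ids[i] for i in keep]


def filter_top_mad(matrix: np.ndarray, feature_ids: list[str], k: int):
    """Keep the k features of largest median absolute deviation."""
    matrix = np.asarray(matrix, dtype=np.float64)
    med = np.median(matrix, axis=0)
    scores = np.median(np.abs(matrix - med), axis=0)
    keep = _top_k(scores, feature_ids, k)
    return matrix[:, keep], [feature_ids[i] for i in keep]


def kmedoids(dist: np.ndarray, k: int, rng: np.random.Generator,
             max_iter: int = 100) -> np.ndarray:
    """Seeded PAM k-medoids (greedy BUILD then SWAP) on a distance matrix."""
    n = dist.shape[0]
    if k >= n:
        return np.arange(n)
    # BUILD: start from the point minimizing total distance, then add greedily.
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(sorted(medoids))
    # SWAP until no improvement.
    for _ in range(max_iter):
        cost = dist[:, medoids].min(axis=1).sum()
        best = (0.0, None)
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        for mi, m in enumerate(medoids):
            others = np.delete(medoids, mi)
            base = dist[:, others].min(axis=1) if others.size else np.full(n, np.inf)
            for h in non_medoids:
                new_cost = np.minimum(base, dist[:, h]).sum()
                if cost - new_cost > best[0] + 1e-12:
                    best = (cost - new_cost, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        medoids = np.array(sorted(medoids))
    return medoids


def filter_correlation_medoid(matrix: np.ndarray, feature_ids: list[str], k: int,
                              seed: int = 0, clara_threshold: int = 2000,
                              clara_sample: int = 500):
    """Pick k representative features by k-medoids on 1 - |pearson| distance.

    Exact PAM below ``clara_threshold`` features; above it a CLARA-style
    scheme clusters seeded feature subsamples and keeps the best medoid set.
    Zero-variance features are excluded before clustering with a warning.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.shape[0] < 3:
        raise ValueError("correlation filtering requires >= 3 samples")
    if k > len(feature_ids):
        raise ValueError(f"k={k} exceeds n_features={len(feature_ids)}")
    rng = np.random.default_rng(seed)
    variances = matrix.var(axis=0)
    valid = np.flatnonzero(variances > 0)
    if valid.size < len(feature_ids):
        warnings.warn(f"excluding {len(feature_ids) - valid.size} zero-variance "
                      "features before medoid clustering")
    if k >= valid.size:
        keep = sorted(valid[:k]) if valid.size >= k else sorted(valid)
        return matrix[:, keep], [feature_ids[i] for i in keep]

    def _pam_on(indices: np.ndarray) -> np.ndarray:
        sub = matrix[:, indices]
        corr = np.corrcoef(sub, rowvar=False)
        dist = 1.0 - np.abs(corr)
        np.fill_diagonal(dist, 0.0)
        return indices[kmedoids(dist, k, rng)]

    if valid.size <= clara_threshold:
        keep = sorted(_pam_on(valid))
    else:
        best_cost, best = np.inf, None
        for _ in range(5):
            sample = rng.choice(valid, size=min(clara_sample, valid.size),
                                replace=False)
            meds = _pam_on(np.sort(sample))
            corr = np.abs(np.corrcoef(matrix[:, valid].T, matrix[:, meds].T)
                          [:valid.size, valid.size:])
            cost = (1.0 - corr.max(axis=1)).sum()
            if cost < best_cost:
                best_cost, best = cost, meds
        keep = sorted(best)
    return matrix[:, keep], [feature_ids[i] for i in keep]


# -------------------------------------------------------------------- scaling

@dataclass
class ScalerState:
    method: str
    scaler: object
    degenerate: np.ndarray  # boolean mask of zero-scale features


def fit_scaler(train_matrix: np.ndarray, method: str = "standard") -> ScalerState:
    train_matrix = np.asarray(train_matrix, dtype=np.float64)
    if train_matrix.shape[0] == 0:
        raise ValueError("cannot fit scaler on an empty training split")
    if method not in _SCALERS:
        raise ValueError(f"unknown scaler method {method!r}")
    scaler = _SCALERS[method]()
    scaler.fit(train_matrix)
    degenerate = train_matrix.max(axis=0) - train_matrix.min(axis=0) == 0
    return ScalerState(method=method, scaler=scaler, degenerate=degenerate)


def apply_scaler(matrix: np.ndarray, state: ScalerState) -> np.ndarray:
    out = state.scaler.transform(np.asarray(matrix, dtype=np.float64))
    out[:, state.degenerate] = 0.0
    return out


def inverse_scaler(matrix: np.ndarray, state: ScalerState) -> np.ndarray:
    return state.scaler.inverse_transform(np.asarray(matrix, dtype=np.float64))


# ------------------------------------------------------------------- encoding

@dataclass
class OneHotState:
    levels: list[str]


def fit_one_hot(column) -> OneHotState:
    levels = sorted({str(v) for v in column})
    return OneHotState(levels=levels)


def apply_one_hot(column, state: OneHotState) -> np.ndarray:
    index = {lvl: i for i, lvl in enumerate(state.levels)}
    out = np.zeros((len(column), len(state.levels)))
    unseen = []
    for row, value in enumerate(column):
        i = index.get(str(value))
        if i is None:
            unseen.append(value)
        else:
            out[row, i] = 1.0
    if unseen:
        warnings.warn(f"one_hot: {len(unseen)} values with unseen levels "
                      f"(e.g. {unseen[0]!r}) encoded as all-zero rows")
    return out


# ------------------------------------------------------------------ splitting

def split_dataset(sample_ids, ratios: tuple[float, float, float],
                  seed: int) -> SplitAssignment:
    """Seeded shuffle split; floor(r*n) for train and valid, remainder to test."""
    if isinstance(sample_ids, int):
        sample_ids = [f"S{i:06d}" for i in range(sample_ids)]
    ratios = tuple(float(r) for r in ratios)
    if any(r < 0 for r in ratios):
        raise ValueError("ratios must be nonnegative")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(sample_ids)
    n_train = int(np.floor(ratios[0] * n))
    n_valid = int(np.floor(ratios[1] * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment: dict[str, str] = {}
    for pos, idx in enumerate(order):
        if pos < n_train:
            part = "train"
        elif pos < n_train + n_valid:
            part = "valid"
        else:
            part = "test"
        assignment[sample_ids[idx]] = part
    return SplitAssignment(assignment=assignment, ratios=ratios, seed=seed)


# ----------------------------------------------------------- mutation scoring

def mutation_score(snv_counts, cds_lengths, cna) -> np.ndarray:
    """Per-gene score: SNV count over coding length plus copy-number alteration."""
    snv = np.asarray(snv_counts, dtype=np.float64)
    cds = np.asarray(cds_lengths, dtype=np.float64)
    cna = np.asarray(cna, dtype=np.float64)
    bad = np.flatnonzero(cds <= 0)
    if bad.size:
        raise ValueError(f"non-positive CDS length for gene index {bad[0]}")
    if np.any(snv < 0):
        raise ValueError("SNV counts must be nonnegative")
    return snv / cds + cna


# --------------------------------------------------------------------- images

def image_preprocess(stack: np.ndarray, channel: int = 0,
                     target_side: int | None = None,
                     allow_resize: bool = True) -> np.ndarray:
    """Project, normalize and resize an image (stack) to (1, H, W) in [0, 1].

    Accepts (Z, C, H, W), (C, H, W) or (H, W) arrays. The requested channel is
    selected, a per-pixel maximum is taken over Z, intensities are rescaled
    min→0 / max→255 and divided by 255. Constant images map to all zeros.
    """
    arr = np.asarray(stack, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[None]
    elif arr.ndim != 4:
        raise ValueError(f"expected 2-4 dims, got {arr.ndim}")
    if channel >= arr.shape[1]:
        raise ValueError(f"channel {channel} out of range for {arr.shape[1]} channels")
    img = arr[:, channel].max(axis=0)  # maximum intensity projection over Z
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo) * 255.0
    else:
        img = np.zeros_like(img)
    img = img / 255.0
    h, w = img.shape
    if target_side is not None and (h, w) != (target_side, target_side):
        if not allow_resize:
            raise ValueError(f"image is {h}x{w}, resize to {target_side} disabled")
        if h != w:
            side = min(h, w)  # center crop to square first
            top, left = (h - side) // 2, (w - side) // 2
            img = img[top:top + side, left:left + side]
        pil = Image.fromarray((img * 255.0).astype(np.uint8))
        pil = pil.resize((target_side, target_side), Image.BILINEAR)
        img = np.asarray(pil, dtype=np.float64) / 255.0
    elif h != w:
        raise ValueError(f"non-square image {h}x{w} with no target side given")
    if target_side is not None and target_side % 32 != 0:
        raise ValueError(f"target side {target_side} is not divisible by 32")
    return img[None]
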