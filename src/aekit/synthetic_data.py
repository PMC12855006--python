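"""Synthetic multimodal fixtures with known latent structure.

A linear-Gaussian factor model drives every modality: class-conditioned
latent factors F are mixed through seeded loading matrices, optionally with
block structure so that feature blocks load predominantly on single factors
(the planted ontology), plus Gaussian noise. Images are filled disks whose
geometry is a deterministic function of the factors, so cross-modal
translation has a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AnnotationTable, ModalityBlock, MultiModalDataset, OntologyMap

__all__ = ["GeneratorSpec", "make_multiomics", "make_ontology", "make_images",
           "make_links"]


@dataclass
class GeneratorSpec:
    n_samples: int = 200
    k_true: int = 2
    feature_counts: dict[str, int] = field(default_factory=lambda: {"rna": 50})
    loading_scale: float = 1.0
    noise_sd: float = 0.1
    n_classes: int = 2
    class_separation: float = 2.0
    paired_fraction: float = 1.0
    block_structure: bool = False
    off_block_scale: float = 0.05
    nonlinear_modalities: tuple = ()
    image_side: int = 64
    image_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.noise_sd < 0 or self.class_separation < 0:
            raise ValueError("noise s.d. and class separation must be >= 0")
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ValueError("paired_fraction must be in [0, 1]")


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:05d}" for i in range(n)]


def make_multiomics(spec: GeneratorSpec) -> tuple[MultiModalDataset, dict]:
    """Generate aligned numeric modalities plus classification/regression tasks.

    Returns the dataset and a ground-truth dict with the factors, loadings
    and class labels.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.k_true
    classes = rng.integers(spec.n_classes, size=n)
    directions = rng.standard_normal((spec.n_classes, k))
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    means = directions / np.where(norms == 0, 1, norms) * spec.class_separation
    factors = means[classes] + rng.standard_normal((n, k))

    sample_ids = _sample_ids(n)
    blocks, loadings = [], {}
    for name, k_m in spec.feature_counts.items():
        if spec.block_structure:
            w = rng.standard_normal((k, k_m)) * spec.off_block_scale
            for j in range(k_m):
                w[j % k, j] = rng.standard_normal() + np.sign(
                    rng.standard_normal()) * spec.loading_scale
        else:
            w = rng.standard_normal((k, k_m)) * spec.loading_scale
        x = factors @ w
        if name in spec.nonlinear_modalities:
            x = np.log1p(np.exp(x))  # softplus gives AEs an edge over PCA
        if spec.noise_sd > 0:
            x = x + rng.standard_normal(x.shape) * spec.noise_sd
        loadings[name] = w
        blocks.append(ModalityBlock(
            name=name, kind="numeric", matrix=x,
            feature_ids=[f"{name}_f{j:04d}" for j in range(k_m)],
            sample_ids=list(sample_ids)))

    readout_w = rng.standard_normal(k)
    readout = factors @ readout_w + rng.standard_normal(n) * spec.noise_sd
    table = pd.DataFrame({
        "class": [f"c{c}" for c in classes],
        "readout": readout,
    }, index=sample_ids)
    annotations = AnnotationTable(table=table, task_specs=[
        ("class", "classification"), ("readout", "regression")])
    dataset = MultiModalDataset(blocks=blocks, sample_ids=list(sample_ids),
                                annotations=annotations)
    truth = {"factors": factors, "loadings": loadings, "classes": classes}
    return dataset, truth


def make_ontology(spec: GeneratorSpec, modality: str, n_super_terms: int = 0,
                  overlap_fraction: float = 0.0) -> OntologyMap:
    """Planted ontology: feature blocks (by index modulo k_true) become terms.

    Feature j maps to term ``j % k_true`` — the factor it predominantly loads
    on when the dataset was generated with ``block_structure=True``. An
    ``overlap_fraction`` of features is additionally mapped to the next term;
    ``n_super_terms > 0`` adds a second level grouping terms round-robin.
    """
    k_m = spec.feature_counts[modality]
    k = spec.k_true
    rng = np.random.default_rng(spec.seed + 1)
    terms = [f"T{t}" for t in range(k)]
    edges = []
    for j in range(k_m):
        fid = f"{modality}_f{j:04d}"
        t = j % k
        edges.append((fid, terms[t]))
        if overlap_fraction > 0 and rng.random() < overlap_fraction and k > 1:
            edges.append((fid, terms[(t + 1) % k]))
    level2 = None
    if n_super_terms > 0:
        level2 = [(terms[t], f"ST{t % n_super_terms}") for t in range(k)]
    return OntologyMap(level1_edges=edges, level2_edges=level2)


def _disk(side: int, cx: float, cy: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    return ((xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2).astype(np.float64)


def make_images(spec: GeneratorSpec, factors: np.ndarray,
                classes: np.ndarray) -> np.ndarray:
    """One grayscale disk image per sample, shape (n, 1, side, side) in [0, 1].

    Disk center tracks the first two latent factors (the first alone for 1-D
    factors) and the radius tracks the class, so class identity and latent
    position are both visible.
    """
    side = spec.image_side
    if side % 32 != 0:
        raise ValueError("image side must be divisible by 32")
    rng = np.random.default_rng(spec.seed + 2)
    n = factors.shape[0]
    f0 = factors[:, 0]
    f1 = factors[:, 1] if factors.shape[1] > 1 else np.zeros(n)

    def squash(v):  # map factors smoothly into the central image region
        return 1.0 / (1.0 + np.exp(-v / 2.0))

    cx = side * (0.25 + 0.5 * squash(f0))
    cy = side * (0.25 + 0.5 * squash(f1))
    radius = side * (0.10 + 0.05 * (classes % 4))
    images = np.empty((n, 1, side, side))
    for i in range(n):
        img = _disk(side, cx[i], cy[i], radius[i])
        if spec.image_noise_sd > 0:
            img = img + rng.standard_normal(img.shape) * spec.image_noise_sd
        images[i, 0] = np.clip(img, 0.0, 1.0)
    return images


def make_links(spec: GeneratorSpec, classes: np.ndarray) -> dict:
    """Sample linkage across the two modalities.

    Paired mode links a seeded ``paired_fraction`` of identical indices;
    unpaired mode permutes modality-B indices within class so only the class
    labels connect the modalities (class marginals are preserved).
    """
    rng = np.random.default_rng(spec.seed + 3)
    n = len(classes)
    if spec.paired_fraction > 0:
        n_paired = int(round(spec.paired_fraction * n))
        chosen = np.sort(rng.choice(n, size=n_paired, replace=False))
        pairs = np.stack([chosen, chosen], axis=1) if n_paired else np.empty((0, 2), int)
        return {"mode": "paired", "pairs": pairs, "labels": np.asarray(classes)}
    if spec.n_classes < 2:
        import warnings
        warnings.warn("paired fraction 0 with no class structure: "
                      "no alignment signal available")
    permuted = np.arange(n)
    for c in np.unique(classes):
        members = np.flatnonzero(classes == c)
        permuted[members] = rng.permutation(members)
    return {"mode": "class", "pairs": np.empty((0, 2), int),
            "b_index": permuted, "labels": np.asarray(classes)}
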