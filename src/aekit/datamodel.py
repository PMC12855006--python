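"""Core data model: modality blocks, annotations, ontologies, run configuration.

Matrices are sample-by-feature ``pandas``-free NumPy arrays with explicit
ordered identifier lists; the run configuration is a strict (unknown keys are
errors) pydantic schema loaded from YAML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "ModalityBlock", "MultiModalDataset", "AnnotationTable", "SplitAssignment",
    "OntologyMap", "RunConfig", "FilterSpec", "ScalerSpec", "DataSpec",
    "ConfigError", "AlignmentError", "OntologyError",
    "load_config", "align_samples", "validate_ontology",
]


class ConfigError(ValueError):
    """Raised for unknown keys or invariant violations in a run configuration."""


class AlignmentError(ValueError):
    """Raised when modalities share no samples."""


class OntologyError(ValueError):
    """Raised for cyclic or level-crossing ontology edges."""


class ModalityKind(str, Enum):
    numeric = "numeric"
    categorical = "categorical"
    image = "image"


@dataclass
class ModalityBlock:
    """One modality: an (n_samples, k_features) matrix plus identifiers.

    For ``kind='image'`` the matrix holds flattened pixels and
    ``image_manifest`` maps each sample to its source path and (C, H, W)
    shape; only square images (H == W) are accepted.
    """

    name: str
    kind: str
    matrix: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    image_manifest: Optional[dict[str, tuple]] = None

    def __post_init__(self):
        self.kind = ModalityKind(self.kind).value
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError(f"block {self.name!r}: matrix must be 2-D")
        if self.matrix.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"block {self.name!r}: {self.matrix.shape[0]} rows vs "
                f"{len(self.sample_ids)} sample ids")
        if self.matrix.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"block {self.name!r}: {self.matrix.shape[1]} columns vs "
                f"{len(self.feature_ids)} feature ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError(f"block {self.name!r}: duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"block {self.name!r}: duplicate sample ids")
        if self.kind == "image":
            if self.image_manifest is None:
                raise ValueError(f"image block {self.name!r} requires a manifest")
            missing = set(self.sample_ids) - set(self.image_manifest)
            if missing:
                raise ValueError(
                    f"image block {self.name!r}: manifest missing {sorted(missing)[:5]}")
            for sid, entry in self.image_manifest.items():
                _, c, h, w = entry
                if h != w:
                    raise ValueError(
                        f"image block {self.name!r}: sample {sid!r} is {h}x{w}; "
                        "only quadratic images are allowed")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def image_shape(self) -> tuple[int, int, int]:
        if self.kind != "image":
            raise ValueError(f"block {self.name!r} is not an image block")
        shapes = {tuple(v[1:]) for v in self.image_manifest.values()}
        if len(shapes) != 1:
            raise ValueError(f"block {self.name!r}: mixed image shapes {shapes}")
        return next(iter(shapes))

    def subset(self, sample_ids: list[str]) -> "ModalityBlock":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        manifest = None
        if self.image_manifest is not None:
            manifest = {s: self.image_manifest[s] for s in sample_ids}
        return ModalityBlock(self.name, self.kind, self.matrix[rows],
                             list(self.feature_ids), list(sample_ids), manifest)


@dataclass
class AnnotationTable:
    """Per-sample annotation columns with declared downstream-task columns."""

    table: pd.DataFrame  # indexed by sample_id
    task_specs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.table.index.has_duplicates:
            raise ValueError("annotation table has duplicate sample ids")
        for column, task in self.task_specs:
            if column not in self.table.columns:
                raise ValueError(f"task column {column!r} not in annotations")
            if task not in ("classification", "regression"):
                raise ValueError(f"unknown task kind {task!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    def subset(self, sample_ids: list[str]) -> "AnnotationTable":
        return AnnotationTable(self.table.loc[sample_ids], list(self.task_specs))


@dataclass
class MultiModalDataset:
    """Aligned modality blocks sharing one canonical sample order."""

    blocks: list[ModalityBlock]
    sample_ids: list[str]
    annotations: AnnotationTable
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("dataset requires at least one block")
        for block in self.blocks:
            if block.sample_ids != self.sample_ids:
                raise ValueError(
                    f"block {block.name!r} sample order does not match dataset")
        if self.annotations.sample_ids != self.sample_ids:
            raise ValueError("annotation sample order does not match dataset")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def block(self, name: str) -> ModalityBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)


@dataclass
class SplitAssignment:
    """train/valid/test membership for every sample of a dataset."""

    assignment: dict[str, str]
    ratios: tuple[float, float, float]
    seed: int

    def __post_init__(self):
        bad = set(self.assignment.values()) - {"train", "valid", "test"}
        if bad:
            raise ValueError(f"unknown split labels {bad}")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")

    def ids(self, part: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == part]

    def counts(self) -> dict[str, int]:
        out = {"train": 0, "valid": 0, "test": 0}
        for part in self.assignment.values():
            out[part] += 1
        return out

    def indices(self, sample_ids: list[str], part: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(sample_ids)
                         if self.assignment[s] == part], dtype=int)


@dataclass
class OntologyMap:
    """Feature→term edges (level 1) and optional term→super-term edges (level 2).

    Term order at each level is the sorted unique term list, so masks built
    from the same edge files are deterministic across runs.
    """

    level1_edges: list[tuple[str, str]]
    level2_edges: Optional[list[tuple[str, str]]] = None

    def __post_init__(self):
        self.level1_edges = sorted(set(map(tuple, self.level1_edges)))
        if self.level2_edges is not None:
            self.level2_edges = sorted(set(map(tuple, self.level2_edges)))
        features = {f for f, _ in self.level1_edges}
        t1 = {t for _, t in self.level1_edges}
        if features & t1:
            raise OntologyError(
                f"level-crossing ids appear as both feature and term: "
                f"{sorted(features & t1)[:5]}")
        if self.level2_edges is not None:
            child = {c for c, _ in self.level2_edges}
            t2 = {t for _, t in self.level2_edges}
            if t2 & (features | t1):
                raise OntologyError("super-term ids collide with lower levels")
            if child - t1:
                raise OntologyError(
                    f"level-2 edges reference unknown level-1 terms: "
                    f"{sorted(child - t1)[:5]}")

    @property
    def features(self) -> list[str]:
        return sorted({f for f, _ in self.level1_edges})

    @property
    def level1_terms(self) -> list[str]:
        return sorted({t for _, t in self.level1_edges})

    @property
    def level2_terms(self) -> list[str]:
        if self.level2_edges is None:
            return []
        return sorted({t for _, t in self.level2_edges})

    @property
    def n_levels(self) -> int:
        return 2 if self.level2_edges else 1

    @property
    def top_terms(self) -> list[str]:
        return self.level2_terms if self.level2_edges else self.level1_terms


# --------------------------------------------------------------------- config

class FilterSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: Literal["variance", "mad", "correlation"] = "variance"
    k: int = Field(gt=0)


class ScalerSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: Literal["standard", "minmax", "robust", "maxabs"] = "standard"


class OntologySpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    level1: str
    level2: Optional[str] = None


class ModalitySpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    path: str
    kind: Literal["numeric", "categorical", "image"] = "numeric"


class DataSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    modalities: dict[str, ModalitySpec] = Field(default_factory=dict)
    annotations: Optional[str] = None
    task_columns: dict[str, Literal["classification", "regression"]] = Field(
        default_factory=dict)


class RunConfig(BaseModel):
    """Every hyperparameter of a pipeline run, with documented defaults."""

    model_config = ConfigDict(extra="forbid")

    architecture: Literal["vanillix", "varix", "stackix", "ontix", "xmodalix"]
    latent_dim: int = Field(gt=0)
    beta_final: float = Field(default=1.0, ge=0)
    anneal_steepness: Optional[float] = Field(default=None, gt=0)  # default 15/epochs
    anneal_midpoint: float = Field(default=0.5, gt=0, lt=1)
    encoding_factor: float = Field(default=4.0, gt=1)
    n_hidden: int = Field(default=2, gt=0)
    dropout: float = Field(default=0.1, ge=0, lt=1)
    learning_rate: float = Field(default=1e-4, gt=0)
    weight_decay: float = Field(default=0.0, ge=0)
    epochs: int = Field(default=100, ge=0)
    batch_size: int = Field(default=64, gt=0)
    pretrain_epochs: int = Field(default=0, ge=0)
    recon_loss: Literal["mse", "bce"] = "mse"
    sim_loss: Literal["kl", "mmd"] = "kl"
    gamma: float = Field(default=0.0, ge=0)
    delta_paired: float = Field(default=0.0, ge=0)
    delta_class: float = Field(default=0.0, ge=0)
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 42
    filter_spec: Optional[FilterSpec] = None
    scaler_spec: ScalerSpec = Field(default_factory=ScalerSpec)
    ontology: Optional[OntologySpec] = None
    channel_base: int = Field(default=32, gt=0)
    data: Optional[DataSpec] = None

    @model_validator(mode="after")
    def _check(self):
        if any(r < 0 for r in self.split_ratios):
            raise ValueError("split ratios must be nonnegative")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if self.architecture == "ontix" and self.ontology is None:
            raise ValueError("architecture 'ontix' requires an ontology section")
        if self.recon_loss == "bce" and self.scaler_spec.method != "minmax":
            raise ValueError("recon_loss 'bce' requires inputs scaled to [0,1] "
                             "(scaler method 'minmax')")
        return self

    def beta_steepness(self) -> float:
        if self.anneal_steepness is not None:
            return self.anneal_steepness
        return 15.0 / max(self.epochs, 1)

    def to_dict(self) -> dict:
        out = self.model_dump(exclude_none=True)
        out["split_ratios"] = list(out["split_ratios"])
        return out


def load_config(path: str) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys and invariant violations raise :class:`ConfigError` naming
    the offending field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            msgs.append(f"{loc}: {err['msg']}")
        raise ConfigError("; ".join(msgs)) from exc


# ------------------------------------------------------------------ alignment

def align_samples(blocks: list[ModalityBlock],
                  annotations: AnnotationTable) -> MultiModalDataset:
    """Restrict all blocks and annotations to their common samples.

    The result is ordered lexicographically by sample id — the canonical
    order used for every downstream tensor. Dropped-sample counts per block
    are logged and stored under ``dataset.meta['dropped']``.
    """
    if not blocks:
        raise AlignmentError("no modality blocks given")
    for block in blocks:
        if block.n_samples == 0:
            raise AlignmentError(f"block {block.name!r} is empty")
    common = set(annotations.sample_ids)
    for block in blocks:
        common &= set(block.sample_ids)
    if not common:
        raise AlignmentError("no samples shared across all blocks and annotations")
    order = sorted(common)
    dropped = {b.name: b.n_samples - len(order) for b in blocks}
    dropped["annotations"] = len(annotations.sample_ids) - len(order)
    for name, n in dropped.items():
        if n:
            logger.info("align_samples: dropped %d samples from %s", n, name)
    return MultiModalDataset(
        blocks=[b.subset(order) for b in blocks],
        sample_ids=order,
        annotations=annotations.subset(order),
        meta={"dropped": dropped},
    )


# ------------------------------------------------------------------- ontology

def validate_ontology(onto: OntologyMap, features: list[str]) -> dict:
    """Cross-check an ontology against a feature list.

    Returns counts of mapped/unmapped features, terms per level, empty terms
    (terms whose features are all absent from ``features``) and overlap
    statistics. Unmapped features are flagged for exclusion from masked runs.
    """
    feature_set = set(features)
    mapped = {f for f, _ in onto.level1_edges if f in feature_set}
    unmapped = sorted(feature_set - mapped)
    term_members: dict[str, set] = {t: set() for t in onto.level1_terms}
    membership_count: dict[str, int] = {}
    for f, t in onto.level1_edges:
        if f in feature_set:
            term_members[t].add(f)
        membership_count[f] = membership_count.get(f, 0) + 1
    empty_terms = sorted(t for t, members in term_members.items() if not members)
    overlapping = sorted(f for f, c in membership_count.items()
                         if c > 1 and f in feature_set)
    report = {
        "n_features": len(feature_set),
        "n_mapped": len(mapped),
        "n_unmapped": len(unmapped),
        "unmapped_features": unmapped,
        "n_level1_terms": len(onto.level1_terms),
        "n_level2_terms": len(onto.level2_terms),
        "empty_terms": empty_terms,
        "overlapping_features": overlapping,
    }
    if unmapped:
        logger.warning("validate_ontology: %d features unmapped and flagged "
                       "for exclusion", len(unmapped))
    return report
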