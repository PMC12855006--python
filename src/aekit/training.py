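"""Loss functions, logistic weight annealing, and optimizer loops.

All architectures minimize a reconstruction term; variational ones add a
β-weighted similarity term whose weight follows a logistic schedule

    β(epoch) = β_final / (1 + exp(-B (epoch - M · total_epochs))).

Validation loss is always reported with the *final* (non-annealed) weights,
and the checkpoint with the best validation total is retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np

from . import nn
from .architectures import (Stackix, XModalixPair, build_stackix,
                            build_vanillix, build_varix)
from .datamodel import MultiModalDataset, RunConfig, SplitAssignment, config_from_dict

logger = logging.getLogger(__name__)

__all__ = [
    "AnnealSchedule", "LossBreakdown", "FitResult", "beta_at",
    "recon_loss", "kl_loss", "mmd_loss", "adversarial_losses",
    "paired_loss", "class_center_loss",
    "fit", "fit_stackix", "fit_xmodalix", "tune",
]


@dataclass
class AnnealSchedule:
    beta_final: float
    steepness: float
    midpoint: float
    total_epochs: int

    @classmethod
    def from_config(cls, config: RunConfig, total_epochs: Optional[int] = None):
        total = config.epochs if total_epochs is None else total_epochs
        steep = (config.anneal_steepness if config.anneal_steepness is not None
                 else 15.0 / max(total, 1))
        return cls(config.beta_final, steep, config.anneal_midpoint, total)


def beta_at(epoch: float, schedule: AnnealSchedule) -> float:
    """Logistic annealing weight at ``epoch``."""
    x = -schedule.steepness * (epoch - schedule.midpoint * schedule.total_epochs)
    return schedule.beta_final / (1.0 + np.exp(np.clip(x, -700, 700)))


def _lift(x) -> nn.Tensor:
    return x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, dtype=np.float64))


def recon_loss(x, x_hat, kind: str = "mse") -> nn.Tensor:
    """Reconstruction loss, mean over batch and features."""
    x, x_hat = _lift(x), _lift(x_hat)
    if kind == "mse":
        return ((x_hat - x) ** 2.0).mean()
    if kind == "bce":
        if np.any(x.data < 0) or np.any(x.data > 1):
            raise ValueError("bce requires targets in [0, 1]")
        p = x_hat.clamp(1e-7, 1 - 1e-7)
        return -(x * p.log() + (1.0 - x) * (1.0 - p).log()).mean()
    raise ValueError(f"unknown reconstruction loss {kind!r}")


def kl_loss(mu, log_var) -> nn.Tensor:
    """KL(q || N(0, I)) = ½ Σ_d (μ² + σ² − 1 − log σ²), batch mean."""
    mu, log_var = _lift(mu), _lift(log_var)
    per_sample = (mu ** 2.0 + log_var.exp() - 1.0 - log_var).sum(axis=-1) * 0.5
    return per_sample.mean() if per_sample.ndim else per_sample


def _pairwise_sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)


def mmd_loss(z, prior) -> nn.Tensor:
    """Unbiased RBF-kernel MMD² between a latent batch and a prior batch.

    Bandwidth by the median heuristic on the pooled pairwise distances;
    clamped at zero.
    """
    z, prior = _lift(z), _lift(prior)
    n, m = z.shape[0], prior.shape[0]
    if n < 2 or m < 2:
        raise ValueError("mmd requires at least 2 points per batch")
    pooled = np.concatenate([z.data, prior.data], axis=0)
    d2 = _pairwise_sq_dists(pooled, pooled)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    bw = max(med, 1e-12)

    def rbf(a: nn.Tensor, b: nn.Tensor) -> nn.Tensor:
        a2 = (a * a).sum(axis=1, keepdims=True)
        b2 = (b * b).sum(axis=1, keepdims=True)
        d = a2 + b2.reshape(1, -1) - 2.0 * (a @ b.transpose((1, 0)))
        return (d * (-1.0 / bw)).exp()

    kzz = rbf(z, z)
    kpp = rbf(prior, prior)
    kzp = rbf(z, prior)
    # diagonals of kzz/kpp are exactly 1 (zero distance)
    term_zz = (kzz.sum() - float(n)) * (1.0 / (n * (n - 1)))
    term_pp = (kpp.sum() - float(m)) * (1.0 / (m * (m - 1)))
    term_zp = kzp.sum() * (2.0 / (n * m))
    out = term_zz + term_pp - term_zp
    return out.clamp(0.0, np.inf)


def adversarial_losses(z_a, z_b, classifier) -> tuple[nn.Tensor, nn.Tensor]:
    """(classifier CE on true modality labels, generator CE on flipped labels).

    The classifier term treats the embeddings as constants; the generator term
    scores the same embeddings against swapped labels so that easily separable
    latent spaces are penalized.
    """
    z_a, z_b = _lift(z_a), _lift(z_b)
    if z_a.shape[0] == 0 or z_b.shape[0] == 0:
        raise ValueError("adversarial loss needs samples from both modalities")
    labels = np.concatenate([np.zeros(z_a.shape[0], dtype=int),
                             np.ones(z_b.shape[0], dtype=int)])
    z_const = nn.Tensor(np.concatenate([z_a.data, z_b.data], axis=0))
    clf_ce = nn.cross_entropy(classifier(z_const), labels)
    z_live = nn.concat([z_a, z_b], axis=0)
    gen_ce = nn.cross_entropy(classifier(z_live), 1 - labels)
    return clf_ce, gen_ce


def paired_loss(z_a, z_b) -> nn.Tensor:
    """Mean absolute deviation across latent dimensions of paired samples."""
    z_a, z_b = _lift(z_a), _lift(z_b)
    if z_a.shape != z_b.shape:
        raise ValueError("paired batches must align sample-for-sample")
    return (z_a - z_b).abs().mean()


def class_center_loss(z, labels) -> nn.Tensor:
    """Mean absolute deviation of each sample from its class center (batch mean)."""
    z = _lift(z)
    labels = np.asarray(labels)
    n = z.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels must match the batch")
    smear = np.zeros((n, n))
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        smear[np.ix_(members, members)] = 1.0 / members.size
    centers = nn.Tensor(smear) @ z
    return (z - centers).abs().mean()


@dataclass
class LossBreakdown:
    epoch: int
    beta: float
    recon: float = 0.0
    similarity: float = 0.0
    adversarial: float = 0.0
    paired: float = 0.0
    class_center: float = 0.0
    gamma: float = 0.0
    delta_paired: float = 0.0
    delta_class: float = 0.0
    total: float = 0.0
    kl_ratio: float = 0.0  # diagnostic: weighted similarity / reconstruction

    def finalize(self) -> "LossBreakdown":
        self.total = (self.recon + self.beta * self.similarity
                      + self.gamma * self.adversarial
                      + self.delta_paired * self.paired
                      + self.delta_class * self.class_center)
        self.kl_ratio = (self.beta * self.similarity / self.recon
                         if self.recon > 0 else 0.0)
        if not np.isfinite(self.total):
            raise RuntimeError(f"non-finite loss at epoch {self.epoch}: {asdict(self)}")
        return self


@dataclass
class FitResult:
    history: list[LossBreakdown]
    best_epoch: int
    best_val: float
    extra: dict = field(default_factory=dict)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _model_losses(model, x: nn.Tensor, config: RunConfig,
                  prior_rng: Optional[np.random.Generator] = None):
    x_hat, mu, log_var, z = model(x)
    rec = recon_loss(x, x_hat, config.recon_loss)
    if not getattr(model, "is_variational", False):
        return rec, None
    if config.sim_loss == "kl":
        sim = kl_loss(mu, log_var)
    else:
        prior = (prior_rng or np.random.default_rng(config.seed)).standard_normal(
            (z.shape[0], z.shape[1]))
        sim = mmd_loss(z, prior)
    return rec, sim


def fit(model, x: np.ndarray, split: SplitAssignment, config: RunConfig,
        sample_ids: Optional[list[str]] = None) -> FitResult:
    """Minibatch training of a single-matrix autoencoder.

    β follows the logistic schedule during training; the per-epoch validation
    breakdown uses the final weights, and the best-validation checkpoint is
    restored into ``model`` on return.
    """
    x = np.asarray(x, dtype=np.float64)
    if sample_ids is None:
        sample_ids = [f"S{i:06d}" for i in range(x.shape[0])]
    idx_train = split.indices(sample_ids, "train")
    idx_valid = split.indices(sample_ids, "valid")
    if idx_train.size == 0:
        raise ValueError("empty training split")
    if idx_valid.size == 0:
        idx_valid = idx_train  # degenerate fallback for tiny runs
    schedule = AnnealSchedule.from_config(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    prior_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    opt = nn.AdamW(model.parameters(), lr=config.learning_rate,
                   weight_decay=config.weight_decay)
    history: list[LossBreakdown] = []
    best_val, best_epoch, best_state = np.inf, -1, model.clone_state()
    for epoch in range(config.epochs):
        beta = beta_at(epoch, schedule)
        model.train()
        for batch in _batches(idx_train.size, config.batch_size, rng):
            xb = nn.Tensor(x[idx_train[batch]])
            rec, sim = _model_losses(model, xb, config, prior_rng)
            loss = rec if sim is None else rec + beta * sim
            opt.zero_grad()
            loss.backward()
            opt.step()
            if hasattr(model, "apply_masks"):
                model.apply_masks()
        entry = _validate(model, x[idx_valid], config, epoch, prior_rng)
        history.append(entry)
        if entry.total < best_val:
            best_val, best_epoch, best_state = entry.total, epoch, model.clone_state()
    if history:
        model.load_state_dict(best_state)
        if hasattr(model, "apply_masks"):
            model.apply_masks()
    return FitResult(history=history, best_epoch=best_epoch,
                     best_val=best_val if history else np.nan)


def _validate(model, x_val: np.ndarray, config: RunConfig, epoch: int,
              prior_rng) -> LossBreakdown:
    model.eval()
    rec, sim = _model_losses(model, nn.Tensor(x_val), config, prior_rng)
    entry = LossBreakdown(epoch=epoch, beta=config.beta_final,
                          recon=float(rec.data),
                          similarity=float(sim.data) if sim is not None else 0.0)
    return entry.finalize()


@dataclass
class StackixFitResult:
    modality_results: list[FitResult]
    top_result: FitResult
    modality_r2: list[float]


def fit_stackix(dataset: MultiModalDataset, config: RunConfig,
                split: Optional[SplitAssignment] = None) -> tuple[Stackix, StackixFitResult]:
    """Two-phase training: per-modality VAEs first, then the top VAE on their
    frozen concatenated embeddings."""
    from .evaluation import reconstruction_r2
    from .preprocess import split_dataset

    if split is None:
        split = split_dataset(dataset.sample_ids, config.split_ratios, config.seed)
    model = build_stackix(dataset, config)
    results = []
    r2s = []
    idx_test = split.indices(dataset.sample_ids, "test")
    for vae, block in zip(model.modality_vaes, dataset.blocks):
        res = fit(vae, block.matrix, split, config, dataset.sample_ids)
        results.append(res)
        test_x = block.matrix[idx_test] if idx_test.size else block.matrix
        r2s.append(reconstruction_r2(test_x, vae.reconstruct(test_x)))
    frozen = [vae.clone_state() for vae in model.modality_vaes]
    embeddings = model.concat_embeddings([b.matrix for b in dataset.blocks])
    top_res = fit(model.top_vae, embeddings, split, config, dataset.sample_ids)
    for vae, state in zip(model.modality_vaes, frozen):  # phase 2 must not touch phase 1
        vae.load_state_dict(state)
    return model, StackixFitResult(modality_results=results, top_result=top_res,
                                   modality_r2=r2s)


def fit_xmodalix(pair: XModalixPair, x_a: np.ndarray, x_b: np.ndarray,
                 split: SplitAssignment, config: RunConfig,
                 sample_ids: Optional[list[str]] = None,
                 pairs: Optional[np.ndarray] = None,
                 labels: Optional[np.ndarray] = None) -> FitResult:
    """Joint cross-modal training with adversarial latent-space alignment.

    ``x_a`` is the numeric modality, ``x_b`` the second modality (images as
    (n, C, H, W)); row i of both arrays belongs to the same index space.
    ``pairs`` lists (i, j) index pairs measured on the same sample (used by
    the paired term); ``labels`` gives shared class labels (used by the
    class-center term). The image VAE is optionally pretrained for
    ``pretrain_epochs`` with its own β annealing before joint training.
    """
    if config.gamma == 0 and config.delta_paired == 0 and config.delta_class == 0:
        warnings.warn("no alignment pressure: gamma, delta_paired and "
                      "delta_class are all zero")
    if config.delta_class > 0 and labels is None:
        raise ValueError("delta_class > 0 requires class labels")
    if config.delta_paired > 0 and (pairs is None or len(pairs) == 0):
        raise ValueError("delta_paired > 0 requires paired sample links")
    x_a = np.asarray(x_a, dtype=np.float64)
    x_b = np.asarray(x_b, dtype=np.float64)
    n = x_a.shape[0]
    if sample_ids is None:
        sample_ids = [f"S{i:06d}" for i in range(n)]
    idx_train = split.indices(sample_ids, "train")
    idx_valid = split.indices(sample_ids, "valid")
    if idx_valid.size == 0:
        idx_valid = idx_train
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    prior_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    pair_map = {int(i): int(j) for i, j in (pairs if pairs is not None else [])}

    history: list[LossBreakdown] = []
    # ---- pretraining of the B-side (image) VAE
    if config.pretrain_epochs > 0:
        pre_sched = AnnealSchedule.from_config(config, config.pretrain_epochs)
        opt_pre = nn.AdamW(pair.vae_b.parameters(), lr=config.learning_rate,
                           weight_decay=config.weight_decay)
        for epoch in range(config.pretrain_epochs):
            beta = beta_at(epoch, pre_sched)
            pair.vae_b.train()
            for batch in _batches(idx_train.size, config.batch_size, rng):
                xb = nn.Tensor(x_b[idx_train[batch]])
                rec, sim = _model_losses(pair.vae_b, xb, config, prior_rng)
                loss = rec + beta * sim
                opt_pre.zero_grad()
                loss.backward()
                opt_pre.step()
            pair.vae_b.eval()
            rec, sim = _model_losses(pair.vae_b, nn.Tensor(x_b[idx_valid]),
                                     config, prior_rng)
            history.append(LossBreakdown(
                epoch=epoch - config.pretrain_epochs, beta=config.beta_final,
                recon=float(rec.data), similarity=float(sim.data)).finalize())

    schedule = AnnealSchedule.from_config(config)
    vae_params = pair.vae_a.parameters() + pair.vae_b.parameters()
    opt_vae = nn.AdamW(vae_params, lr=config.learning_rate,
                       weight_decay=config.weight_decay)
    opt_clf = nn.AdamW(pair.classifier.parameters(), lr=config.learning_rate)
    best_val, best_epoch = np.inf, -1
    best_state = (pair.vae_a.clone_state(), pair.vae_b.clone_state())
    for epoch in range(config.epochs):
        beta = beta_at(epoch, schedule)
        pair.vae_a.train()
        pair.vae_b.train()
        pair.classifier.train()
        for batch in _batches(idx_train.size, config.batch_size, rng):
            ids = idx_train[batch]
            xa = nn.Tensor(x_a[ids])
            xb = nn.Tensor(x_b[ids])
            xa_hat, mu_a, lv_a, z_a = pair.vae_a(xa)
            xb_hat, mu_b, lv_b, z_b = pair.vae_b(xb)
            # 1 classifier step : 1 VAE step
            clf_ce, _ = adversarial_losses(z_a, z_b, pair.classifier)
            opt_clf.zero_grad()
            pair.vae_a.zero_grad()
            pair.vae_b.zero_grad()
            clf_ce.backward()
            opt_clf.step()
            _, gen_ce = adversarial_losses(z_a, z_b, pair.classifier)
            rec_a = recon_loss(xa, xa_hat, "mse")
            rec_b = recon_loss(xb, xb_hat, config.recon_loss)
            sim = kl_loss(mu_a, lv_a) + kl_loss(mu_b, lv_b)
            total = rec_a + rec_b + beta * sim + config.gamma * gen_ce
            if config.delta_paired > 0:
                rows_a = [int(i) for i in ids if int(i) in pair_map]
                if rows_a:
                    rows_b = [pair_map[i] for i in rows_a]
                    za_p = pair.vae_a.encode(nn.Tensor(x_a[rows_a]))
                    zb_p = pair.vae_b.encode(nn.Tensor(x_b[rows_b]))
                    total = total + config.delta_paired * paired_loss(za_p, zb_p)
            if config.delta_class > 0:
                pooled = nn.concat([z_a, z_b], axis=0)
                pooled_labels = np.concatenate([labels[ids], labels[ids]])
                total = total + config.delta_class * class_center_loss(
                    pooled, pooled_labels)
            opt_vae.zero_grad()
            pair.classifier.zero_grad()
            total.backward()
            opt_vae.step()
        entry = _validate_xmodalix(pair, x_a, x_b, idx_valid, config, epoch,
                                   pair_map, labels)
        history.append(entry)
        if entry.total < best_val:
            best_val, best_epoch = entry.total, epoch
            best_state = (pair.vae_a.clone_state(), pair.vae_b.clone_state())
    pair.vae_a.load_state_dict(best_state[0])
    pair.vae_b.load_state_dict(best_state[1])
    return FitResult(history=history, best_epoch=best_epoch, best_val=best_val)


def _validate_xmodalix(pair, x_a, x_b, idx_valid, config, epoch, pair_map,
                       labels) -> LossBreakdown:
    pair.vae_a.eval()
    pair.vae_b.eval()
    pair.classifier.eval()
    xa = nn.Tensor(x_a[idx_valid])
    xb = nn.Tensor(x_b[idx_valid])
    xa_hat, mu_a, lv_a, z_a = pair.vae_a(xa)
    xb_hat, mu_b, lv_b, z_b = pair.vae_b(xb)
    _, gen_ce = adversarial_losses(z_a, z_b, pair.classifier)
    entry = LossBreakdown(
        epoch=epoch, beta=config.beta_final,
        recon=float(recon_loss(xa, xa_hat, "mse").data
                    + recon_loss(xb, xb_hat, config.recon_loss).data),
        similarity=float(kl_loss(mu_a, lv_a).data + kl_loss(mu_b, lv_b).data),
        adversarial=float(gen_ce.data),
        gamma=config.gamma, delta_paired=config.delta_paired,
        delta_class=config.delta_class)
    rows_a = [int(i) for i in idx_valid if int(i) in pair_map]
    if rows_a and config.delta_paired > 0:
        rows_b = [pair_map[i] for i in rows_a]
        entry.paired = float(paired_loss(
            pair.vae_a.embed(x_a[rows_a]), pair.vae_b.embed(x_b[rows_b])).data)
    if labels is not None and config.delta_class > 0:
        pooled = np.concatenate([z_a.data, z_b.data], axis=0)
        pooled_labels = np.concatenate([labels[idx_valid], labels[idx_valid]])
        entry.class_center = float(class_center_loss(pooled, pooled_labels).data)
    return entry.finalize()


DEFAULT_SEARCH_SPACE = {
    "learning_rate": ("log", 1e-5, 1e-2),
    "weight_decay": ("log", 1e-8, 1e-3),
    "dropout": ("uniform", 0.0, 0.5),
    "n_hidden": ("choice", [1, 2, 3]),
}


def tune(x: np.ndarray, split: SplitAssignment, config: RunConfig,
         n_trials: int, search_space: Optional[dict] = None,
         build_fn: Optional[Callable] = None,
         sample_ids: Optional[list[str]] = None) -> tuple[RunConfig, list[dict]]:
    """Seeded random hyperparameter search minimizing validation total loss.

    β is deliberately not part of the searchable space. Returns the best
    configuration and the full trial log (params + objective per trial).
    """
    search_space = search_space or DEFAULT_SEARCH_SPACE
    if "beta_final" in search_space:
        raise ValueError("beta_final is not tunable via loss optimization")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    trials = []
    best = (np.inf, None)
    for trial in range(n_trials):
        params = {}
        for name, spec in search_space.items():
            kind = spec[0]
            if kind == "log":
                params[name] = float(np.exp(rng.uniform(np.log(spec[1]),
                                                        np.log(spec[2]))))
            elif kind == "uniform":
                params[name] = float(rng.uniform(spec[1], spec[2]))
            elif kind == "choice":
                params[name] = spec[1][rng.integers(len(spec[1]))]
            else:
                raise ValueError(f"unknown search-space kind {kind!r}")
        trial_config = config_from_dict({**config.to_dict(), **params})
        if build_fn is not None:
            model = build_fn(trial_config)
        elif config.architecture == "vanillix":
            model = build_vanillix(x.shape[1], trial_config)
        else:
            model = build_varix(x.shape[1], trial_config)
        result = fit(model, x, split, trial_config, sample_ids)
        trials.append({"trial": trial, **params, "objective": result.best_val})
        if result.best_val < best[0]:
            best = (result.best_val, trial_config)
    return best[1], trials
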