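# aekit

A config-driven pipeline for preprocessing multimodal tabular/image data,
training five autoencoder families, and evaluating the resulting embeddings.

Architectures:

- **vanillix** — plain autoencoder with a deterministic bottleneck
- **varix** — β-VAE with a standard-normal prior, logistic β annealing and a
  KL or MMD similarity loss
- **stackix** — hierarchical VAE: per-modality VAEs (latent width
  `max(2, round(k/8))`) trained first, then a top VAE over their concatenated
  embeddings
- **ontix** — variational encoder with an ontology-masked decoder (one or two
  term levels); masked weights are exactly zero throughout training, with an
  optional dense layer when the latent width is below the number of top-level
  terms
- **xmodalix** — cross-modal pair (numeric VAE + 5-layer convolutional image
  VAE) aligned by an adversarial latent classifier plus paired and
  class-center losses, enabling modality translation

Evaluation metrics: per-sample reconstruction R², grid-based latent coverage,
Gaussian total correlation, downstream ML tasks (linear/SVM/random forest)
Z-scored against random-feature baselines, repetition robustness
(mean |Pearson r| per latent dimension), and PCA/UMAP baselines.

The neural-network backend (`aekit.nn`) is a small, gradient-checked NumPy
reverse-mode autodiff engine (linear, masked-linear, batch-norm, dropout,
conv/transposed-conv layers, AdamW), so the package has no deep-learning
framework dependency.

## CLI

Every stage is driven by a YAML config (see `aekit.datamodel.RunConfig` for
the schema; unknown keys are errors). Generate a self-contained synthetic run
directory and execute the full pipeline:

```bash
aekit make-fixtures --outdir demo --n-samples 120 --seed 0
aekit run-all --config demo/config.yaml --outdir demo/out
```

Stages can also run individually (`preprocess`, `train`, `evaluate`,
`visualize`, `tune`), each with `--config`, `--outdir` and an optional
`--seed` override. `run-all` resumes from the manifest (`manifest.json`) and
skips completed stages while the config hash is unchanged. Outputs are TSV
matrices/latents/loss histories, JSON metrics, and PNG figures.

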