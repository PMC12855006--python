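import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aekit import nn
from aekit.architectures import (LatentClassifier, build_vanillix, build_varix,
                                 build_xmodalix)
from aekit.datamodel import config_from_dict
from aekit.preprocess import split_dataset
from aekit.training import (AnnealSchedule, adversarial_losses, beta_at,
                            class_center_loss, fit, fit_stackix, fit_xmodalix,
                            kl_loss, mmd_loss, paired_loss, recon_loss, tune)


def make_config(**overrides):
    base = {"architecture": "varix", "latent_dim": 2, "epochs": 5,
            "batch_size": 16, "learning_rate": 1e-3, "beta_final": 0.01,
            "seed": 0}
    base.update(overrides)
    return config_from_dict(base)


class TestBetaSchedule:
    def test_midpoint_is_half(self):
        s = AnnealSchedule(beta_final=2.0, steepness=0.3, midpoint=0.4,
                           total_epochs=100)
        np.testing.assert_allclose(beta_at(40, s), 1.0)

    def test_zero_final_is_zero_everywhere(self):
        s = AnnealSchedule(0.0, 1.0, 0.5, 100)
        assert all(beta_at(e, s) == 0.0 for e in range(0, 101, 10))

    def test_step_limit_for_large_steepness(self):
        s = AnnealSchedule(1.0, 1e6, 0.5, 100)
        np.testing.assert_allclose(beta_at(51, s), 1.0)
        np.testing.assert_allclose(beta_at(49, s), 0.0, atol=1e-12)

    @given(steep=st.floats(0.01, 10), mid=st.floats(0.1, 0.9),
           total=st.integers(10, 1000))
    @settings(max_examples=50, deadline=None)
    def test_nondecreasing(self, steep, mid, total):
        s = AnnealSchedule(1.0, steep, mid, total)
        vals = [beta_at(e, s) for e in range(0, total + 1, max(total // 20, 1))]
        assert all(a <= b + 1e-15 for a, b in zip(vals, vals[1:]))

    def test_start_negligible_when_bmt_large(self):
        total = 100
        s = AnnealSchedule(1.0, 15.0 / total, 0.5, total)  # B*M*T = 7.5 > 5
        assert beta_at(0, s) < 0.01 * s.beta_final


class TestReconLoss:
    def test_perfect_is_zero(self):
        assert float(recon_loss([[1.0, 2.0]], [[1.0, 2.0]], "mse").data) == 0.0

    def test_mse_example(self):
        out = recon_loss([[0.0, 1.0]], [[0.5, 0.5]], "mse")
        np.testing.assert_allclose(float(out.data), 0.25)

    def test_bce_at_targets_near_zero(self):
        out = recon_loss([[0.0, 1.0]], [[0.0, 1.0]], "bce")
        assert 0 <= float(out.data) < 1e-5

    def test_bce_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            recon_loss([[2.0]], [[0.5]], "bce")


class TestKLLoss:
    def test_prior_is_zero(self):
        assert float(kl_loss([[0.0]], [[0.0]]).data) == 0.0

    def test_unit_mean(self):
        np.testing.assert_allclose(float(kl_loss([[1.0]], [[0.0]]).data), 0.5)

    def test_variance_e(self):
        out = float(kl_loss([[0.0]], [[1.0]]).data)
        np.testing.assert_allclose(out, 0.5 * (np.e - 2.0), atol=1e-12)

    @given(mu=st.floats(-3, 3), logvar=st.floats(-3, 3))
    @settings(max_examples=100, deadline=None)
    def test_nonnegative_zero_iff_prior(self, mu, logvar):
        val = float(kl_loss([[mu]], [[logvar]]).data)
        assert val >= -1e-12
        if abs(mu) > 1e-3 or abs(logvar) > 1e-3:
            assert val > 0


def mmd_oracle(z, prior, bw):
    """Direct unbiased-estimator arithmetic, independent of the autograd path."""
    def k(a, b):
        return np.exp(-((a[:, None, :] - b[None, :, :]) ** 2).sum(-1) / bw)
    n, m = len(z), len(prior)
    kzz, kpp, kzp = k(z, z), k(prior, prior), k(z, prior)
    return ((kzz.sum() - np.trace(kzz)) / (n * (n - 1))
            + (kpp.sum() - np.trace(kpp)) / (m * (m - 1))
            - 2 * kzp.mean())


class TestMMDLoss:
    def test_identical_batches_zero(self, rng):
        z = rng.standard_normal((20, 3))
        assert float(mmd_loss(z, z.copy()).data) <= 1e-10

    def test_shuffled_batch_small(self, rng):
        z = rng.standard_normal((40, 2))
        val = float(mmd_loss(z, z[rng.permutation(40)]).data)
        assert val < 0.05

    def test_separated_point_masses_match_oracle(self):
        z = np.array([[0.0], [0.0]])
        prior = np.array([[10.0], [10.0]])
        pooled = np.vstack([z, prior])
        d2 = ((pooled[:, None] - pooled[None]) ** 2).sum(-1)
        bw = np.median(d2[np.triu_indices(4, k=1)])
        expected = mmd_oracle(z, prior, bw)
        np.testing.assert_allclose(float(mmd_loss(z, prior).data), expected,
                                   atol=1e-12)
        assert expected > 0.5


class TestAdversarialLosses:
    def test_chance_classifier_gives_ln2(self, rng):
        clf = LatentClassifier(2, rng)
        for p in clf.parameters():
            p.data[:] = 0.0  # uniform logits -> p = 0.5 for both classes
        z = rng.standard_normal((8, 2))
        clf_ce, gen_ce = adversarial_losses(z[:4], z[4:], clf)
        np.testing.assert_allclose(float(clf_ce.data), np.log(2))
        np.testing.assert_allclose(float(gen_ce.data), np.log(2))

    def test_confident_classifier_large_generator_loss(self, rng):
        clf = LatentClassifier(1, rng)
        z_a = np.full((6, 1), -5.0)
        z_b = np.full((6, 1), 5.0)
        opt = nn.AdamW(clf.parameters(), lr=1e-2)
        for _ in range(300):
            ce, _ = adversarial_losses(z_a, z_b, clf)
            opt.zero_grad()
            ce.backward()
            opt.step()
        clf_ce, gen_ce = adversarial_losses(z_a, z_b, clf)
        assert float(clf_ce.data) < 0.1
        assert float(gen_ce.data) > 1.0

    def test_single_modality_errors(self, rng):
        clf = LatentClassifier(2, rng)
        with pytest.raises(ValueError):
            adversarial_losses(np.zeros((0, 2)), np.zeros((3, 2)), clf)

    def test_classifier_step_treats_embeddings_as_constants(self, rng):
        clf = LatentClassifier(2, rng)
        z_a = nn.Tensor(rng.standard_normal((4, 2)), requires_grad=True)
        z_b = nn.Tensor(rng.standard_normal((4, 2)), requires_grad=True)
        clf_ce, _ = adversarial_losses(z_a, z_b, clf)
        clf_ce.backward()
        assert z_a.grad is None and z_b.grad is None


class TestPairedLoss:
    def test_identical_zero(self):
        assert float(paired_loss([[1.0, 2.0]], [[1.0, 2.0]]).data) == 0.0

    def test_example(self):
        np.testing.assert_allclose(
            float(paired_loss([[0.0, 0.0]], [[1.0, 3.0]]).data), 2.0)

    def test_symmetric(self, rng):
        a, b = rng.standard_normal((5, 3)), rng.standard_normal((5, 3))
        np.testing.assert_allclose(float(paired_loss(a, b).data),
                                   float(paired_loss(b, a).data))


class TestClassCenterLoss:
    def test_identical_members_zero(self):
        z = np.array([[1.0, 2.0], [1.0, 2.0]])
        assert float(class_center_loss(z, ["a", "a"]).data) == 0.0

    def test_two_member_example(self):
        z = np.array([[0.0], [2.0]])
        np.testing.assert_allclose(float(class_center_loss(z, ["a", "a"]).data),
                                   1.0)

    def test_singletons_zero(self, rng):
        z = rng.standard_normal((3, 2))
        assert float(class_center_loss(z, ["a", "b", "c"]).data) == 0.0


class TestFit:
    def test_rank_matching_vanillix_reconstructs(self, rng):
        w = rng.standard_normal((2, 20))
        x = rng.standard_normal((80, 2)) @ w
        cfg = make_config(architecture="vanillix", epochs=200, batch_size=32,
                          learning_rate=1e-2, dropout=0.0)
        split = split_dataset([f"S{i:06d}" for i in range(80)], (0.6, 0.2, 0.2), 0)
        model = build_vanillix(20, cfg)
        result = fit(model, x, split, cfg)
        assert result.history[-1].recon < 0.15 * x.var()

    def test_best_checkpoint_restored(self, rng):
        x = rng.standard_normal((40, 10))
        cfg = make_config(epochs=8)
        split = split_dataset([f"S{i:06d}" for i in range(40)], (0.6, 0.2, 0.2), 0)
        model = build_varix(10, cfg)
        result = fit(model, x, split, cfg)
        best = min(h.total for h in result.history)
        np.testing.assert_allclose(result.best_val, best)

    def test_seed_reproducible_history(self, rng):
        x = rng.standard_normal((40, 10))
        cfg = make_config(epochs=4)
        split = split_dataset([f"S{i:06d}" for i in range(40)], (0.6, 0.2, 0.2), 0)
        h1 = fit(build_varix(10, cfg), x, split, cfg).history
        h2 = fit(build_varix(10, cfg), x, split, cfg).history
        assert [h.total for h in h1] == [h.total for h in h2]

    def test_beta_zero_varix_loss_is_pure_reconstruction(self, rng):
        x = rng.standard_normal((40, 10))
        cfg = make_config(epochs=3, beta_final=0.0)
        split = split_dataset([f"S{i:06d}" for i in range(40)], (0.6, 0.2, 0.2), 0)
        result = fit(build_varix(10, cfg), x, split, cfg)
        for h in result.history:
            assert h.total == h.recon

    def test_validation_uses_final_weights_not_annealed(self, rng):
        x = rng.standard_normal((40, 10))
        cfg = make_config(epochs=3, beta_final=0.5)
        split = split_dataset([f"S{i:06d}" for i in range(40)], (0.6, 0.2, 0.2), 0)
        result = fit(build_varix(10, cfg), x, split, cfg)
        for h in result.history:
            assert h.beta == 0.5  # final weight, though annealed beta(0) ~ 0
            np.testing.assert_allclose(h.total, h.recon + 0.5 * h.similarity)


class TestFitStackix:
    def test_two_phase_freezes_modality_vaes(self, factor_dataset):
        _, dataset, _ = factor_dataset
        cfg = make_config(architecture="stackix", epochs=3)
        model, result = fit_stackix(dataset, cfg)
        assert len(result.modality_results) == 2
        assert len(result.modality_r2) == 2
        before = [vae.clone_state() for vae in model.modality_vaes]
        # retrain top on the same frozen embeddings; phase-1 weights unchanged
        emb = model.concat_embeddings([b.matrix for b in dataset.blocks])
        assert emb.shape[1] == model.stack_plan.top_input_dim
        for vae, state in zip(model.modality_vaes, before):
            for a, b in zip(vae.state_dict(), state):
                np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def trained_pair():
    rng = np.random.default_rng(0)
    n = 48
    factors = rng.standard_normal((n, 2))
    x_a = factors @ rng.standard_normal((2, 16))
    x_b = np.clip(factors @ rng.standard_normal((2, 8)) * 0.3 + 0.5, 0, 1)
    cfg = make_config(architecture="xmodalix", epochs=4, pretrain_epochs=2,
                      gamma=0.1, delta_paired=1.0, batch_size=16)
    from aekit.architectures import (LatentClassifier, Varix, XModalixPair,
                                     build_hidden_dims)
    mrng = np.random.default_rng(1)
    pair = XModalixPair(
        vae_a=Varix(16, 2, build_hidden_dims(16, 4, 2, 2), 0.1, mrng),
        vae_b=Varix(8, 2, build_hidden_dims(8, 4, 2, 2), 0.1, mrng),
        classifier=LatentClassifier(2, mrng))
    split = split_dataset([f"S{i:06d}" for i in range(n)], (0.6, 0.2, 0.2), 0)
    pairs = np.stack([np.arange(n), np.arange(n)], axis=1)
    result = fit_xmodalix(pair, x_a, x_b, split, cfg, pairs=pairs)
    return pair, result, cfg


class TestFitXmodalix:
    def test_history_includes_pretraining(self, trained_pair):
        _, result, cfg = trained_pair
        assert len(result.history) == cfg.pretrain_epochs + cfg.epochs
        assert result.history[0].epoch < 0  # pretraining epochs are negative

    def test_paired_loss_decreases(self, trained_pair):
        _, result, _ = trained_pair
        joint = [h for h in result.history if h.epoch >= 0]
        assert joint[-1].paired < joint[0].paired

    def test_no_alignment_pressure_warns(self, rng):
        cfg = make_config(architecture="xmodalix", epochs=1, gamma=0.0)
        pair_cfg = make_config(architecture="xmodalix", channel_base=2)
        pair = build_xmodalix(6, (1, 64, 64), pair_cfg)
        split = split_dataset([f"S{i:06d}" for i in range(8)], (0.5, 0.25, 0.25), 0)
        with pytest.warns(UserWarning, match="alignment"):
            fit_xmodalix(pair, rng.standard_normal((8, 6)),
                         rng.random((8, 1, 64, 64)), split, cfg)


@pytest.fixture(scope="module")
def tune_setup():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((40, 2)) @ rng.standard_normal((2, 10))
    split = split_dataset([f"S{i:06d}" for i in range(40)], (0.6, 0.2, 0.2), 0)
    return x, split


class TestTune:
    def test_single_trial_returned(self, tune_setup):
        x, split = tune_setup
        best, trials = tune(x, split, make_config(epochs=2), 1)
        assert len(trials) == 1
        assert best is not None

    def test_best_not_worse_than_any_trial(self, tune_setup):
        x, split = tune_setup
        best, trials = tune(x, split, make_config(epochs=2), 4)
        objectives = [t["objective"] for t in trials]
        assert min(objectives) == pytest.approx(
            fit(build_varix(10, best), x, split, best).best_val, rel=0.5)

    def test_seeded_reproducible(self, tune_setup):
        x, split = tune_setup
        _, t1 = tune(x, split, make_config(epochs=2), 3)
        _, t2 = tune(x, split, make_config(epochs=2), 3)
        assert t1 == t2

    def test_beta_not_searchable(self, tune_setup):
        x, split = tune_setup
        with pytest.raises(ValueError, match="beta"):
            tune(x, split, make_config(epochs=1), 1,
                 search_space={"beta_final": ("uniform", 0, 1)})
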