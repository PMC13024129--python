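"""VAE-SQI: pre-screen indicators, loss closed forms, the beta warm-up,
weighted fusion, adaptive thresholding, screening guards and evaluation."""

import numpy as np
import pytest

from radarbp import nn
from radarbp.data import WindowDataset
from radarbp.dsp import standardize
from radarbp.nn.autodiff import Tensor
from radarbp.sqi import (LeakageError, SQIScorer, SQIWeights, VAE, VAEConfig,
                         adaptive_threshold, beta_schedule, evaluate_sqi,
                         fit_vae, fuse_sqi, prescreen_score, screen_dataset,
                         vae_loss)


def _pulse_train(f=1.2, n=1000, fs=100.0, seed=0, noise=0.01):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * f * t) + 0.3 * np.sin(4 * np.pi * f * t + 0.8)
    return standardize(x + noise * rng.standard_normal(n))


class TestPrescreen:
    def test_clean_pulse_scores_high(self):
        b = prescreen_score(_pulse_train())
        assert b.hr_band_ratio >= 0.9
        assert b.interval_regularity >= 0.9
        assert b.s_p > 0.7

    def test_white_noise_low_periodicity(self):
        rng = np.random.default_rng(1)
        vals = [prescreen_score(standardize(rng.standard_normal(1000)))
                .periodicity_strength for _ in range(50)]
        assert np.mean(vals) <= 0.2

    def test_constant_window_scores_zero(self):
        assert prescreen_score(np.full(1000, 3.0)).s_p == 0.0

    def test_all_indicators_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            arr = prescreen_score(standardize(rng.standard_normal(1000))).as_array()
            assert np.all(arr >= 0) and np.all(arr <= 1)


class TestVAELoss:
    def test_perfect_reconstruction_standard_latent_zero_loss(self):
        x = Tensor(np.random.default_rng(0).standard_normal((2, 1, 100)))
        mu = Tensor(np.zeros((2, 64)))
        logvar = Tensor(np.zeros((2, 64)))
        total, rec, kl = vae_loss(x, x, mu, logvar, beta=1.0)
        assert total.item() == pytest.approx(0.0)

    def test_unit_mean_latent_closed_form_kl(self):
        # mu = 1 in all 64 dims, logvar = 0 -> KL = 0.5 * 64 = 32
        x = Tensor(np.zeros((3, 1, 50)))
        mu = Tensor(np.ones((3, 64)))
        logvar = Tensor(np.zeros((3, 64)))
        total, rec, kl = vae_loss(x, x, mu, logvar, beta=1.0)
        assert kl.item() == pytest.approx(32.0)
        assert total.item() == pytest.approx(32.0)

    def test_beta_zero_ignores_latent(self):
        rng = np.random.default_rng(1)
        x = Tensor(rng.standard_normal((2, 1, 80)))
        x_hat = Tensor(rng.standard_normal((2, 1, 80)))
        mu = Tensor(rng.standard_normal((2, 16)) * 10)
        logvar = Tensor(rng.standard_normal((2, 16)))
        total, rec, _ = vae_loss(x, x_hat, mu, logvar, beta=0.0)
        assert total.item() == pytest.approx(rec.item())

    def test_rec_uses_per_window_length_scaling(self):
        x = Tensor(np.zeros((1, 1, 200)))
        x_hat = Tensor(np.ones((1, 1, 200)))
        _, rec, _ = vae_loss(x, x_hat, Tensor(np.zeros((1, 4))),
                             Tensor(np.zeros((1, 4))), 0.0)
        assert rec.item() == pytest.approx(1.0)  # ||1||^2 / L = 200/200


class TestBetaSchedule:
    def test_warmup_endpoints(self):
        assert beta_schedule(1) == pytest.approx(0.01)
        assert beta_schedule(30) == pytest.approx(0.5)
        assert beta_schedule(100) == pytest.approx(0.5)

    def test_linear_in_between(self):
        mid = beta_schedule(15)
        assert 0.01 < mid < 0.5
        diffs = np.diff([beta_schedule(e) for e in range(1, 31)])
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-12)


class TestVAEArchitecture:
    def test_full_config_stage_widths(self):
        cfg = VAEConfig()
        assert cfg.channels == (32, 64, 128, 256)
        assert cfg.latent_dim == 64
        assert cfg.kernel == 7

    def test_decoder_restores_input_length(self):
        vae = VAE(VAEConfig.tiny(1000), rng_seed=0)
        x_hat, mu, logvar = vae(Tensor(np.random.default_rng(0)
                                       .standard_normal((2, 1, 1000))))
        assert x_hat.shape == (2, 1, 1000)
        assert mu.shape == (2, 16)

    def test_full_profile_builds_and_runs(self):
        # full-size encoder/decoder (32/64/128/256 channels, latent 64)
        vae = VAE(VAEConfig(input_len=1000), rng_seed=2)
        x_hat, mu, logvar = vae(Tensor(np.zeros((1, 1, 1000))))
        assert x_hat.shape == (1, 1, 1000)
        assert mu.shape == (1, 64) and logvar.shape == (1, 64)

    def test_final_tanh_bounds_output(self):
        vae = VAE(VAEConfig.tiny(500), rng_seed=1)
        x_hat, *_ = vae(Tensor(np.random.default_rng(1)
                               .standard_normal((2, 1, 500)) * 10))
        assert np.all(np.abs(x_hat.data) <= 1.0)


class TestFitVAE:
    def test_top35_selection_and_history(self):
        rng = np.random.default_rng(3)
        segs = np.stack([_pulse_train(seed=i, n=256) for i in range(20)])
        pres = rng.uniform(0, 1, 20)
        model, hist = fit_vae(segs, pres, VAEConfig.tiny(256), rng_seed=0,
                              stage1_epochs=3, stage2_epochs=2, batch_size=8)
        assert len(hist["stage1_indices"]) == 7  # round(0.35 * 20)
        assert set(hist["stage1_indices"]) == set(np.argsort(pres)[::-1][:7])
        assert hist["beta"][0] == pytest.approx(0.01)
        assert len(hist["loss"]) == 5
        assert hist["stage"] == [1, 1, 1, 2, 2]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_vae(np.zeros((0, 100)), np.zeros(0))


class TestFusion:
    def test_unit_components_fuse_to_one(self):
        assert fuse_sqi(np.ones((1, 4)))[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("onehot,expected", [
        ([1, 0, 0, 0], 0.35), ([0, 1, 0, 0], 0.15),
        ([0, 0, 1, 0], 0.30), ([0, 0, 0, 1], 0.20),
    ])
    def test_single_component_recovers_weight(self, onehot, expected):
        assert fuse_sqi(np.array([onehot], dtype=float))[0] \
            == pytest.approx(expected)

    def test_weights_validate(self):
        with pytest.raises(ValueError):
            SQIWeights(w_r=0.9, w_l=0.15, w_m=0.3, w_p=0.2)


class TestAdaptiveThreshold:
    def test_uniform_scores_retain_80(self):
        scores = np.arange(1.0, 101.0)
        tau = adaptive_threshold(scores, 0.8)
        assert (scores >= tau).sum() == 80

    def test_all_equal_all_pass(self):
        scores = np.full(50, 0.7)
        tau = adaptive_threshold(scores, 0.8)
        assert (scores >= tau).sum() == 50

    def test_retain_everything(self):
        scores = np.random.default_rng(0).uniform(0, 1, 30)
        tau = adaptive_threshold(scores, 1.0)
        assert tau == pytest.approx(scores.min())
        assert (scores >= tau).sum() == 30


class TestEvaluateSQI:
    def test_perfect_separation(self):
        scores = np.concatenate([np.zeros(50), np.ones(50)])
        labels = np.concatenate([np.zeros(50), np.ones(50)])
        ev = evaluate_sqi(scores, labels)
        assert ev.roc_auc == pytest.approx(1.0)
        assert ev.f1_at_best_threshold == pytest.approx(1.0)

    def test_independent_scores_near_chance(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(0, 1, 1000)
        labels = rng.integers(0, 2, 1000)
        assert abs(evaluate_sqi(scores, labels).roc_auc - 0.5) <= 0.05

    def test_reversal_antisymmetry(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 1, 200)
        labels = (scores + rng.normal(0, 0.3, 200) > 0.5).astype(int)
        a = evaluate_sqi(scores, labels).roc_auc
        b = evaluate_sqi(-scores, labels).roc_auc
        assert b == pytest.approx(1.0 - a)


class TestScreeningGuards:
    def _toy_splits(self):
        rng = np.random.default_rng(6)
        def ds(subjects, split):
            n = 10 * len(subjects)
            return WindowDataset(
                rpw=rng.standard_normal((n, 128)),
                abp=rng.standard_normal((n, 128)),
                sbp=rng.uniform(100, 160, n), dbp=rng.uniform(60, 95, n),
                subject=np.repeat(subjects, 10), corrupt=np.zeros(n, np.uint8),
                split=split)
        return ds([0, 1, 2], "train"), ds([3], "val"), ds([4], "test")

    def _fit_scorer(self, train):
        scorer = SQIScorer(VAEConfig.tiny(128))
        scorer.fit(train, rng_seed=0, stage1_epochs=1, stage2_epochs=1,
                   batch_size=16)
        return scorer

    def test_retention_counts_and_weight_normalization(self):
        train, val, test = self._toy_splits()
        scorer = self._fit_scorer(train)
        splits, reports = screen_dataset(
            {"train": train, "val": val, "test": test}, scorer, 0.8)
        assert len(splits["train"]) >= int(np.ceil(0.8 * len(train)))
        assert np.mean(reports["train"].weight) == pytest.approx(1.0, abs=1e-6)

    def test_leakage_guard_trips_on_subject_overlap(self):
        train, val, test = self._toy_splits()
        scorer = self._fit_scorer(train)
        with pytest.raises(LeakageError):
            screen_dataset({"train": train, "val": train, "test": test},
                           scorer, 0.8)

    def test_unfitted_scorer_rejected(self):
        train, val, test = self._toy_splits()
        with pytest.raises(ValueError):
            SQIScorer(VAEConfig.tiny(128)).score(train)
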