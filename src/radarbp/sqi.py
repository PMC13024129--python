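"""Unsupervised VAE-based signal-quality index (VAE-SQI) for pulse windows.

A heuristic pre-screen scores each standardized window on six physiology /
statistics indicators (periodicity, heart-band energy, spike suppression,
drift, inter-peak regularity, high-frequency noise).  A 1-D convolutional
VAE is then trained in two stages — first on the top 35% of windows ranked
by the pre-screen score, then fine-tuned on all windows at a much smaller
learning rate — with the KL weight beta warmed up linearly from 0.01 to 0.5
over the first 30 epochs.

After training, each window receives four component scores:

====================  ==========================================  ======
component             based on                                    weight
====================  ==========================================  ======
reconstruction S_R    error e_i = ||x~ - x^||^2 / L               0.35
latent S_L            distance of the latent mean to the
                      high-quality centre                          0.15
morphology S_M        peak count, peak preservation, smoothness    0.30
physiological S_P     the pre-screen score                         0.20
====================  ==========================================  ======

fused as S_i = w_R S_R + w_L S_L + w_M S_M + w_P S_P, thresholded so that a
fixed fraction (default 80%) of windows is retained, and exported as sample
weights (mean 1 over retained training windows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score

from . import nn
from .data import WindowDataset
from .dsp import standardize

__all__ = [
    "PrescreenBreakdown", "prescreen_score", "SQIWeights", "VAEConfig", "VAE",
    "vae_loss", "beta_schedule", "fit_vae", "component_scores", "fuse_sqi",
    "adaptive_threshold", "SQIScorer", "SQIReport", "evaluate_sqi", "LeakageError",
]


class LeakageError(RuntimeError):
    """Raised when quality screening would leak across split boundaries."""


# ---------------------------------------------------------------------------
# heuristic pre-screening
# ---------------------------------------------------------------------------

@dataclass
class PrescreenBreakdown:
    periodicity_strength: float
    hr_band_ratio: float
    spike_score: float
    drift_score: float
    interval_regularity: float
    hf_noise_score: float

    @property
    def s_p(self) -> float:
        vals = (self.periodicity_strength, self.hr_band_ratio, self.spike_score,
                self.drift_score, self.interval_regularity, self.hf_noise_score)
        return float(np.mean(vals))

    def as_array(self) -> np.ndarray:
        return np.array([self.periodicity_strength, self.hr_band_ratio,
                         self.spike_score, self.drift_score,
                         self.interval_regularity, self.hf_noise_score])


def _band_energy_fraction(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    freqs, psd = sps.periodogram(x, fs=fs)
    total = psd.sum()
    if total <= 0:
        return 0.0
    band = (freqs >= lo) & (freqs <= hi)
    return float(psd[band].sum() / total)


def prescreen_score(window: np.ndarray, fs: float = 100.0) -> PrescreenBreakdown:
    """Six [0, 1] indicators of pulse-wave plausibility; all zero for a
    constant window.  The fused score ``s_p`` is their unweighted mean."""
    x = np.asarray(window, dtype=np.float64)
    if x.std() < 1e-12:
        return PrescreenBreakdown(0, 0, 0, 0, 0, 0)
    xs = (x - x.mean()) / x.std()
    n = len(xs)

    # autocorrelation-based periodicity in the plausible beat-lag window
    lags = np.arange(int(0.33 * fs), min(int(1.5 * fs) + 1, n - 1))
    ac = np.correlate(xs, xs, mode="full")[n - 1:] / n
    periodicity = float(np.clip(np.max(ac[lags]) / (ac[0] + 1e-12), 0.0, 1.0))

    hr_band = float(np.clip(_band_energy_fraction(xs, fs, 0.8, 3.0), 0.0, 1.0))

    d = np.diff(xs)
    mad = np.median(np.abs(d - np.median(d))) * 1.4826 + 1e-12
    z = (d - np.median(d)) / mad
    spike = float(np.clip(1.0 - 20.0 * np.mean(np.abs(z) > 6.0), 0.0, 1.0))

    drift = float(np.clip(1.0 - _band_energy_fraction(xs, fs, 0.0, 0.4), 0.0, 1.0))

    peaks, _ = sps.find_peaks(xs, distance=int(0.33 * fs), prominence=0.3)
    if len(peaks) >= 3:
        intervals = np.diff(peaks)
        cv = intervals.std() / (intervals.mean() + 1e-12)
        regularity = float(np.clip(1.0 - min(1.0, cv), 0.0, 1.0))
    else:
        regularity = 0.0

    hf = float(np.clip(1.0 - _band_energy_fraction(xs, fs, 10.0, fs / 2), 0.0, 1.0))
    return PrescreenBreakdown(periodicity, hr_band, spike, drift, regularity, hf)


def prescreen_scores(windows: np.ndarray, fs: float = 100.0) -> np.ndarray:
    return np.array([prescreen_score(w, fs).s_p for w in windows])


# ---------------------------------------------------------------------------
# the 1-D convolutional VAE
# ---------------------------------------------------------------------------

@dataclass
class SQIWeights:
    w_r: float = 0.35
    w_l: float = 0.15
    w_m: float = 0.30
    w_p: float = 0.20

    def __post_init__(self):
        vals = (self.w_r, self.w_l, self.w_m, self.w_p)
        if any(v < 0 for v in vals) or abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_r, self.w_l, self.w_m, self.w_p])


@dataclass
class VAEConfig:
    """Encoder: four Conv1d(kernel 7, stride 2) stages with batch-norm,
    LeakyReLU(0.2) and one residual block each; mirrored transposed-conv
    decoder with a final Tanh.  Defaults follow the full-size architecture;
    ``tiny()`` is a width-reduced profile for CPU-budget runs."""

    input_len: int = 1000
    channels: tuple[int, ...] = (32, 64, 128, 256)
    latent_dim: int = 64
    kernel: int = 7
    leaky_slope: float = 0.2

    @classmethod
    def tiny(cls, input_len: int = 1000) -> "VAEConfig":
        return cls(input_len=input_len, channels=(8, 16, 32, 64), latent_dim=16)


class _ResBlock1d(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv1d(channels, channels, 3, rng, padding=1)
        self.bn1 = nn.BatchNorm1d(channels)
        self.conv2 = nn.Conv1d(channels, channels, 3, rng, padding=1)
        self.bn2 = nn.BatchNorm1d(channels)

    def forward(self, x):
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        return (h + x).relu()


class VAE(nn.Module):
    """1-D variational autoencoder over standardized pulse windows."""

    def __init__(self, config: VAEConfig, rng_seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(rng_seed)
        k = config.kernel
        pad = k // 2
        chans = (1,) + tuple(config.channels)
        lengths = [config.input_len]
        enc = []
        for cin, cout in zip(chans[:-1], chans[1:]):
            enc.append(nn.Sequential(
                nn.Conv1d(cin, cout, k, rng, stride=2, padding=pad),
                nn.BatchNorm1d(cout), nn.LeakyReLU(config.leaky_slope),
                _ResBlock1d(cout, rng)))
            lengths.append((lengths[-1] + 2 * pad - k) // 2 + 1)
        self.encoder_stages = enc
        self.enc_lengths = lengths
        flat = config.channels[-1] * lengths[-1]
        self.fc_mu = nn.Linear(flat, config.latent_dim, rng)
        self.fc_logvar = nn.Linear(flat, config.latent_dim, rng)
        self.fc_dec = nn.Linear(config.latent_dim, flat, rng)
        dec = []
        rev = chans[::-1]          # (C4, C3, C2, C1, 1)
        targets = lengths[::-1]    # deepest ... input_len
        for i, (cin, cout) in enumerate(zip(rev[:-1], rev[1:])):
            out_pad = targets[i + 1] - (2 * targets[i] - 1)
            layers: list[nn.Module] = [nn.ConvTranspose1d(
                cin, cout, k, rng, stride=2, padding=pad, output_padding=out_pad)]
            if cout != 1:
                layers += [nn.BatchNorm1d(cout), nn.LeakyReLU(config.leaky_slope),
                           _ResBlock1d(cout, rng)]
            else:
                layers.append(nn.Tanh())
            dec.append(nn.Sequential(*layers))
        self.decoder_stages = dec
        self._sample_rng = np.random.default_rng(rng_seed + 1)

    # ------------------------------------------------------------------
    def encode(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        h = x
        for stage in self.encoder_stages:
            h = stage(h)
        flat = h.reshape(h.shape[0], -1)
        return self.fc_mu(flat), self.fc_logvar(flat)

    def decode(self, z: nn.Tensor) -> nn.Tensor:
        c_last = self.config.channels[-1]
        h = self.fc_dec(z).reshape(z.shape[0], c_last, self.enc_lengths[-1])
        for stage in self.decoder_stages:
            h = stage(h)
        return h

    def reparameterize(self, mu: nn.Tensor, logvar: nn.Tensor) -> nn.Tensor:
        eps = self._sample_rng.standard_normal(mu.shape)
        return mu + (logvar * 0.5).exp() * nn.Tensor(eps)

    def forward(self, x: nn.Tensor, sample: bool = True):
        mu, logvar = self.encode(x)
        z = self.reparameterize(mu, logvar) if sample else mu
        return self.decode(z), mu, logvar

    def reconstruct(self, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic mean-latent reconstruction; returns (x_hat, mu)."""
        self.eval()
        x = nn.Tensor(windows[:, None, :])
        mu, _ = self.encode(x)
        x_hat = self.decode(mu)
        return x_hat.data[:, 0, :], mu.data


def vae_loss(x: nn.Tensor, x_hat: nn.Tensor, mu: nn.Tensor, logvar: nn.Tensor,
             beta: float):
    """Reconstruction + beta * KL.  The reconstruction term is the squared
    L2 error divided by the window length L (not by batch x L), matching the
    per-window definition; the KL term is the analytic Gaussian divergence
    to the standard normal, averaged over the batch."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    for t in (x, x_hat, mu, logvar):
        if not np.all(np.isfinite(t.data)):
            raise ValueError("non-finite input to vae_loss")
    L = x.shape[-1]
    diff = x - x_hat
    rec = (diff * diff).sum(axis=(1, 2)).mean() * (1.0 / L)
    kl = ((logvar.exp() + mu * mu - 1.0 - logvar) * 0.5).sum(axis=1).mean()
    return rec + kl * beta, rec, kl


def beta_schedule(epoch: int, beta_start: float = 0.01, beta_end: float = 0.5,
                  warmup_epochs: int = 30) -> float:
    """Linear KL warm-up: beta_start at epoch 1, beta_end from epoch
    ``warmup_epochs`` onward (epochs are 1-based)."""
    if epoch >= warmup_epochs:
        return beta_end
    frac = (epoch - 1) / (warmup_epochs - 1)
    return beta_start + (beta_end - beta_start) * frac


def fit_vae(segments: np.ndarray, prescreen: np.ndarray,
            config: VAEConfig | None = None, rng_seed: int = 0,
            stage1_epochs: int = 100, stage2_epochs: int = 60,
            lr_stage1: float = 3e-4, lr_stage2: float = 1.5e-5,
            top_fraction: float = 0.35, batch_size: int = 64,
            warmup_epochs: int = 30) -> tuple[VAE, dict]:
    """Two-stage VAE training.

    Stage 1 trains on the top ``top_fraction`` of windows ranked by the
    pre-screen score; stage 2 fine-tunes on all windows at the reduced
    learning rate.  The KL weight follows :func:`beta_schedule` on the
    global epoch counter.  Returns the model and a loss history.
    """
    segments = np.asarray(segments, dtype=np.float64)
    if segments.ndim != 2 or len(segments) == 0:
        raise ValueError("need a non-empty (N, L) array of standardized windows")
    config = config or VAEConfig(input_len=segments.shape[1])
    n = len(segments)
    n_top = max(1, int(round(top_fraction * n)))
    top_idx = np.argsort(prescreen)[::-1][:n_top]

    model = VAE(config, rng_seed=rng_seed)
    rng = np.random.default_rng(rng_seed + 17)
    history = {"loss": [], "rec": [], "kl": [], "beta": [], "stage": []}
    epoch_global = 0
    for stage, (idx, epochs, lr) in enumerate(
            [(top_idx, stage1_epochs, lr_stage1),
             (np.arange(n), stage2_epochs, lr_stage2)], start=1):
        opt = nn.Adam(model.parameters(), lr=lr)
        for _ in range(epochs):
            epoch_global += 1
            beta = beta_schedule(epoch_global, warmup_epochs=warmup_epochs)
            order = rng.permutation(idx)
            losses, recs, kls = [], [], []
            model.train()
            for start in range(0, len(order), batch_size):
                batch = segments[order[start:start + batch_size]][:, None, :]
                x = nn.Tensor(batch)
                x_hat, mu, logvar = model(x)
                total, rec, kl = vae_loss(x, x_hat, mu, logvar, beta)
                opt.zero_grad()
                total.backward()
                opt.step()
                losses.append(total.item())
                recs.append(rec.item())
                kls.append(kl.item())
            history["loss"].append(float(np.mean(losses)))
            history["rec"].append(float(np.mean(recs)))
            history["kl"].append(float(np.mean(kls)))
            history["beta"].append(beta)
            history["stage"].append(stage)
    history["stage1_indices"] = top_idx
    return model, history


# ---------------------------------------------------------------------------
# component scores and fusion
# ---------------------------------------------------------------------------

@dataclass
class SQICalibration:
    hq_center: np.ndarray
    median_e: float
    median_d: float


def _morphology_score(window: np.ndarray, recon: np.ndarray, fs: float) -> float:
    """Mean of three [0, 1] sub-scores: plausible peak count for the window
    duration, fraction of input peaks preserved (+-3 samples) in the
    reconstruction, and second-difference smoothness."""
    dur = len(window) / fs
    min_dist = int(0.33 * fs)
    peaks, _ = sps.find_peaks(window, distance=min_dist, prominence=0.3)
    n_lo, n_hi = dur * 0.66, dur * 3.0
    c = len(peaks)
    if n_lo <= c <= n_hi:
        count_score = 1.0
    else:
        gap = (n_lo - c) if c < n_lo else (c - n_hi)
        count_score = max(0.0, 1.0 - gap / n_lo)

    rpeaks, _ = sps.find_peaks(recon, distance=min_dist, prominence=0.1)
    if c == 0:
        preserve = 0.0
    else:
        preserve = float(np.mean([np.any(np.abs(rpeaks - p) <= 3) if len(rpeaks)
                                  else False for p in peaks]))

    var = window.var()
    if var < 1e-12:
        smooth = 0.0
    else:
        d2 = np.diff(window, n=2)
        smooth = max(0.0, 1.0 - min(1.0, np.mean(d2 * d2) / (6.0 * var)))
    return float(np.mean([count_score, preserve, smooth]))


def component_scores(windows: np.ndarray, vae: VAE, calibration: SQICalibration,
                     prescreen: np.ndarray, fs: float = 100.0):
    """(S_R, S_L, S_M, S_P) per window, each in [0, 1].

    S_R = exp(-e_i / median e) decreases monotonically in the reconstruction
    error; S_L = exp(-d_i / median d) in the latent distance to the
    high-quality centre; S_M aggregates morphology; S_P adopts the
    pre-screen score unchanged.  Also returns the raw (e_i, d_i).
    """
    if calibration is None:
        raise ValueError("scorer is uncalibrated: fit the VAE first")
    windows = np.asarray(windows, dtype=np.float64)
    recon, mu = vae.reconstruct(windows)
    L = windows.shape[1]
    e = np.sum((windows - recon) ** 2, axis=1) / L
    d = np.linalg.norm(mu - calibration.hq_center[None, :], axis=1)
    s_r = np.exp(-e / max(calibration.median_e, 1e-12))
    s_l = np.exp(-d / max(calibration.median_d, 1e-12))
    s_m = np.array([_morphology_score(w, r, fs) for w, r in zip(windows, recon)])
    s_p = np.clip(np.asarray(prescreen, dtype=np.float64), 0.0, 1.0)
    comps = np.clip(np.stack([s_r, s_l, s_m, s_p], axis=1), 0.0, 1.0)
    return comps, e, d


def fuse_sqi(components: np.ndarray, weights: SQIWeights | None = None) -> np.ndarray:
    """Exact weighted sum S = w_R S_R + w_L S_L + w_M S_M + w_P S_P."""
    weights = weights or SQIWeights()
    comps = np.asarray(components, dtype=np.float64)
    return comps @ weights.as_array()


def adaptive_threshold(scores: np.ndarray, retain_fraction: float = 0.8) -> float:
    """Threshold tau such that the top ``ceil(retain_fraction * N)`` windows
    (plus any ties at tau) pass with ``score >= tau``."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("empty score list")
    if not (0.0 < retain_fraction <= 1.0):
        raise ValueError("retain_fraction must lie in (0, 1]")
    k = int(np.ceil(retain_fraction * scores.size))
    return float(np.sort(scores)[::-1][k - 1])


# ---------------------------------------------------------------------------
# the frozen scorer and dataset screening
# ---------------------------------------------------------------------------

@dataclass
class SQIReport:
    components: np.ndarray     # (N, 4)
    score: np.ndarray          # (N,)
    e: np.ndarray
    d: np.ndarray
    threshold: float | None = None
    passed: np.ndarray | None = None
    weight: np.ndarray | None = None


class SQIScorer:
    """Fits the VAE on training-split subjects, freezes calibration, and
    scores any split forward-pass-only."""

    def __init__(self, config: VAEConfig | None = None,
                 weights: SQIWeights | None = None):
        self.config = config
        self.weights = weights or SQIWeights()
        self.vae: VAE | None = None
        self.calibration: SQICalibration | None = None
        self.train_subjects: set[int] | None = None
        self.history: dict | None = None

    def fit(self, train: WindowDataset, rng_seed: int = 0, **fit_kwargs) -> "SQIScorer":
        windows = np.stack([standardize(w) for w in train.rpw])
        pres = prescreen_scores(windows, train.fs)
        config = self.config or VAEConfig(input_len=windows.shape[1])
        self.vae, self.history = fit_vae(windows, pres, config,
                                         rng_seed=rng_seed, **fit_kwargs)
        top_idx = self.history["stage1_indices"]
        recon, mu = self.vae.reconstruct(windows[top_idx])
        L = windows.shape[1]
        e = np.sum((windows[top_idx] - recon) ** 2, axis=1) / L
        center = mu.mean(axis=0)
        dist = np.linalg.norm(mu - center[None, :], axis=1)
        self.calibration = SQICalibration(
            hq_center=center, median_e=float(np.median(e)),
            median_d=float(np.median(dist)))
        self.train_subjects = set(int(s) for s in train.subjects())
        return self

    def score(self, ds: WindowDataset) -> SQIReport:
        if self.vae is None or self.calibration is None:
            raise ValueError("scorer is uncalibrated: call fit() first")
        windows = np.stack([standardize(w) for w in ds.rpw])
        pres = prescreen_scores(windows, ds.fs)
        comps, e, d = component_scores(windows, self.vae, self.calibration, pres, ds.fs)
        return SQIReport(components=comps, score=fuse_sqi(comps, self.weights), e=e, d=d)


def screen_dataset(splits: dict[str, WindowDataset], scorer: SQIScorer,
                   retain_fraction: float = 0.8):
    """Apply the frozen scorer to every split; retain the top fraction per
    split; export sample weights rescaled to mean 1 over retained training
    windows.  Raises :class:`LeakageError` if the scorer saw any subject that
    now sits in a non-training split.
    """
    if scorer.train_subjects is None:
        raise ValueError("scorer is unfitted")
    for name, ds in splits.items():
        if name == "train":
            continue
        overlap = scorer.train_subjects & set(int(s) for s in ds.subjects())
        if overlap:
            raise LeakageError(
                f"SQI scorer was fitted on subjects {sorted(overlap)} that "
                f"appear in the {name!r} split")
    if "train" in splits:
        extra = set(int(s) for s in scorer.train_subjects) \
            - set(int(s) for s in splits["train"].subjects())
        if extra:
            raise LeakageError(
                f"SQI scorer provenance includes non-training subjects {sorted(extra)}")

    reports: dict[str, SQIReport] = {}
    filtered: dict[str, WindowDataset] = {}
    train_scale = 1.0
    for name, ds in splits.items():
        rep = scorer.score(ds)
        tau = adaptive_threshold(rep.score, retain_fraction)
        passed = rep.score >= tau
        rep.threshold = tau
        rep.passed = passed
        reports[name] = rep
        filtered[name] = ds.select(passed, split=name)
    if "train" in reports:
        rep = reports["train"]
        train_scale = float(np.mean(rep.score[rep.passed]))
    for name, rep in reports.items():
        rep.weight = rep.score[rep.passed] / train_scale
    return filtered, reports


# ---------------------------------------------------------------------------
# evaluation of the quality index itself
# ---------------------------------------------------------------------------

@dataclass
class SQIEvaluation:
    roc_auc: float
    average_precision: float
    f1_at_best_threshold: float
    pearson_r_vs_error: float | None = None
    spearman_rho_vs_error: float | None = None


def evaluate_sqi(scores: np.ndarray, quality_labels: np.ndarray,
                 errors: np.ndarray | None = None) -> SQIEvaluation:
    """Discrimination metrics of the quality score against binary labels
    (1 = genuinely high quality).  F1 is reported at the score threshold
    that maximizes it.  If per-window estimation errors are supplied, the
    Pearson/Spearman correlations of score vs error are included."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(quality_labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary")
    auc = float(roc_auc_score(labels, scores))
    ap = float(average_precision_score(labels, scores))
    prec, rec, _ = precision_recall_curve(labels, scores)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.nan_to_num(2 * prec * rec / (prec + rec))
    best_f1 = float(np.max(f1))
    r = rho = None
    if errors is not None:
        r = float(stats.pearsonr(scores, errors)[0])
        rho = float(stats.spearmanr(scores, errors)[0])
    return SQIEvaluation(auc, ap, best_f1, r, rho)
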