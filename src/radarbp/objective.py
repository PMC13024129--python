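"""Multi-task training objective.

Total loss L = L_BP + lambda_ABP * L_ABP, where L_BP is a Huber
(threshold delta = 1 mmHg) regression loss with the systolic term weighted
by lambda_SBP = 2.0, and L_ABP is a Smooth-L1 loss between the
instance-normalized predicted and reference ABP waveforms (so the auxiliary
task supervises morphology, not absolute pressure — it is invariant to
per-sample affine rescaling of either waveform).  Per-window quality sample
weights multiply both terms before the batch mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autodiff import Tensor

__all__ = ["LossConfig", "LossBundle", "huber", "bp_loss", "abp_recon_loss",
           "total_loss", "instance_normalize"]


@dataclass
class LossConfig:
    lambda_sbp: float = 2.0
    lambda_abp: float = 0.01
    delta: float = 1.0            # mmHg
    use_sample_weights: bool = True

    def __post_init__(self):
        if min(self.lambda_sbp, self.lambda_abp, self.delta) < 0:
            raise ValueError("loss hyperparameters must be non-negative")


@dataclass
class LossBundle:
    total: Tensor
    l_bp: float
    l_abp: float
    l_sbp: float
    l_dbp: float


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def huber_elementwise(y_hat, y, delta: float = 1.0) -> Tensor:
    """Per-element Huber loss: 0.5 e^2 for |e| <= delta, else
    delta |e| - 0.5 delta^2 (the continuous form; symmetric in sign)."""
    y_hat, y = _lift(y_hat), _lift(y)
    e = y_hat - y
    abs_e = e.abs()
    mask = Tensor((np.abs(e.data) <= delta).astype(float))
    quad = e * e * 0.5
    lin = abs_e * delta - 0.5 * delta * delta
    return mask * quad + (1.0 - mask) * lin


def huber(y_hat, y, delta: float = 1.0) -> Tensor:
    """Batch-mean Huber loss."""
    return huber_elementwise(y_hat, y, delta).mean()


def bp_loss(pred_sbp, pred_dbp, y_sbp, y_dbp, cfg: LossConfig | None = None,
            sample_weights=None) -> Tensor:
    """L_BP = lambda_SBP * L_delta(SBP) + L_delta(DBP), with optional
    per-sample quality weights applied before the batch mean (weights are
    not renormalized, so scaling all weights scales the loss linearly)."""
    cfg = cfg or LossConfig()
    per = huber_elementwise(pred_sbp, y_sbp, cfg.delta) * cfg.lambda_sbp \
        + huber_elementwise(pred_dbp, y_dbp, cfg.delta)
    if sample_weights is not None and cfg.use_sample_weights:
        per = per * _lift(sample_weights)
    return per.mean()


def instance_normalize(wave: Tensor, eps: float = 1e-8) -> Tensor:
    """Per-sample zero-mean unit-variance normalization over time."""
    wave = _lift(wave)
    mu = wave.mean(axis=-1, keepdims=True)
    centered = wave - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps * eps) ** -0.5


def abp_recon_loss(pred_wave, target_wave, sample_weights=None,
                   cfg: LossConfig | None = None) -> Tensor:
    """Smooth-L1 (beta = 1) between instance-normalized waveforms, averaged
    over samples and time."""
    cfg = cfg or LossConfig()
    pred, target = _lift(pred_wave), _lift(target_wave)
    if pred.shape != target.shape:
        raise ValueError("waveform shapes must match")
    p = instance_normalize(pred)
    t = instance_normalize(target)
    per = huber_elementwise(p, t, 1.0).mean(axis=-1)
    if sample_weights is not None and cfg.use_sample_weights:
        per = per * _lift(sample_weights)
    return per.mean()


def total_loss(pred, y_sbp, y_dbp, y_abp, cfg: LossConfig | None = None,
               sample_weights=None) -> LossBundle:
    """L = L_BP + lambda_ABP * L_ABP (exact composition; lambda_ABP = 0
    disables the auxiliary path)."""
    cfg = cfg or LossConfig()
    l_sbp = huber_elementwise(pred.sbp, y_sbp, cfg.delta)
    l_dbp = huber_elementwise(pred.dbp, y_dbp, cfg.delta)
    per_bp = l_sbp * cfg.lambda_sbp + l_dbp
    if sample_weights is not None and cfg.use_sample_weights:
        per_bp = per_bp * _lift(sample_weights)
    l_bp = per_bp.mean()
    if cfg.lambda_abp != 0.0:
        l_abp = abp_recon_loss(pred.abp, y_abp, sample_weights, cfg)
        total = l_bp + l_abp * cfg.lambda_abp
        l_abp_val = l_abp.item()
    else:
        total = l_bp
        l_abp_val = 0.0
    return LossBundle(total=total, l_bp=l_bp.item(), l_abp=l_abp_val,
                      l_sbp=l_sbp.mean().item(), l_dbp=l_dbp.mean().item())
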