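"""Label-preserving augmentation of standardized pulse windows.

Five operators — circular time shift, amplitude scaling, time warping,
Gaussian noise injection and sinusoidal baseline wander — each applied
independently with probability 0.5, in the fixed order
shift -> scale -> warp -> noise -> wander.  Blood-pressure labels and the
paired ABP waveform are carried unchanged: every operator either permutes,
rescales or mildly perturbs the window without touching its label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import WindowDataset

__all__ = ["AugmentConfig", "apply_augmentation", "augment_dataset", "AugmentLeakageError"]


class AugmentLeakageError(RuntimeError):
    """Raised when augmentation is requested on a non-training split."""


@dataclass
class AugmentConfig:
    factor: int = 3                      # augmented copies per original
    op_probability: float = 0.5
    shift_frac: float = 0.10             # circular shift up to +-10% of L
    scale_range: tuple[float, float] = (0.9, 1.1)
    noise_sd: float = 0.02               # relative to the window's own sd
    warp_range: tuple[float, float] = (0.95, 1.05)
    wander_amp: float = 0.05             # on the standardized scale
    wander_freq: float = 0.5             # Hz

    def __post_init__(self):
        if not (0.0 <= self.op_probability <= 1.0):
            raise ValueError("probability must lie in [0, 1]")
        for name in ("scale_range", "warp_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not well-ordered")


def _time_warp(x: np.ndarray, ratio: float) -> np.ndarray:
    """Resample by a single uniform ratio, then linearly interpolate back
    to the original length."""
    n = len(x)
    m = max(2, int(round(n * ratio)))
    stretched = np.interp(np.linspace(0, n - 1, m), np.arange(n), x)
    return np.interp(np.linspace(0, m - 1, n), np.arange(m), stretched)


def apply_augmentation(window: np.ndarray, config: AugmentConfig,
                       rng: np.random.Generator, fs: float = 100.0) -> np.ndarray:
    """One augmented copy of ``window``; length is always preserved and a
    draw in which every operator is skipped returns the input exactly."""
    x = np.asarray(window, dtype=np.float64).copy()
    n = len(x)
    p = config.op_probability
    # draws are consumed unconditionally so the op sequence stays aligned
    if rng.random() < p:                                     # circular time shift
        max_shift = int(round(config.shift_frac * n))
        shift = int(rng.integers(-max_shift, max_shift + 1)) if max_shift else 0
        x = np.roll(x, shift)
    if rng.random() < p:                                     # amplitude scaling
        x = x * rng.uniform(*config.scale_range)
    if rng.random() < p:                                     # time warping
        x = _time_warp(x, rng.uniform(*config.warp_range))
    if rng.random() < p:                                     # Gaussian noise
        x = x + rng.normal(0.0, config.noise_sd * (x.std() + 1e-12), size=n)
    if rng.random() < p:                                     # baseline wander
        t = np.arange(n) / fs
        x = x + config.wander_amp * np.sin(
            2 * np.pi * config.wander_freq * t + rng.uniform(0, 2 * np.pi))
    return x


def augment_dataset(ds: WindowDataset, config: AugmentConfig | None = None,
                    rng_seed: int = 0) -> WindowDataset:
    """Originals plus ``config.factor`` augmented copies of every window
    (so 4x the window count at the default factor 3).  Copies inherit the
    subject id and the (SBP, DBP, ABP) labels unchanged.  Refuses to run on
    validation/test splits."""
    if ds.split is not None and ds.split != "train":
        raise AugmentLeakageError(
            f"augmentation is restricted to the training split, got {ds.split!r}")
    config = config or AugmentConfig()
    rng = np.random.default_rng(rng_seed)
    blocks = [ds.rpw]
    for _ in range(config.factor):
        blocks.append(np.stack([apply_augmentation(w, config, rng, ds.fs)
                                for w in ds.rpw]))
    reps = config.factor + 1
    return replace(
        ds,
        rpw=np.concatenate(blocks),
        abp=np.tile(ds.abp, (reps, 1)),
        sbp=np.tile(ds.sbp, reps),
        dbp=np.tile(ds.dbp, reps),
        subject=np.tile(ds.subject, reps),
        corrupt=np.tile(ds.corrupt, reps),
    )
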