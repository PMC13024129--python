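"""Training and evaluation protocol.

Subject-wise 70/10/20 splitting, the AdamW + cosine-annealing training loop
with early stopping on validation loss, blood-pressure agreement metrics
(ME/SD/MAE/RMSE/Pearson r, cumulative error percentages, Bland-Altman
limits, per-subject breakdown), AAMI / BHS grading, and controlled ablation
runners.  Error sign convention throughout: predicted - reference.  The
error SD uses the sample (n-1) convention, so RMSE^2 = ME^2 +
SD^2 (n-1)/n.
"""

from __future__ import annotations


import json
import warnings
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from . import nn
from .augment import AugmentConfig, augment_dataset
from .data import WindowDataset
from .dsp import standardize
from .model import MARUMTL, ModelConfig, derivative_channels
from .objective import LossConfig, total_loss
from .sqi import SQIScorer, VAEConfig, screen_dataset

__all__ = [
    "TrainConfig", "MetricsReport", "TargetMetrics", "split_by_subject",
    "split_subject_ids", "train", "predict", "evaluate", "evaluate_model",
    "aami_check", "bhs_grade", "bland_altman", "save_checkpoint",
    "load_checkpoint", "run_ablation", "run_experiment",
]

AAMI_ME_LIMIT = 5.0    # mmHg
AAMI_SD_LIMIT = 8.0    # mmHg
BHS_THRESHOLDS = {"A": (60.0, 85.0, 95.0),
                  "B": (50.0, 75.0, 90.0),
                  "C": (40.0, 65.0, 85.0)}


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    exact = [r * n for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    order = np.argsort([b - e for b, e in zip(base, exact)], kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base


def split_subject_ids(subjects: np.ndarray, ratios=(0.7, 0.1, 0.2),
                      seed: int = 0) -> tuple[list, list, list]:
    subjects = list(np.unique(subjects))
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for a 3-way split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    counts = _largest_remainder(len(subjects), tuple(ratios))
    shuffled = [subjects[i] for i in order]
    train = shuffled[:counts[0]]
    val = shuffled[counts[0]:counts[0] + counts[1]]
    test = shuffled[counts[0] + counts[1]:]
    return train, val, test


def split_by_subject(ds: WindowDataset, ratios=(0.7, 0.1, 0.2), seed: int = 0):
    """Subject-disjoint (train, val, test) datasets with split tags; subject
    counts follow largest-remainder rounding of the ratios."""
    tr, va, te = split_subject_ids(ds.subject, ratios, seed)
    return (ds.subset_subjects(tr, split="train"),
            ds.subset_subjects(va, split="val"),
            ds.subset_subjects(te, split="test"))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-5
    batch_size: int = 512
    max_epochs: int = 120
    patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")

    @classmethod
    def tiny(cls, max_epochs: int = 30, **kwargs) -> "TrainConfig":
        """CPU profile: small batch, short schedule, and a learning rate
        scaled up for the narrow network / small batch regime."""
        kwargs.setdefault("batch_size", 32)
        kwargs.setdefault("patience", min(10, max_epochs - 1))
        kwargs.setdefault("lr", 3e-3)
        return cls(max_epochs=max_epochs, **kwargs)


def _model_inputs(ds: WindowDataset) -> np.ndarray:
    return np.stack([derivative_channels(standardize(w), ds.fs) for w in ds.rpw])


def _batch_losses(model: MARUMTL, X: np.ndarray, ds: WindowDataset,
                  loss_cfg: LossConfig, batch_size: int) -> float:
    """Forward-only mean total loss over a dataset (no weighting)."""
    vals, counts = [], []
    for s in range(0, len(X), batch_size):
        xb = X[s:s + batch_size]
        pred = model(xb)
        bundle = total_loss(pred, ds.sbp[s:s + batch_size],
                            ds.dbp[s:s + batch_size], ds.abp[s:s + batch_size],
                            loss_cfg)
        vals.append(bundle.total.item())
        counts.append(len(xb))
    return float(np.average(vals, weights=counts))


def train(model: MARUMTL, train_ds: WindowDataset, val_ds: WindowDataset,
          train_cfg: TrainConfig | None = None,
          loss_cfg: LossConfig | None = None,
          sample_weights: np.ndarray | None = None) -> dict:
    """AdamW + cosine annealing with early stopping on validation loss.

    The regression-head bias is initialized at the training-label mean so
    optimization starts at the data centre of the mmHg scale.  Returns a
    history dict and restores the best-validation weights in-place.
    """
    if len(train_ds) == 0:
        raise ValueError("empty training split")
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    rng = np.random.default_rng(train_cfg.seed)

    X_tr = _model_inputs(train_ds)
    X_va = _model_inputs(val_ds) if len(val_ds) else None
    model.set_output_bias(train_ds.sbp.mean(), train_ds.dbp.mean())

    opt = nn.AdamW(model.parameters(), lr=train_cfg.lr,
                   weight_decay=train_cfg.weight_decay)
    sched = nn.CosineAnnealingLR(opt, t_max=train_cfg.max_epochs)
    history = {"train_loss": [], "val_loss": [], "best_val": [], "lr": []}
    best_val = np.inf
    best_state = model.state_dict()
    stall = 0
    for epoch in range(train_cfg.max_epochs):
        model.train()
        order = rng.permutation(len(X_tr))
        losses = []
        for s in range(0, len(order), train_cfg.batch_size):
            idx = order[s:s + train_cfg.batch_size]
            pred = model(X_tr[idx])
            w = sample_weights[idx] if sample_weights is not None else None
            bundle = total_loss(pred, train_ds.sbp[idx], train_ds.dbp[idx],
                                train_ds.abp[idx], loss_cfg, w)
            opt.zero_grad()
            bundle.total.backward()
            opt.step()
            losses.append(bundle.total.item())
        sched.step()
        model.eval()
        val_loss = (_batch_losses(model, X_va, val_ds, loss_cfg,
                                  train_cfg.batch_size)
                    if X_va is not None else float(np.mean(losses)))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state_dict()
            stall = 0
        else:
            stall += 1
        history["best_val"].append(best_val)
        if stall >= train_cfg.patience:
            break
    model.load_state_dict(best_state)
    history["stopped_epoch"] = len(history["train_loss"])
    return history


def predict(model: MARUMTL, ds: WindowDataset, batch_size: int = 64):
    """(sbp, dbp, abp) predictions as numpy arrays."""
    model.eval()
    X = _model_inputs(ds)
    sbp, dbp, abp = [], [], []
    for s in range(0, len(X), batch_size):
        pred = model(X[s:s + batch_size])
        sbp.append(pred.sbp.data)
        dbp.append(pred.dbp.data)
        abp.append(pred.abp.data)
    return np.concatenate(sbp), np.concatenate(dbp), np.concatenate(abp)


# ---------------------------------------------------------------------------
# metrics and grading
# ---------------------------------------------------------------------------

def aami_check(me: float, sd: float) -> bool:
    """Device-accuracy criterion: |ME| <= 5 mmHg and SD <= 8 mmHg
    (boundaries inclusive)."""
    if not (np.isfinite(me) and np.isfinite(sd)):
        raise ValueError("ME and SD must be finite")
    return abs(me) <= AAMI_ME_LIMIT and sd <= AAMI_SD_LIMIT


def bhs_grade(pct5: float, pct10: float, pct15: float) -> str:
    """Cumulative-error grade: the best of A/B/C whose three thresholds are
    all met (inclusive), else D."""
    if not (0 <= pct5 <= pct10 <= pct15 <= 100):
        raise ValueError("cumulative percentages must be non-decreasing in [0, 100]")
    for grade, (t5, t10, t15) in BHS_THRESHOLDS.items():
        if pct5 >= t5 and pct10 >= t10 and pct15 >= t15:
            return grade
    return "D"


def bland_altman(errors: np.ndarray) -> dict:
    bias = float(np.mean(errors))
    sd = float(np.std(errors, ddof=1))
    return {"bias": bias, "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd}


@dataclass
class TargetMetrics:
    me: float
    sd: float
    mae: float
    rmse: float
    r: float
    pct5: float
    pct10: float
    pct15: float
    aami_pass: bool
    bhs: str
    bland_altman: dict
    per_subject_mae: dict
    per_subject_r: dict


@dataclass
class MetricsReport:
    sbp: TargetMetrics
    dbp: TargetMetrics
    n_windows: int

    def to_dict(self) -> dict:
        return {"sbp": asdict(self.sbp), "dbp": asdict(self.dbp),
                "n_windows": self.n_windows}


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("Pearson r undefined for constant input; reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _target_metrics(pred: np.ndarray, ref: np.ndarray,
                    subjects: np.ndarray) -> TargetMetrics:
    err = pred - ref
    abs_err = np.abs(err)
    me = float(np.mean(err))
    sd = float(np.std(err, ddof=1))
    per_mae, per_r = {}, {}
    for sid in np.unique(subjects):
        m = subjects == sid
        per_mae[int(sid)] = float(np.mean(abs_err[m]))
        per_r[int(sid)] = (_pearson(pred[m], ref[m]) if m.sum() > 1
                           else float("nan"))
    pct5, pct10, pct15 = (float(np.mean(abs_err <= t) * 100) for t in (5, 10, 15))
    return TargetMetrics(
        me=me, sd=sd, mae=float(np.mean(abs_err)),
        rmse=float(np.sqrt(np.mean(err ** 2))), r=_pearson(pred, ref),
        pct5=pct5, pct10=pct10, pct15=pct15,
        aami_pass=aami_check(me, sd), bhs=bhs_grade(pct5, pct10, pct15),
        bland_altman=bland_altman(err), per_subject_mae=per_mae,
        per_subject_r=per_r)


def evaluate(pred_sbp: np.ndarray, pred_dbp: np.ndarray,
             ref_sbp: np.ndarray, ref_dbp: np.ndarray,
             subjects: np.ndarray) -> MetricsReport:
    """Agreement metrics from paired predictions and references."""
    n = len(ref_sbp)
    if n < 2:
        raise ValueError("need at least 2 windows (SD undefined otherwise)")
    return MetricsReport(
        sbp=_target_metrics(np.asarray(pred_sbp, float), np.asarray(ref_sbp, float),
                            np.asarray(subjects)),
        dbp=_target_metrics(np.asarray(pred_dbp, float), np.asarray(ref_dbp, float),
                            np.asarray(subjects)),
        n_windows=n)


def evaluate_model(model: MARUMTL, ds: WindowDataset) -> MetricsReport:
    sbp, dbp, _ = predict(model, ds)
    return evaluate(sbp, dbp, ds.sbp, ds.dbp, ds.subject)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: MARUMTL, path) -> None:
    state = model.state_dict()
    cfg = json.dumps(asdict(model.config))
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **{f"param::{k}": v for k, v in state.items()})


def load_checkpoint(path, rng_seed: int = 0) -> MARUMTL:
    with np.load(path) as z:
        cfg_raw = json.loads(bytes(z["__config__"]).decode())
        cfg_raw["blocks"] = tuple(cfg_raw["blocks"])
        model = MARUMTL(ModelConfig(**cfg_raw), rng_seed=rng_seed)
        model.load_state_dict({k[len("param::"):]: z[k]
                               for k in z.files if k.startswith("param::")})
    return model


# ---------------------------------------------------------------------------
# experiment pipeline and ablations
# ---------------------------------------------------------------------------

def run_experiment(dataset: WindowDataset, model_cfg: ModelConfig,
                   train_cfg: TrainConfig, loss_cfg: LossConfig | None = None,
                   seed: int = 0, use_sqi: bool = True,
                   retain_fraction: float = 0.8, augment_factor: int = 3,
                   vae_config: VAEConfig | None = None,
                   vae_epochs: tuple[int, int] = (30, 15)) -> dict:
    """Full protocol on one dataset: split by subject, fit the quality
    scorer on training subjects only, screen all splits, augment the
    training split, train, evaluate on the screened test split.

    Returns a dict with the trained model, metrics report, screening
    reports and baseline (predict-the-training-mean) MAEs.
    """
    loss_cfg = loss_cfg or LossConfig()
    train_ds, val_ds, test_ds = split_by_subject(dataset, seed=seed)
    weights = None
    reports = None
    if use_sqi and retain_fraction < 1.0:
        scorer = SQIScorer(vae_config or VAEConfig.tiny(dataset.window_len))
        scorer.fit(train_ds, rng_seed=seed, stage1_epochs=vae_epochs[0],
                   stage2_epochs=vae_epochs[1])
        splits, reports = screen_dataset(
            {"train": train_ds, "val": val_ds, "test": test_ds},
            scorer, retain_fraction)
        train_ds, val_ds, test_ds = splits["train"], splits["val"], splits["test"]
        weights = reports["train"].weight
    if augment_factor > 0:
        n0 = len(train_ds)
        train_ds = augment_dataset(train_ds, AugmentConfig(factor=augment_factor),
                                   rng_seed=seed + 1)
        if weights is not None:
            weights = np.tile(weights, augment_factor + 1)
        assert len(train_ds) == (augment_factor + 1) * n0
    model = MARUMTL(model_cfg, rng_seed=seed + 2)
    history = train(model, train_ds, val_ds,
                    replace(train_cfg, seed=seed + 3), loss_cfg, weights)
    metrics = evaluate_model(model, test_ds)
    baseline_sbp = float(np.mean(np.abs(train_ds.sbp.mean() - test_ds.sbp)))
    baseline_dbp = float(np.mean(np.abs(train_ds.dbp.mean() - test_ds.dbp)))
    return {"model": model, "metrics": metrics, "history": history,
            "sqi_reports": reports, "splits": (train_ds, val_ds, test_ds),
            "baseline_mae": {"sbp": baseline_sbp, "dbp": baseline_dbp}}


ABLATION_SUITES = {
    "lambda_sweep": [0.0, 0.01, 0.05, 0.1, 0.2, 0.5],
    "sqi_retention": [1.0, 0.9, 0.8, 0.7],
    "temporal_module": ["bimamba", "mamba", "none"],
    "bottleneck_variant": ["multiscale_cta", "multiscale_plain", "single_scale"],
}


def run_ablation(suite: str, dataset: WindowDataset, model_cfg: ModelConfig,
                 train_cfg: TrainConfig, seed: int = 0,
                 variants: list | None = None, **experiment_kwargs) -> pd.DataFrame:
    """Train one model per variant under identical seeds and a shared
    subject split; one metrics row per variant."""
    if suite not in ABLATION_SUITES:
        raise ValueError(f"unknown suite {suite!r}; options: {sorted(ABLATION_SUITES)}")
    variants = ABLATION_SUITES[suite] if variants is None else variants
    rows = []
    ref_split = None
    for variant in variants:
        cfg = model_cfg
        kwargs = dict(experiment_kwargs)
        if suite == "lambda_sweep":
            kwargs["loss_cfg"] = LossConfig(lambda_abp=float(variant))
        elif suite == "sqi_retention":
            kwargs["retain_fraction"] = float(variant)
            kwargs["use_sqi"] = float(variant) < 1.0
        elif suite == "temporal_module":
            cfg = replace(model_cfg, temporal_module=str(variant))
        elif suite == "bottleneck_variant":
            cfg = replace(model_cfg, bottleneck=str(variant))
        result = run_experiment(dataset, cfg, train_cfg, seed=seed, **kwargs)
        split_subjects = tuple(tuple(int(s) for s in ds.subjects())
                               for ds in result["splits"])
        if ref_split is None:
            ref_split = split_subjects
        elif split_subjects != ref_split:
            raise AssertionError("ablation variants diverged in subject split")
        m = result["metrics"]
        rows.append({"variant": variant,
                     "sbp_mae": m.sbp.mae, "sbp_sd": m.sbp.sd, "sbp_r": m.sbp.r,
                     "sbp_bhs": m.sbp.bhs, "dbp_mae": m.dbp.mae,
                     "dbp_sd": m.dbp.sd, "dbp_r": m.dbp.r, "dbp_bhs": m.dbp.bhs,
                     "aami": m.sbp.aami_pass and m.dbp.aami_pass})
    return pd.DataFrame(rows)
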