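"""In-memory window dataset and its HDF5/NPZ on-disk schema.

A :class:`WindowDataset` holds N fixed-length radar-pulse-wave (RPW) windows
with paired arterial-blood-pressure (ABP) waveforms, per-window SBP/DBP
scalars in mmHg, integer subject ids and binary corruption labels.  On disk
the layout is one HDF5 group per subject::

    /subjects/<id>/rpw      (W, L) float32
    /subjects/<id>/abp      (W, L) float32
    /subjects/<id>/sbp      (W,)   float32
    /subjects/<id>/dbp      (W,)   float32
    /subjects/<id>/corrupt  (W,)   uint8

with file attributes ``fs`` (Hz) and ``schema_version``.  Storage indices are
0-based.  An ``.npz`` fallback with flat arrays is also supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

SCHEMA_VERSION = 1


@dataclass
class WindowDataset:
    rpw: np.ndarray          # (N, L)
    abp: np.ndarray          # (N, L)
    sbp: np.ndarray          # (N,)
    dbp: np.ndarray          # (N,)
    subject: np.ndarray      # (N,) int
    corrupt: np.ndarray      # (N,) uint8
    fs: float = 100.0
    split: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.rpw)
        for name in ("abp", "sbp", "dbp", "subject", "corrupt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch")

    def __len__(self) -> int:
        return len(self.rpw)

    @property
    def window_len(self) -> int:
        return self.rpw.shape[1]

    def subjects(self) -> np.ndarray:
        return np.unique(self.subject)

    def select(self, mask: np.ndarray, split: str | None = None) -> "WindowDataset":
        return replace(
            self,
            rpw=self.rpw[mask], abp=self.abp[mask], sbp=self.sbp[mask],
            dbp=self.dbp[mask], subject=self.subject[mask], corrupt=self.corrupt[mask],
            split=self.split if split is None else split,
        )

    def subset_subjects(self, subject_ids, split: str | None = None) -> "WindowDataset":
        mask = np.isin(self.subject, np.asarray(list(subject_ids)))
        return self.select(mask, split=split)


def save_dataset(ds: WindowDataset, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, rpw=ds.rpw.astype(np.float32), abp=ds.abp.astype(np.float32),
                 sbp=ds.sbp.astype(np.float32), dbp=ds.dbp.astype(np.float32),
                 subject=ds.subject.astype(np.int64), corrupt=ds.corrupt.astype(np.uint8),
                 fs=np.float64(ds.fs), schema_version=np.int64(SCHEMA_VERSION))
        return
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = float(ds.fs)
        f.attrs["schema_version"] = SCHEMA_VERSION
        grp = f.create_group("subjects")
        for sid in ds.subjects():
            m = ds.subject == sid
            g = grp.create_group(str(int(sid)))
            g.create_dataset("rpw", data=ds.rpw[m].astype(np.float32))
            g.create_dataset("abp", data=ds.abp[m].astype(np.float32))
            g.create_dataset("sbp", data=ds.sbp[m].astype(np.float32))
            g.create_dataset("dbp", data=ds.dbp[m].astype(np.float32))
            g.create_dataset("corrupt", data=ds.corrupt[m].astype(np.uint8))


def load_dataset(path: str | Path) -> WindowDataset:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return WindowDataset(
                rpw=np.asarray(z["rpw"], dtype=np.float64),
                abp=np.asarray(z["abp"], dtype=np.float64),
                sbp=np.asarray(z["sbp"], dtype=np.float64),
                dbp=np.asarray(z["dbp"], dtype=np.float64),
                subject=np.asarray(z["subject"], dtype=np.int64),
                corrupt=np.asarray(z["corrupt"], dtype=np.uint8),
                fs=float(z["fs"]),
            )
    rpw, abp, sbp, dbp, subject, corrupt = [], [], [], [], [], []
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])
        for sid in sorted(f["subjects"], key=int):
            g = f["subjects"][sid]
            w = len(g["rpw"])
            rpw.append(np.asarray(g["rpw"], dtype=np.float64))
            abp.append(np.asarray(g["abp"], dtype=np.float64))
            sbp.append(np.asarray(g["sbp"], dtype=np.float64))
            dbp.append(np.asarray(g["dbp"], dtype=np.float64))
            corrupt.append(np.asarray(g["corrupt"], dtype=np.uint8))
            subject.append(np.full(w, int(sid), dtype=np.int64))
    return WindowDataset(
        rpw=np.concatenate(rpw), abp=np.concatenate(abp), sbp=np.concatenate(sbp),
        dbp=np.concatenate(dbp), subject=np.concatenate(subject),
        corrupt=np.concatenate(corrupt), fs=fs,
    )
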