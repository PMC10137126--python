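"""Epoch container data model and its on-disk directory format.

An :class:`EpochSet` holds one subject's trials x channels x samples tensor
(microvolts) together with the sampling geometry and a per-trial info table.
Time is stored as ``(sampling_rate, t0_index)``, never as per-sample floats,
so the sample grid is uniform by construction; time zero is the onset of the
second stimulus.

On disk an epoch set is a directory with three inspectable files::

    meta.json    schema-versioned metadata (geometry, channels, dtype, shape)
    data.bin     the raw tensor, little-endian floats in trial-major order
    trials.csv   the per-trial info table (subject, ma, tp, trial, correct, rt_s)

The blob preserves the in-memory dtype (``<f4`` or ``<f8``, recorded in the
metadata) so the round trip is bit-exact.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, VersionError

SCHEMA_VERSION = 1

TRIAL_COLUMNS = ["subject", "ma", "tp", "trial", "correct", "rt_s"]

_ALLOWED_DTYPES = {"<f4": np.dtype("<f4"), "<f8": np.dtype("<f8")}


@dataclass
class EpochSet:
    """Trial-epoched multichannel data for one subject (or a merged set)."""

    data: np.ndarray  # (n_trials, n_channels, n_samples), microvolts
    sampling_rate: float
    t0_index: int
    channels: list[str]
    trial_info: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError("data: expected a 3-d (trials, channels, "
                              f"samples) tensor, got ndim={self.data.ndim}")
        n_trials, n_channels, n_samples = self.data.shape
        if len(self.channels) != n_channels:
            raise FormatError(
                f"channels: {len(self.channels)} labels for a tensor with "
                f"{n_channels} channels")
        if not 0 <= self.t0_index < n_samples:
            raise FormatError(f"t0_index: {self.t0_index} outside "
                              f"[0, {n_samples})")
        if len(self.trial_info) != n_trials:
            raise FormatError(
                f"trial_info: {len(self.trial_info)} rows for {n_trials} "
                "trials")
        self.trial_info = self.trial_info.reset_index(drop=True)

    # -- geometry -----------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds; exactly one sample is at 0.0."""
        return (np.arange(self.n_samples) - self.t0_index) / self.sampling_rate

    def channel_indices(self, names) -> list[int]:
        missing = [ch for ch in names if ch not in self.channels]
        if missing:
            raise FormatError(f"channels: unknown channel(s) {missing}")
        return [self.channels.index(ch) for ch in names]

    def copy_with(self, *, data=None, sampling_rate=None, t0_index=None,
                  trial_info=None) -> "EpochSet":
        return EpochSet(
            data=self.data.copy() if data is None else data,
            sampling_rate=self.sampling_rate if sampling_rate is None
            else sampling_rate,
            t0_index=self.t0_index if t0_index is None else t0_index,
            channels=list(self.channels),
            trial_info=(self.trial_info if trial_info is None
                        else trial_info).copy(),
        )

    def select_trials(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return self.copy_with(data=self.data[mask],
                              trial_info=self.trial_info.loc[mask])

    def cell_mask(self, ma: str, tp: str) -> np.ndarray:
        return ((self.trial_info["ma"] == ma)
                & (self.trial_info["tp"] == tp)).to_numpy()


@dataclass
class BehaviorTable:
    """Long-format behavioral records: one row per subject x cell x trial."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=TRIAL_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"frame: missing column(s) {missing}")
        dup = self.frame.duplicated(subset=["subject", "ma", "tp", "trial"])
        if dup.any():
            raise FormatError("frame: (subject, ma, tp, trial) rows must be "
                              "unique")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, columns=TRIAL_COLUMNS)

    @classmethod
    def from_csv(cls, path) -> "BehaviorTable":
        return cls(frame=_coerce_correct(pd.read_csv(path)))


def _coerce_correct(frame: pd.DataFrame) -> pd.DataFrame:
    """Make the ``correct`` column a real boolean, however CSV parsed it."""
    if "correct" in frame and frame["correct"].dtype != bool:
        frame["correct"] = frame["correct"].map(
            {"True": True, "False": False, 1: True, 0: False,
             True: True, False: False})
        if frame["correct"].isna().any():
            raise FormatError("correct: column contains non-boolean values")
        frame["correct"] = frame["correct"].astype(bool)
    return frame


# ---------------------------------------------------------------------------
# On-disk container
# ---------------------------------------------------------------------------

def write_epochs(e: EpochSet, path) -> None:
    """Write ``e`` to directory ``path`` (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dtype = e.data.dtype.newbyteorder("<")
    if dtype.str not in _ALLOWED_DTYPES:
        dtype = np.dtype("<f8")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "sampling_rate": float(e.sampling_rate),
        "t0_index": int(e.t0_index),
        "channels": list(e.channels),
        "n_trials": int(e.n_trials),
        "n_samples": int(e.n_samples),
        "dtype": dtype.str,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    np.ascontiguousarray(e.data, dtype=dtype).tofile(path / "data.bin")
    e.trial_info.to_csv(path / "trials.csv", index=False,
                        columns=TRIAL_COLUMNS)


def read_epochs(path) -> EpochSet:
    """Read an epoch container written by :func:`write_epochs`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"meta.json: missing in {path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"meta.json: not valid JSON ({exc})") from exc
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise VersionError(
            f"schema_version: container has {version!r}, this reader "
            f"supports {SCHEMA_VERSION}")
    for key in ("sampling_rate", "t0_index", "channels", "n_trials",
                "n_samples", "dtype"):
        if key not in meta:
            raise FormatError(f"{key}: missing from meta.json")
    dtype_str = meta["dtype"]
    if dtype_str not in _ALLOWED_DTYPES:
        raise FormatError(f"dtype: unsupported {dtype_str!r}")
    dtype = _ALLOWED_DTYPES[dtype_str]
    n_trials, n_samples = int(meta["n_trials"]), int(meta["n_samples"])
    channels = list(meta["channels"])
    expected = n_trials * len(channels) * n_samples * dtype.itemsize
    blob = path / "data.bin"
    if not blob.exists():
        raise FormatError(f"data.bin: missing in {path}")
    actual = blob.stat().st_size
    if actual != expected:
        raise FormatError(
            f"data.bin: size {actual} bytes does not match metadata shape "
            f"({n_trials} x {len(channels)} x {n_samples}, {dtype_str}) "
            f"= {expected} bytes")
    data = np.fromfile(blob, dtype=dtype).reshape(
        n_trials, len(channels), n_samples)
    trial_info = _coerce_correct(pd.read_csv(path / "trials.csv"))
    return EpochSet(data=data, sampling_rate=float(meta["sampling_rate"]),
                    t0_index=int(meta["t0_index"]), channels=channels,
                    trial_info=trial_info)
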