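"""In-memory containers: epoched EEG and time-frequency grids."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["EpochSet", "TFRGrid"]


@dataclass
class EpochSet:
    """Epoched multichannel EEG: trials x channels x time, in microvolts.

    ``times`` is in seconds with stimulus onset at t = 0.  ``trials`` is a
    long-format table aligned with axis 0 of ``data`` (columns typically:
    participant, trial, block, objecthood, frequency, source_id,
    category).  ``meta['history']`` records processing steps.
    """

    data: np.ndarray
    srate: float
    chan_names: list[str]
    times: np.ndarray
    trials: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        n_trials, n_chan, n_times = self.data.shape
        if len(self.chan_names) != n_chan:
            raise ValueError("channel label count does not match data")
        if len(set(self.chan_names)) != n_chan:
            raise ValueError("channel labels must be unique")
        if len(self.times) != n_times:
            raise ValueError("time axis length does not match data")
        if len(self.trials) != n_trials:
            raise ValueError("trial table length does not match data")
        if np.isnan(self.data).any():
            raise ValueError("epoch data contains NaN")
        if self.srate <= 0:
            raise ValueError("sampling rate must be positive")
        self.meta.setdefault("history", [])

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self, data: np.ndarray | None = None) -> "EpochSet":
        return EpochSet(
            data=self.data.copy() if data is None else data,
            srate=self.srate,
            chan_names=list(self.chan_names),
            times=self.times.copy(),
            trials=self.trials.copy(),
            meta={**self.meta, "history": list(self.meta.get("history", []))},
        )

    def log(self, step: str) -> None:
        self.meta["history"].append(step)

    def channel_index(self, labels: Sequence[str]) -> np.ndarray:
        missing = [lab for lab in labels if lab not in self.chan_names]
        if missing:
            raise KeyError(f"unknown channel label(s): {missing}")
        return np.array([self.chan_names.index(lab) for lab in labels])

    def time_mask(self, window_s: tuple[float, float]) -> np.ndarray:
        lo, hi = window_s
        if lo > hi:
            raise ValueError("window start must not exceed end")
        if lo < self.times[0] - 1e-12 or hi > self.times[-1] + 1e-12:
            raise ValueError(
                f"window [{lo}, {hi}] s outside epoch "
                f"[{self.times[0]:.3f}, {self.times[-1]:.3f}] s"
            )
        return (self.times >= lo - 1e-12) & (self.times <= hi + 1e-12)

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[mask],
            srate=self.srate,
            chan_names=list(self.chan_names),
            times=self.times.copy(),
            trials=self.trials.loc[mask].reset_index(drop=True),
            meta={**self.meta, "history": list(self.meta.get("history", []))},
        )


@dataclass
class TFRGrid:
    """Time-frequency power: channels x frequencies x times.

    ``mode`` records whether power was computed on the trial average
    ("evoked") or per trial then averaged ("total").  ``normalized`` marks
    percent-change-from-baseline units; raw power is in uV^2.  Bins whose
    analysis window would extend beyond the epoch are NaN.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    chan_names: list[str]
    mode: str
    normalized: bool = False
    baseline_window: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.shape != (len(self.chan_names), len(self.freqs), len(self.times)):
            raise ValueError("power must be channels x freqs x times")
        if self.mode not in ("evoked", "total"):
            raise ValueError("mode must be 'evoked' or 'total'")

    def channel_index(self, labels: Sequence[str]) -> np.ndarray:
        missing = [lab for lab in labels if lab not in self.chan_names]
        if missing:
            raise KeyError(f"unknown channel label(s): {missing}")
        return np.array([self.chan_names.index(lab) for lab in labels])
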