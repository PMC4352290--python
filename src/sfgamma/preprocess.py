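"""Deterministic signal conditioning before ERP and time-frequency analysis.

The ERP chain is: 40 Hz low-pass Butterworth -> baseline subtraction
(-200..0 ms).  The TFR chain is: band-stop Butterworth at 49-51 Hz (line)
and 84-86 Hz (monitor refresh), order 2, then linear detrending — no
time-domain baseline subtraction.  All filters are applied zero-phase
(forward-backward), which doubles the effective order and removes group
delay; the filter chain is logged into the container metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.signal

from .containers import EpochSet

__all__ = [
    "FilterSpec",
    "butterworth_filter",
    "detrend_linear",
    "baseline_subtract",
    "cluster_average",
    "reject_threshold",
    "ERP_LOWPASS",
    "BANDSTOP_LINE",
    "BANDSTOP_MONITOR",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter specification, applied zero-phase.

    ``band`` is a single edge in Hz for a low-pass, or (low, high) for a
    band-stop.  ``order`` is the design order of the one-way filter; the
    forward-backward application squares the magnitude response.
    """

    kind: Literal["low-pass", "band-stop"]
    band: float | tuple[float, float]
    order: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("low-pass", "band-stop"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        edges = np.atleast_1d(np.asarray(self.band, dtype=float))
        if np.any(edges <= 0):
            raise ValueError("band edges must be positive")
        if self.kind == "band-stop" and (len(edges) != 2 or edges[0] >= edges[1]):
            raise ValueError("band-stop needs (low, high) with low < high")

    def sos(self, srate: float) -> np.ndarray:
        nyq = srate / 2.0
        edges = np.atleast_1d(np.asarray(self.band, dtype=float))
        if np.any(edges >= nyq):
            raise ValueError(f"band edge at or above Nyquist ({nyq} Hz)")
        btype = "lowpass" if self.kind == "low-pass" else "bandstop"
        wn = edges / nyq
        return scipy.signal.butter(self.order, wn if len(wn) > 1 else wn[0], btype, output="sos")

    def gain_at(self, freq_hz: float, srate: float) -> float:
        """Two-pass (forward-backward) magnitude response at one frequency."""
        w, h = scipy.signal.sosfreqz(self.sos(srate), worN=[2 * np.pi * freq_hz / srate])
        return float(np.abs(h[0]) ** 2)


#: the standard specs of the two analysis chains
ERP_LOWPASS = FilterSpec("low-pass", 40.0, order=4)
BANDSTOP_LINE = FilterSpec("band-stop", (49.0, 51.0), order=2)
BANDSTOP_MONITOR = FilterSpec("band-stop", (84.0, 86.0), order=2)


def butterworth_filter(epochs: EpochSet, spec: FilterSpec) -> EpochSet:
    """Zero-phase Butterworth filtering along time, per trial and channel."""
    sos = spec.sos(epochs.srate)
    out = epochs.copy(data=scipy.signal.sosfiltfilt(sos, epochs.data, axis=-1))
    out.log(f"butterworth:{spec.kind}:{spec.band}:order{spec.order}:zero-phase")
    return out


def detrend_linear(epochs: EpochSet) -> EpochSet:
    """Remove the least-squares linear trend per trial and channel."""
    if epochs.data.shape[-1] < 2:
        raise ValueError("need at least two samples to detrend")
    out = epochs.copy(data=scipy.signal.detrend(epochs.data, axis=-1, type="linear"))
    out.log("detrend:linear")
    return out


def baseline_subtract(
    epochs: EpochSet, window_s: tuple[float, float] = (-0.2, 0.0)
) -> EpochSet:
    """Subtract the per-trial/channel mean over the baseline window."""
    mask = epochs.time_mask(window_s)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    baseline = epochs.data[..., mask].mean(axis=-1, keepdims=True)
    out = epochs.copy(data=epochs.data - baseline)
    out.log(f"baseline:{window_s}")
    return out


def cluster_average(
    data: EpochSet | np.ndarray,
    channels: Sequence[str],
    chan_names: Sequence[str] | None = None,
    name: str | None = None,
) -> np.ndarray | EpochSet:
    """Unweighted mean over an electrode cluster.

    With an EpochSet input, returns a single-channel EpochSet named after
    the cluster.  With a plain channels x time (or trials x channels x
    time) array plus ``chan_names``, returns the averaged array with the
    channel axis dropped.
    """
    label = name or "+".join(channels)
    if isinstance(data, EpochSet):
        idx = data.channel_index(channels)
        out = EpochSet(
            data=data.data[:, idx, :].mean(axis=1, keepdims=True),
            srate=data.srate,
            chan_names=[label],
            times=data.times.copy(),
            trials=data.trials.copy(),
            meta={**data.meta, "history": list(data.meta.get("history", []))},
        )
        out.log(f"cluster_average:{label}")
        return out
    if chan_names is None:
        raise ValueError("chan_names required for array input")
    missing = [c for c in channels if c not in chan_names]
    if missing:
        raise KeyError(f"unknown channel label(s): {missing}")
    idx = [list(chan_names).index(c) for c in channels]
    arr = np.asarray(data, dtype=float)
    axis = arr.ndim - 2  # channel axis for (..., channels, time)
    return arr.take(idx, axis=axis).mean(axis=axis)


def common_average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference to the instantaneous mean across channels.

    Off by default throughout the pipeline (data are analysed
    as-recorded); provided as a config option.
    """
    out = epochs.copy(data=epochs.data - epochs.data.mean(axis=1, keepdims=True))
    out.log("reference:common-average")
    return out


def reject_threshold(epochs: EpochSet, abs_uv: float) -> EpochSet:
    """Drop trials whose absolute amplitude exceeds ``abs_uv`` anywhere.

    Simple plumbing rejector (off by default in the pipeline); statistical
    artifact rejection is out of scope.
    """
    if abs_uv <= 0:
        raise ValueError("threshold must be positive")
    keep = np.abs(epochs.data).max(axis=(1, 2)) <= abs_uv
    out = epochs.select_trials(keep)
    out.log(f"reject_threshold:{abs_uv}uV:dropped{int((~keep).sum())}")
    return out
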