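"""ERP component quantification: mean amplitude, local peak, peak-to-peak.

The P1 (85-130 ms, positive) and N1 (145-220 ms, negative) are measured
at two lateral occipital clusters (P7/PO7 and P8/PO8) on the
condition-wise trial average.  Local peak detection follows the
convention of common ERP measurement tools: the in-window extremum that
is not surpassed (in the polarity direction) by any sample within +-5
sampling points — +-9.8 ms at 512 Hz — with the neighbourhood allowed to
extend past the window edge into the epoch; if no sample qualifies, the
absolute in-window extremum is returned flagged ``is_local=False``.
Peak-value ties break toward the earliest latency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .containers import EpochSet
from .design import CELLS
from .montage import CLUSTER_LEFT, CLUSTER_RIGHT
from .preprocess import cluster_average

__all__ = [
    "ComponentWindow",
    "P1_WINDOW",
    "N1_WINDOW",
    "Peak",
    "average_erp",
    "mean_amplitude",
    "local_peak",
    "peak_to_peak",
    "build_measure_table",
]


@dataclass(frozen=True)
class ComponentWindow:
    """Measurement window and polarity of an ERP component."""

    name: str
    window_ms: tuple[float, float]
    polarity: Literal["positive", "negative"]
    neighborhood: int = 5

    def __post_init__(self) -> None:
        if self.window_ms[0] >= self.window_ms[1]:
            raise ValueError("window start must precede end")
        if self.neighborhood < 1:
            raise ValueError("neighbourhood must be >= 1 sample")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")


P1_WINDOW = ComponentWindow("P1", (85.0, 130.0), "positive")
N1_WINDOW = ComponentWindow("N1", (145.0, 220.0), "negative")


class Peak(NamedTuple):
    latency_ms: float
    amplitude: float
    is_local: bool


def average_erp(epochs: EpochSet, cell: tuple[str, str] | None = None) -> np.ndarray:
    """Pointwise trial average (channels x time); all trials included.

    ``cell`` selects (objecthood, frequency); None averages everything.
    The average deliberately includes error trials — ERP measures are not
    conditioned on behavioural performance.
    """
    if cell is None:
        mask = np.ones(epochs.n_trials, dtype=bool)
    else:
        obj, freq = cell
        mask = (
            (epochs.trials["objecthood"] == obj) & (epochs.trials["frequency"] == freq)
        ).to_numpy()
    if not mask.any():
        raise ValueError(f"no trials in cell {cell}")
    return epochs.data[mask].mean(axis=0)


def _window_mask(times_s: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    t_ms = times_s * 1000.0
    mask = (t_ms >= window_ms[0] - 1e-9) & (t_ms <= window_ms[1] + 1e-9)
    if window_ms[0] < t_ms[0] - 1e-9 or window_ms[1] > t_ms[-1] + 1e-9:
        raise ValueError(f"window {window_ms} ms outside epoch")
    return mask


def mean_amplitude(
    waveform: np.ndarray, times_s: np.ndarray, window_ms: tuple[float, float]
) -> float:
    """Mean of the samples whose time falls in the closed window (uV)."""
    mask = _window_mask(times_s, window_ms)
    if not mask.any():
        raise ValueError("window contains no samples")
    return float(np.asarray(waveform, dtype=float)[mask].mean())


def local_peak(
    waveform: np.ndarray, times_s: np.ndarray, comp: ComponentWindow
) -> Peak:
    """Local-peak latency and amplitude within a component window.

    A sample qualifies as a local peak if no sample within
    ``comp.neighborhood`` points on either side (searched over the whole
    epoch, not just the window) exceeds it in the polarity direction.
    Falls back to the absolute in-window extremum with is_local=False.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1:
        raise ValueError("waveform must be one-dimensional")
    sign = 1.0 if comp.polarity == "positive" else -1.0
    v = sign * w
    mask = _window_mask(times_s, comp.window_ms)
    idx_in = np.flatnonzero(mask)
    if idx_in.size == 0:
        raise ValueError("window shorter than one sample")

    k = comp.neighborhood
    # candidates ordered by decreasing (signed) value, earliest-first on ties
    order = idx_in[np.lexsort((idx_in, -v[idx_in]))]
    for i in order:
        lo, hi = max(0, i - k), min(len(v), i + k + 1)
        neighbourhood = v[lo:hi]
        if v[i] >= neighbourhood.max():
            return Peak(float(times_s[i] * 1000.0), float(w[i]), True)
    i = order[0]  # absolute extremum fallback
    return Peak(float(times_s[i] * 1000.0), float(w[i]), False)


def peak_to_peak(p1: Peak, n1: Peak) -> float:
    """P1 peak amplitude minus N1 peak amplitude (uV).

    Positive when the N1 dips below the P1; quantifies the N1 deflection
    independently of the absolute level inherited from the P1.
    """
    return float(p1.amplitude - n1.amplitude)


_DEFAULT_CLUSTERS = {"left": CLUSTER_LEFT, "right": CLUSTER_RIGHT}


def build_measure_table(
    epochs: EpochSet,
    windows: Sequence[ComponentWindow] = (P1_WINDOW, N1_WINDOW),
    clusters: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Long-format component measures per participant x cell x cluster.

    For every design cell and hemisphere cluster: mean amplitude, local
    peak latency and amplitude per component, and the P1-N1 peak-to-peak
    difference.  Input epochs must already be low-pass filtered and
    baseline subtracted.
    """
    clusters = clusters or _DEFAULT_CLUSTERS
    by_name = {w.name: w for w in windows}
    rows = []
    for participant in sorted(epochs.trials["participant"].unique()):
        pmask = (epochs.trials["participant"] == participant).to_numpy()
        sub = epochs.select_trials(pmask)
        for cell in CELLS:
            erp = average_erp(sub, cell)
            for cname, labels in clusters.items():
                wave = cluster_average(erp, labels, chan_names=epochs.chan_names)
                peaks = {}
                for comp in windows:
                    peaks[comp.name] = local_peak(wave, epochs.times, comp)
                    rows.extend(
                        [
                            _row(participant, cell, cname, f"{comp.name}_mean_amp",
                                 mean_amplitude(wave, epochs.times, comp.window_ms), "uV"),
                            _row(participant, cell, cname, f"{comp.name}_peak_lat",
                                 peaks[comp.name].latency_ms, "ms"),
                            _row(participant, cell, cname, f"{comp.name}_peak_amp",
                                 peaks[comp.name].amplitude, "uV"),
                        ]
                    )
                if "P1" in by_name and "N1" in by_name:
                    rows.append(
                        _row(participant, cell, cname, "peak_to_peak",
                             peak_to_peak(peaks["P1"], peaks["N1"]), "uV")
                    )
    return pd.DataFrame(rows)


def _row(participant, cell, cluster, measure, value, units):
    return {
        "participant": participant,
        "objecthood": cell[0],
        "frequency": cell[1],
        "cluster": cluster,
        "measure": measure,
        "value": value,
        "units": units,
    }
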