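"""Synthetic epoched EEG and behaviour with known injected effects.

Every downstream stage (ERP measures, gamma-band power, ANOVA) is tested
by parameter recovery against this generator.  Each trial is the sum of

* 1/f background noise (spectrally shaped white noise, exponent 1);
* 50 Hz line noise and an 85 Hz monitor component (random phase);
* condition-dependent P1 and N1 deflections — Gaussian-windowed
  monophasic bumps whose peak amplitude and peak latency are the injected
  cell parameters, lateralised to parieto-occipital channels;
* a phase-locked 35 Hz burst at ~100 ms (evoked gamma), identical phase
  on every trial;
* a non-phase-locked gamma burst at 200-500 ms with a
  participant-specific centre frequency (induced/total gamma), whose
  phase is drawn independently per trial so it cancels in the trial
  average but survives per-trial power.

Default cell means reproduce the study's printed condition structure
(see docs/methods.md); between-subject variability is additive Gaussian
jitter per participant.  Gaussian component shapes are a synthetic
convention chosen so expected window means are analytic, not an empirical
claim about ERP morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .containers import EpochSet
from .design import CELLS, ExperimentDesign
from .montage import component_gains

__all__ = [
    "GroundTruthEffects",
    "simulate_epochs",
    "iter_participant_epochs",
    "simulate_behavior",
    "gaussian_bump",
    "gaussian_window_mean",
    "P1_SIGMA_MS",
    "N1_SIGMA_MS",
]

Cell = tuple[str, str]

# component shape constants (synthetic conventions)
P1_SIGMA_MS = 12.0
N1_SIGMA_MS = 18.0
EGBA_FREQ_HZ = 35.0
EGBA_CENTER_MS = 100.0
EGBA_SIGMA_MS = 25.0
TGBA_CENTER_MS = 350.0
TGBA_SIGMA_MS = 75.0
P1_HEMI_ASYMMETRY = 0.13  # right-larger P1 topography


def _cells(obj_vals: dict[str, float] | None = None, **by_cell: float) -> dict[Cell, float]:
    out = {}
    for (obj, sf) in CELLS:
        key = f"{obj}_{sf}"
        if key in by_cell:
            out[(obj, sf)] = by_cell[key]
        elif obj_vals is not None:
            out[(obj, sf)] = obj_vals[obj]
    return out


def _const_cells(value: float) -> dict[Cell, float]:
    return {c: value for c in CELLS}


@dataclass
class GroundTruthEffects:
    """Injected per-cell parameters and noise model.

    Amplitudes are peak values in uV at the focal (cluster) channels;
    latencies are the Gaussian centres in ms.  ``*_sd_between`` are
    between-participant standard deviations of an additive offset shared
    by all cells (so within-subject effects are exact in expectation).
    """

    # P1 peak amplitude (uV): additive object + SF + hemisphere structure
    p1_amp: dict[Cell, float] = field(
        default_factory=lambda: _cells(
            object_HSF=3.57, object_BB=4.22, object_LSF=3.24,
            nonobject_HSF=2.95, nonobject_BB=3.60, nonobject_LSF=2.62,
        )
    )
    p1_lat: dict[Cell, float] = field(default_factory=lambda: _const_cells(105.0))
    # N1 signed peak deflection (uV, negative-going); interaction: BB
    # non-objects show a strongly reduced N1
    n1_amp: dict[Cell, float] = field(
        default_factory=lambda: _cells(
            object_HSF=-3.30, object_BB=-2.10, object_LSF=-3.30,
            nonobject_HSF=-3.30, nonobject_BB=-0.08, nonobject_LSF=-1.98,
        )
    )
    # N1 peak latency (ms): objects later than non-objects, HSF later than LSF
    n1_lat: dict[Cell, float] = field(
        default_factory=lambda: _cells(
            object_HSF=177.0, object_BB=172.0, object_LSF=170.0,
            nonobject_HSF=169.0, nonobject_BB=164.0, nonobject_LSF=162.0,
        )
    )
    # phase-locked low-gamma burst amplitude (uV): SF effect, no object
    # effect; calibrated so the evoked percent change from baseline at the
    # default noise model and 80 trials/cell lands on the study scale
    # (HSF ~805%, BB ~619%, LSF ~634%)
    egba_amp: dict[Cell, float] = field(
        default_factory=lambda: _cells(
            object_HSF=3.57, object_BB=3.13, object_LSF=3.17,
            nonobject_HSF=3.57, nonobject_BB=3.13, nonobject_LSF=3.17,
        )
    )
    # induced gamma amplitude (uV): object effect only; calibrated to the
    # total-power percent-change scale (objects ~18.1%, non-objects ~7.6%)
    tgba_amp: dict[Cell, float] = field(
        default_factory=lambda: _cells({"object": 2.23, "nonobject": 1.45})
    )
    # behaviour: lognormal RT cell means (ms) and Bernoulli error rates
    rt_mean_ms: dict[Cell, float] = field(
        default_factory=lambda: _cells(
            object_HSF=642.0, object_BB=580.0, object_LSF=722.5,
            nonobject_HSF=522.0, nonobject_BB=570.0, nonobject_LSF=531.5,
        )
    )
    error_rate: dict[Cell, float] = field(
        default_factory=lambda: _cells(
            object_HSF=0.05, object_BB=0.03, object_LSF=0.13,
            nonobject_HSF=0.01, nonobject_BB=0.01, nonobject_LSF=0.01,
        )
    )
    rt_sigma_log: float = 0.25

    # noise model
    noise_exponent: float = 1.0
    noise_scale_uv: float = 10.0
    line_50hz_uv: float = 2.0
    line_85hz_uv: float = 1.0

    # participant-specific induced-gamma centre frequency range (Hz)
    tgba_freq_range_hz: tuple[float, float] = (52.0, 76.0)
    tgba_freq_hz: float | None = None  # fix for all participants if set

    # between-subject additive offsets (sd)
    amp_sd_between: float = 0.5
    lat_sd_between: float = 5.0
    egba_sd_between: float = 0.5
    tgba_sd_between: float = 0.25
    rt_sd_between: float = 30.0
    error_sd_between: float = 0.005

    def __post_init__(self) -> None:
        for cell, p in self.error_rate.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"error rate outside [0, 1] for cell {cell}")
        if self.noise_scale_uv < 0:
            raise ValueError("noise scale must be non-negative")
        for d in (self.p1_amp, self.n1_amp, self.egba_amp, self.tgba_amp):
            if not all(np.isfinite(list(d.values()))):
                raise ValueError("amplitudes must be finite")

    def zeroed(self) -> "GroundTruthEffects":
        """Copy with all signal amplitudes, noise and jitter set to zero."""
        return replace(
            self,
            p1_amp=_const_cells(0.0), n1_amp=_const_cells(0.0),
            egba_amp=_const_cells(0.0), tgba_amp=_const_cells(0.0),
            noise_scale_uv=0.0, line_50hz_uv=0.0, line_85hz_uv=0.0,
            amp_sd_between=0.0, lat_sd_between=0.0,
            egba_sd_between=0.0, tgba_sd_between=0.0,
        )


def gaussian_bump(times_s: np.ndarray, center_ms: float, sigma_ms: float) -> np.ndarray:
    """Unit-peak Gaussian envelope over a time axis in seconds."""
    t_ms = times_s * 1000.0
    return np.exp(-0.5 * ((t_ms - center_ms) / sigma_ms) ** 2)


def gaussian_window_mean(
    center_ms: float,
    sigma_ms: float,
    window_ms: tuple[float, float],
    srate: float,
    epoch_window_s: tuple[float, float] = (-0.6, 0.9),
) -> float:
    """Expected mean of a unit-peak Gaussian bump over a measurement window.

    Evaluated on the same discrete sample grid the analysis uses, so a
    measured window-mean amplitude equals (injected peak) x (this factor)
    in the noise-free limit.
    """
    n = int(round((epoch_window_s[1] - epoch_window_s[0]) * srate))
    times = epoch_window_s[0] + np.arange(n) / srate
    mask = (times * 1000.0 >= window_ms[0] - 1e-9) & (times * 1000.0 <= window_ms[1] + 1e-9)
    return float(gaussian_bump(times[mask], center_ms, sigma_ms).mean())


def _one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, ...], exponent: float, scale: float
) -> np.ndarray:
    """Spectrally shaped white noise with power ~ 1/f**exponent, unit-sd then scaled."""
    if scale == 0.0:
        return np.zeros(shape)
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    k = np.arange(spec.shape[-1], dtype=float)
    weights = np.zeros_like(k)
    weights[1:] = k[1:] ** (-exponent / 2.0)  # amplitude weighting; DC removed
    shaped = np.fft.irfft(spec * weights, n=n, axis=-1)
    # analytic output variance of unit-variance white input through the weights
    w2 = weights**2
    var = (w2[0] + 2.0 * w2[1:-1].sum() + (w2[-1] if n % 2 == 0 else 2.0 * w2[-1])) / n
    return shaped * (scale / np.sqrt(var))


def _participant_rng(seed: int, participant: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, participant])


def _jitter(truth: GroundTruthEffects, rng: np.random.Generator) -> dict:
    """Draw one additive offset per parameter family for a participant."""
    return {
        "p1_amp": rng.normal(0.0, truth.amp_sd_between),
        "n1_amp": rng.normal(0.0, truth.amp_sd_between),
        "p1_lat": rng.normal(0.0, truth.lat_sd_between),
        "n1_lat": rng.normal(0.0, truth.lat_sd_between),
        "egba_amp": rng.normal(0.0, truth.egba_sd_between),
        "tgba_amp": rng.normal(0.0, truth.tgba_sd_between),
        "tgba_freq": (
            truth.tgba_freq_hz
            if truth.tgba_freq_hz is not None
            else rng.uniform(*truth.tgba_freq_range_hz)
        ),
    }


def _simulate_one_participant(
    schedule_p: pd.DataFrame,
    truth: GroundTruthEffects,
    seed: int,
    design: ExperimentDesign,
    channels: Sequence[str],
) -> EpochSet:
    p = int(schedule_p["participant"].iloc[0])
    rng = _participant_rng(seed, p, 0xEE6)
    jit = _jitter(truth, rng)

    srate = design.srate
    t0, t1 = design.epoch_window_s
    n_times = int(round((t1 - t0) * srate))
    times = t0 + np.arange(n_times) / srate
    n_chan = len(channels)
    n_trials = len(schedule_p)

    gains_erp = component_gains(list(channels), "erp")
    gains_p1 = component_gains(list(channels), "erp", hemi_asymmetry=P1_HEMI_ASYMMETRY)
    gains_egba = component_gains(list(channels), "egba")
    gains_tgba = component_gains(list(channels), "tgba")

    data = _one_over_f_noise(
        rng, (n_trials, n_chan, n_times), truth.noise_exponent, truth.noise_scale_uv
    )
    for freq_hz, amp in ((50.0, truth.line_50hz_uv), (85.0, truth.line_85hz_uv)):
        if amp > 0:
            phase = rng.uniform(0.0, 2.0 * np.pi, size=(n_trials, n_chan, 1))
            data += amp * np.sin(2.0 * np.pi * freq_hz * times[None, None, :] + phase)

    obj = schedule_p["objecthood"].to_numpy()
    freq = schedule_p["frequency"].to_numpy()
    for cell in CELLS:
        mask = (obj == cell[0]) & (freq == cell[1])
        if not mask.any():
            continue
        n_cell = int(mask.sum())
        p1 = (truth.p1_amp[cell] + jit["p1_amp"]) * gaussian_bump(
            times, truth.p1_lat[cell] + jit["p1_lat"], P1_SIGMA_MS
        )
        n1 = (truth.n1_amp[cell] + jit["n1_amp"]) * gaussian_bump(
            times, truth.n1_lat[cell] + jit["n1_lat"], N1_SIGMA_MS
        )
        erp = gains_p1[:, None] * p1[None, :] + gains_erp[:, None] * n1[None, :]

        egba_amp = max(truth.egba_amp[cell] + jit["egba_amp"], 0.0)
        egba = (
            egba_amp
            * gaussian_bump(times, EGBA_CENTER_MS, EGBA_SIGMA_MS)
            * np.cos(2.0 * np.pi * EGBA_FREQ_HZ * times)
        )  # fixed zero phase on every trial: fully phase-locked
        cell_common = erp + gains_egba[:, None] * egba[None, :]
        data[mask] += cell_common[None, :, :]

        tgba_amp = max(truth.tgba_amp[cell] + jit["tgba_amp"], 0.0)
        if tgba_amp > 0:
            env = gaussian_bump(times, TGBA_CENTER_MS, TGBA_SIGMA_MS)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_cell, 1, 1))
            burst = (
                tgba_amp
                * env[None, None, :]
                * np.cos(2.0 * np.pi * jit["tgba_freq"] * times[None, None, :] + phases)
            )
            data[mask] += burst * gains_tgba[None, :, None]

    meta = {
        "history": ["simulate_epochs"],
        "truth_tgba_freq_hz": jit["tgba_freq"],
        "seed": seed,
    }
    return EpochSet(
        data=data,
        srate=srate,
        chan_names=list(channels),
        times=times,
        trials=schedule_p.reset_index(drop=True),
        meta=meta,
    )


def simulate_epochs(
    schedule: pd.DataFrame,
    truth: GroundTruthEffects,
    seed: int,
    *,
    design: ExperimentDesign | None = None,
    channels: Sequence[str] | None = None,
    participants: Sequence[int] | None = None,
) -> EpochSet:
    """Simulate epoched EEG for (a subset of) the scheduled participants.

    Results for a given participant are identical whether generated alone
    or as part of the full study (per-participant random streams).
    """
    design = design or ExperimentDesign()
    channels = list(channels) if channels is not None else list(design.channels)
    if participants is None:
        participants = sorted(schedule["participant"].unique())
    parts = [
        _simulate_one_participant(
            schedule[schedule["participant"] == p], truth, seed, design, channels
        )
        for p in participants
    ]
    if len(parts) == 1:
        return parts[0]
    return EpochSet(
        data=np.concatenate([e.data for e in parts]),
        srate=parts[0].srate,
        chan_names=list(channels),
        times=parts[0].times,
        trials=pd.concat([e.trials for e in parts], ignore_index=True),
        meta={"history": ["simulate_epochs"], "seed": seed},
    )


def iter_participant_epochs(
    schedule: pd.DataFrame,
    truth: GroundTruthEffects,
    seed: int,
    *,
    design: ExperimentDesign | None = None,
    channels: Sequence[str] | None = None,
) -> Iterator[EpochSet]:
    """Yield one participant's EpochSet at a time (memory-friendly)."""
    design = design or ExperimentDesign()
    channels = list(channels) if channels is not None else list(design.channels)
    for p in sorted(schedule["participant"].unique()):
        yield _simulate_one_participant(
            schedule[schedule["participant"] == p], truth, seed, design, channels
        )


# response taxonomy: conditional error-type probabilities given an error
_OBJECT_ERROR_TYPES = (("wrong-category", 0.70), ("object-as-nonobject", 0.15), ("miss", 0.15))
_NONOBJECT_ERROR_TYPES = (("nonobject-as-object", 0.50), ("miss", 0.50))


def simulate_behavior(
    schedule: pd.DataFrame, truth: GroundTruthEffects, seed: int
) -> pd.DataFrame:
    """Simulate RTs (lognormal, cell-shifted) and categorisation responses.

    Errors are Bernoulli per cell and split into distinguishable types:
    for objects — wrong category (man-made vs natural), calling an object
    a non-object, or a miss; for non-objects — calling it an object, or a
    miss.  Misses get NaN reaction times.
    """
    frames = []
    for p in sorted(schedule["participant"].unique()):
        rng = _participant_rng(seed, int(p), 0xBE4)
        sp = schedule[schedule["participant"] == p].reset_index(drop=True)
        rt_off = rng.normal(0.0, truth.rt_sd_between)
        err_off = rng.normal(0.0, truth.error_sd_between)
        n = len(sp)
        rts = np.empty(n)
        responses = np.empty(n, dtype=object)
        correct = np.zeros(n, dtype=bool)
        for i, row in sp.iterrows():
            cell = (row["objecthood"], row["frequency"])
            mu = truth.rt_mean_ms[cell] + rt_off
            sig = truth.rt_sigma_log
            rts[i] = rng.lognormal(np.log(mu) - sig**2 / 2.0, sig)
            p_err = float(np.clip(truth.error_rate[cell] + err_off, 0.0, 1.0))
            if rng.random() < p_err:
                types = (
                    _OBJECT_ERROR_TYPES
                    if row["objecthood"] == "object"
                    else _NONOBJECT_ERROR_TYPES
                )
                names, probs = zip(*types)
                kind = names[rng.choice(len(names), p=np.array(probs))]
                if kind == "miss":
                    responses[i] = "none"
                    rts[i] = np.nan
                elif kind == "wrong-category":
                    responses[i] = "natural" if row["category"] == "man-made" else "man-made"
                elif kind == "object-as-nonobject":
                    responses[i] = "nonobject"
                else:  # nonobject-as-object
                    responses[i] = "man-made"
            else:
                correct[i] = True
                responses[i] = (
                    row["category"] if row["objecthood"] == "object" else "nonobject"
                )
        out = sp.copy()
        out["rt_ms"] = rts
        out["response"] = responses
        out["correct"] = correct
        frames.append(out)
    return pd.concat(frames, ignore_index=True)
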