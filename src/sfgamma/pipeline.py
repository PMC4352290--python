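"""Configuration-driven orchestration: simulate -> preprocess -> ERP ->
time-frequency -> statistics, with logging and provenance.

A run writes, under its output directory: the trial schedule and
behaviour tables (TSV), the long-format measure table (CSV), one ANOVA
table per measure (CSV), a plain-text report with APA-style lines and
condition means, a JSON manifest (config hash, stage order, package
versions, per-stage wall-clock), and optionally the first participant's
epochs as an HDF5 container.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .containers import EpochSet
from .design import ExperimentDesign, generate_design
from .erp import build_measure_table
from .io import write_epochs
from .montage import CHANNELS_64, CHANNELS_POSTERIOR_14
from .preprocess import (
    BANDSTOP_LINE,
    BANDSTOP_MONITOR,
    ERP_LOWPASS,
    baseline_subtract,
    butterworth_filter,
    common_average_reference,
    detrend_linear,
)
from .simulate import GroundTruthEffects, iter_participant_epochs, simulate_behavior
from .stats import anova_report, rm_anova
from .tfr import MultitaperSpec, build_gamma_table

__all__ = ["RunConfig", "run_pipeline", "erp_chain", "tfr_chain"]

_CELL_FIELDS = {
    "p1_amp", "p1_lat", "n1_amp", "n1_lat", "egba_amp", "tgba_amp",
    "rt_mean_ms", "error_rate",
}
_SCALAR_FIELDS = {
    "rt_sigma_log", "noise_exponent", "noise_scale_uv", "line_50hz_uv",
    "line_85hz_uv", "tgba_freq_hz", "amp_sd_between", "lat_sd_between",
    "egba_sd_between", "tgba_sd_between", "rt_sd_between", "error_sd_between",
}


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    n_participants: int = Field(default=15, ge=1)
    trials_per_cell: int = Field(default=80, ge=2)
    n_blocks: int = Field(default=6, ge=1)
    montage: Literal["full", "posterior"] = "posterior"
    seed: int = 0
    out_dir: str = "sfgamma_run"
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    erp_lowpass_hz: float = 40.0
    mt_window_s: float = 0.25
    mt_n_tapers: int = 5
    egba_band_hz: tuple[float, float] = (30.0, 60.0)
    gg_policy: Literal["mauchly", "always", "never"] = "mauchly"
    common_average_reference: bool = False
    save_epochs: bool = False
    truth: dict = Field(default_factory=dict)

    @field_validator("truth")
    @classmethod
    def _known_truth_keys(cls, v: dict) -> dict:
        unknown = set(v) - _CELL_FIELDS - _SCALAR_FIELDS
        if unknown:
            raise ValueError(f"unknown ground-truth field(s): {sorted(unknown)}")
        return v

    def build_truth(self) -> GroundTruthEffects:
        truth = GroundTruthEffects()
        for key, val in self.truth.items():
            if key in _CELL_FIELDS:
                base = dict(getattr(truth, key))
                if isinstance(val, dict):
                    for cell_key, x in val.items():
                        obj, sf = cell_key.split("_")
                        base[(obj, sf)] = float(x)
                else:
                    base = {c: float(val) for c in base}
                setattr(truth, key, base)
            else:
                setattr(truth, key, val if val is None else float(val))
        truth.__post_init__()
        return truth

    def build_design(self) -> ExperimentDesign:
        channels = CHANNELS_64 if self.montage == "full" else CHANNELS_POSTERIOR_14
        return ExperimentDesign(
            n_participants=self.n_participants,
            trials_per_cell=self.trials_per_cell,
            n_blocks=self.n_blocks,
            channels=list(channels),
        )


def erp_chain(epochs: EpochSet, config: RunConfig) -> EpochSet:
    """(Optional re-reference ->) low-pass -> baseline subtraction."""
    if config.common_average_reference:
        epochs = common_average_reference(epochs)
    spec = ERP_LOWPASS if config.erp_lowpass_hz == 40.0 else \
        type(ERP_LOWPASS)("low-pass", config.erp_lowpass_hz, order=ERP_LOWPASS.order)
    out = butterworth_filter(epochs, spec)
    lo, hi = config.baseline_ms
    return baseline_subtract(out, (lo / 1000.0, hi / 1000.0))


def tfr_chain(epochs: EpochSet, config: RunConfig) -> EpochSet:
    """(Optional re-reference ->) band-stop (line + monitor) -> detrend."""
    if config.common_average_reference:
        epochs = common_average_reference(epochs)
    out = butterworth_filter(epochs, BANDSTOP_LINE)
    out = butterworth_filter(out, BANDSTOP_MONITOR)
    return detrend_linear(out)


def _cell_means(measures: pd.DataFrame, measure: str) -> pd.DataFrame:
    sub = measures[measures["measure"] == measure]
    return (
        sub.groupby(["objecthood", "frequency"])["value"].mean().unstack().round(3)
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full study replica; deterministic given the seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.model_dump(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "package_version": __version__,
        "stages": [],
    }

    def stage(name):
        manifest["stages"].append({"name": name, "t_start": time.time()})
        return name

    def done():
        manifest["stages"][-1]["seconds"] = round(
            time.time() - manifest["stages"][-1].pop("t_start"), 2
        )

    design = config.build_design()
    truth = config.build_truth()
    mt_spec = MultitaperSpec(window_s=config.mt_window_s, n_tapers=config.mt_n_tapers)

    try:
        stage("design")
        schedule = generate_design(design, config.seed)
        schedule.to_csv(out / "schedule.tsv", sep="\t", index=False)
        done()

        stage("behavior")
        behavior = simulate_behavior(schedule, truth, config.seed)
        behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
        done()

        stage("eeg_measures")
        erp_tables, gamma_tables = [], []
        for ep in iter_participant_epochs(schedule, truth, config.seed, design=design):
            if config.save_epochs and not (out / "epochs_p1.h5").exists():
                write_epochs(ep, out / "epochs_p1.h5")
            erp_tables.append(build_measure_table(erp_chain(ep, config)))
            gamma_tables.append(
                build_gamma_table(tfr_chain(ep, config), mt_spec,
                                  egba_band_hz=config.egba_band_hz)
            )
        measures = pd.concat(erp_tables + gamma_tables, ignore_index=True)
        measures.to_csv(out / "measures.csv", index=False)
        done()

        stage("stats")
        report_parts = []
        # behaviour: RT on correct trials only; errors include every trial
        correct = behavior[behavior["correct"]]
        rt_cells = (
            correct.groupby(["participant", "objecthood", "frequency"], sort=False)["rt_ms"]
            .mean().reset_index()
        )
        behavior = behavior.assign(error=~behavior["correct"])
        err_cells = (
            behavior.groupby(["participant", "objecthood", "frequency"], sort=False)["error"]
            .mean().mul(100.0).reset_index()
        )
        anovas = {}
        anovas["rt"] = rm_anova(rt_cells, "rt_ms", ["objecthood", "frequency"],
                                gg_policy=config.gg_policy)
        report_parts.append(anova_report(anovas["rt"], "reaction time (ms, correct trials)"))
        anovas["errors"] = rm_anova(err_cells, "error", ["objecthood", "frequency"],
                                    gg_policy=config.gg_policy)
        report_parts.append(anova_report(anovas["errors"], "errors (%)"))

        for measure, factors in [
            ("P1_mean_amp", ["objecthood", "frequency", "cluster"]),
            ("N1_mean_amp", ["objecthood", "frequency", "cluster"]),
            ("P1_peak_lat", ["objecthood", "frequency", "cluster"]),
            ("N1_peak_lat", ["objecthood", "frequency", "cluster"]),
            ("peak_to_peak", ["objecthood", "frequency", "cluster"]),
            ("egba", ["objecthood", "frequency"]),
            ("tgba", ["objecthood", "frequency", "cluster"]),
        ]:
            sub = measures[measures["measure"] == measure]
            anovas[measure] = rm_anova(sub, "value", factors, gg_policy=config.gg_policy)
            report_parts.append(anova_report(anovas[measure], measure))
            report_parts.append(f"cell means ({measure}):\n{_cell_means(measures, measure)}\n")
        for name, table in anovas.items():
            table.to_csv(out / f"anova_{name}.csv", index=False)
        (out / "report.txt").write_text("\n\n".join(report_parts) + "\n")
        done()
    except Exception as err:  # tag the failing stage for the caller
        failed = manifest["stages"][-1]["name"] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline stage '{failed}' failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
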