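"""Experimental design: trial schedules with source-image counterbalancing.

The study crosses objecthood (object / non-object) with spatial frequency
(HSF / BB / LSF) within subjects: 80 trials per cell, 480 per participant,
in 6 blocks of 80.  Each participant sees every source image twice (once
intact, once phase-scrambled) at a single spatial-frequency level; the
assignment of sources to levels rotates Latin-square fashion across
participants so that, pooled over any three consecutive participants,
every source appears at every level exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import CHANNELS_64

__all__ = ["ExperimentDesign", "generate_design", "SF_LEVELS", "OBJECTHOOD_LEVELS", "CELLS"]

SF_LEVELS = ["HSF", "BB", "LSF"]
OBJECTHOOD_LEVELS = ["object", "nonobject"]
#: the six design cells in canonical order
CELLS = [(o, f) for o in OBJECTHOOD_LEVELS for f in SF_LEVELS]


@dataclass
class ExperimentDesign:
    """Design parameters; defaults are the study conditions."""

    n_participants: int = 15
    trials_per_cell: int = 80
    n_blocks: int = 6
    srate: float = 512.0
    channels: list[str] = field(default_factory=lambda: list(CHANNELS_64))
    epoch_window_s: tuple[float, float] = (-0.6, 0.9)
    # fixation 500-800 ms, stimulus 500 ms, post-fixation 1000 ms, blank 900-1200 ms
    timing_ms: dict = field(
        default_factory=lambda: {
            "fixation": (500, 800),
            "stimulus": 500,
            "post_fixation": 1000,
            "blank": (900, 1200),
        }
    )

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if self.trials_per_cell < 1:
            raise ValueError("need at least one trial per cell")
        if self.total_trials % self.n_blocks != 0:
            raise ValueError(
                f"{self.n_blocks} blocks do not divide {self.total_trials} trials evenly"
            )

    @property
    def total_trials(self) -> int:
        return self.trials_per_cell * 6

    @property
    def n_sources(self) -> int:
        # every source appears once per objecthood at one SF level
        return self.trials_per_cell * 3


def generate_design(design: ExperimentDesign, seed: int) -> pd.DataFrame:
    """Generate the full multi-participant trial schedule.

    Returns a long table with one row per trial: participant (1-based),
    trial (presentation order within participant), block, objecthood,
    frequency, source_id, category.  Sources alternate man-made / natural
    by id; each spatial-frequency group therefore contains equal halves,
    which requires an even ``trials_per_cell``.
    """
    if design.trials_per_cell % 2 != 0:
        raise ValueError(
            "trials_per_cell must be even to split each cell into "
            "man-made and natural halves"
        )
    if design.n_participants % 3 != 0:
        warnings.warn(
            "participant count not divisible by 3: source-to-frequency "
            "counterbalancing is incomplete over the whole sample",
            stacklevel=2,
        )

    n_src = design.n_sources
    source_ids = np.arange(n_src)
    categories = np.where(source_ids % 2 == 0, "man-made", "natural")
    # three balanced groups; group membership fixed, level assignment rotates
    groups = [source_ids[g::3] for g in range(3)]

    block_len = design.total_trials // design.n_blocks
    frames = []
    for p in range(1, design.n_participants + 1):
        rng = np.random.default_rng([seed, 0x5EED, p])
        rows = {"objecthood": [], "frequency": [], "source_id": []}
        for g, grp in enumerate(groups):
            sf = SF_LEVELS[(g + (p - 1)) % 3]
            for src in grp:
                for obj in OBJECTHOOD_LEVELS:
                    rows["objecthood"].append(obj)
                    rows["frequency"].append(sf)
                    rows["source_id"].append(int(src))
        df = pd.DataFrame(rows)
        order = rng.permutation(len(df))
        df = df.iloc[order].reset_index(drop=True)
        df.insert(0, "participant", p)
        df.insert(1, "trial", np.arange(len(df)))
        df.insert(2, "block", np.arange(len(df)) // block_len)
        df["category"] = categories[df["source_id"].to_numpy()]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
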