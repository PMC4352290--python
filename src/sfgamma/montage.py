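"""Channel labels and cluster definitions.

A 64-channel 10-10 label set stands in for the recording montage; no 3-D
head geometry is modelled.  Cluster membership (analysis regions) and the
coarse scalp topographies used by the synthetic generator are defined by
label lists, mirroring how analysis clusters are specified in practice.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CHANNELS_64",
    "CHANNELS_POSTERIOR_14",
    "CLUSTER_LEFT",
    "CLUSTER_RIGHT",
    "CLUSTER_OCCIPITAL",
    "CLUSTER_TGBA_LEFT",
    "CLUSTER_TGBA_RIGHT",
    "component_gains",
]

CHANNELS_64: list[str] = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
]
assert len(CHANNELS_64) == 64 and len(set(CHANNELS_64)) == 64

#: reduced posterior montage for fast simulations — covers every analysis cluster
CHANNELS_POSTERIOR_14: list[str] = [
    "Cz", "Pz", "P5", "P6", "P7", "P8", "PO7", "PO8",
    "PO3", "POz", "PO4", "O1", "Oz", "O2",
]

# ERP analysis clusters: lateral occipital electrode pairs
CLUSTER_LEFT = ["P7", "PO7"]
CLUSTER_RIGHT = ["P8", "PO8"]
# evoked gamma: occipital cluster
CLUSTER_OCCIPITAL = ["O1", "Oz", "O2", "POz"]
# total gamma: bilaterally symmetric posterior clusters
CLUSTER_TGBA_LEFT = ["P7", "PO7", "O1"]
CLUSTER_TGBA_RIGHT = ["P8", "PO8", "O2"]

_LEFT = CLUSTER_LEFT
_RIGHT = CLUSTER_RIGHT


def _is_posterior(label: str) -> bool:
    return label[0] in ("P", "O", "I") and not label.startswith("Fp")


def component_gains(
    labels: list[str],
    component: str,
    *,
    hemi_asymmetry: float = 0.0,
) -> np.ndarray:
    """Per-channel scalp gain of an injected component.

    Focal channels (the component's analysis cluster) get unit gain,
    other posterior channels 0.5, anterior channels 0.1.  A positive
    ``hemi_asymmetry`` a scales right-cluster channels by ``1 + a`` and
    left-cluster channels by ``1 - a`` (used for the P1's right-larger
    topography).
    """
    focal = {
        "erp": set(CLUSTER_LEFT + CLUSTER_RIGHT),
        "egba": set(CLUSTER_OCCIPITAL),
        "tgba": set(CLUSTER_TGBA_LEFT + CLUSTER_TGBA_RIGHT),
    }[component]
    gains = np.empty(len(labels))
    for i, lab in enumerate(labels):
        if lab in focal:
            gains[i] = 1.0
        elif _is_posterior(lab):
            gains[i] = 0.5
        else:
            gains[i] = 0.1
    if hemi_asymmetry:
        for i, lab in enumerate(labels):
            if lab in _RIGHT:
                gains[i] *= 1.0 + hemi_asymmetry
            elif lab in _LEFT:
                gains[i] *= 1.0 - hemi_asymmetry
    return gains
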