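"""HDF5 epoch container and table I/O.

Schema (version ``1.1``): datasets ``/data`` (trials x channels x time,
float64, uV), ``/times`` (s), ``/srate`` (Hz, scalar), ``/channels``
(UTF-8 labels), ``/trials_tsv`` (the condition table serialised as TSV
text so the container round-trips losslessly as a single file), plus the
processing history under ``/history``.  Files with an older minor version
read with a warning; a different major version is refused.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet

__all__ = ["SCHEMA_VERSION", "write_epochs", "read_epochs"]

SCHEMA_VERSION = "1.1"


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an EpochSet to the HDF5 container."""
    path = Path(path)
    buf = _io.StringIO()
    epochs.trials.to_csv(buf, sep="\t", index=False)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("srate", data=float(epochs.srate))
        f.create_dataset(
            "channels", data=np.array(epochs.chan_names, dtype=h5py.string_dtype())
        )
        f.create_dataset("trials_tsv", data=buf.getvalue())
        f.create_dataset(
            "history",
            data=np.array(epochs.meta.get("history", []), dtype=h5py.string_dtype()),
        )


def read_epochs(path: str | Path) -> EpochSet:
    """Read an EpochSet back; lossless for data, labels, srate and trials."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as err:
        raise OSError(f"not a readable HDF5 epoch container: {path}") from err
    with f:
        version = f.attrs.get("schema_version")
        if version is None:
            raise ValueError(f"{path}: missing schema version; not an epoch container")
        major, minor = (int(x) for x in str(version).split("."))
        ours_major, ours_minor = (int(x) for x in SCHEMA_VERSION.split("."))
        if major != ours_major:
            raise ValueError(
                f"{path}: unsupported schema major version {version} "
                f"(this reader supports {SCHEMA_VERSION})"
            )
        if minor < ours_minor:
            warnings.warn(
                f"{path}: older schema minor version {version}; reading anyway",
                stacklevel=2,
            )
        required = ("data", "times", "srate", "channels", "trials_tsv")
        missing = [k for k in required if k not in f]
        if missing:
            raise ValueError(f"{path}: container missing dataset(s) {missing}")
        trials = pd.read_csv(_io.StringIO(f["trials_tsv"][()].decode()), sep="\t")
        history = [h.decode() for h in f["history"][()]] if "history" in f else []
        return EpochSet(
            data=f["data"][()],
            srate=float(f["srate"][()]),
            chan_names=[c.decode() for c in f["channels"][()]],
            times=f["times"][()],
            trials=trials,
            meta={"history": history, "schema_version": str(version)},
        )
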