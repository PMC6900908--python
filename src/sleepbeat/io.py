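"""Recording I/O.

Native format is a delimited matrix: ``<stem>.tsv`` holding samples x channels
(header = channel labels) next to a ``<stem>.json`` sidecar with sample rate
and epoch markers.  EDF files are read through :mod:`mne` when available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import EegRecording

__all__ = ["save_recording", "load_recording", "read_edf"]


def save_recording(rec: EegRecording, stem) -> tuple[Path, Path]:
    """Write ``<stem>.tsv`` (samples x channels) and ``<stem>.json`` sidecar."""
    stem = Path(stem)
    tsv, sidecar = stem.with_suffix(".tsv"), stem.with_suffix(".json")
    pd.DataFrame(rec.data.T, columns=list(rec.channels)).to_csv(
        tsv, sep="\t", index=False, float_format="%.4f"
    )
    sidecar.write_text(json.dumps({
        "sample_rate": rec.sample_rate,
        "channels": list(rec.channels),
        "epochs": {k: list(v) for k, v in rec.epochs.items()},
    }, indent=1))
    return tsv, sidecar


def load_recording(stem) -> EegRecording:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    df = pd.read_csv(stem.with_suffix(".tsv"), sep="\t")
    if list(df.columns) != meta["channels"]:
        raise ValueError("sidecar channel labels disagree with matrix header")
    return EegRecording(
        data=df.to_numpy().T,
        sample_rate=float(meta["sample_rate"]),
        channels=tuple(meta["channels"]),
        epochs={k: tuple(v) for k, v in meta["epochs"].items()},
    )


def read_edf(path, epochs: dict[str, tuple[float, float]] | None = None) -> EegRecording:
    """Read an EDF recording (microvolts) via mne; epoch markers supplied separately."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EegRecording(
        data=raw.get_data() * 1e6,
        sample_rate=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        epochs=epochs or {},
    )
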