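"""CSV / NPZ readers and writers for the pipeline's tabular artifacts.

Uptake tables and feature matrices are CSV (subjects x columns, labeled
header, subject id index). Networks are labeled square CSV. EEG recordings
use an NPZ container holding the channels x samples array, the sampling
rate and the channel labels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .metabolic import IndividualNetwork
from .synthetic import EEGRecording, UptakeMatrix

__all__ = [
    "write_uptake", "read_uptake", "write_network", "read_network",
    "write_eeg", "read_eeg", "write_features", "read_features",
]


def write_uptake(um: UptakeMatrix, path: str | Path) -> None:
    um.to_frame().rename_axis("subject_id").to_csv(path)


def read_uptake(path: str | Path) -> UptakeMatrix:
    df = pd.read_csv(path, index_col=0)
    return UptakeMatrix(
        df.to_numpy(float), list(df.columns), [str(i) for i in df.index]
    )


def write_network(net: IndividualNetwork, path: str | Path) -> None:
    pd.DataFrame(net.W, index=net.region_labels, columns=net.region_labels).to_csv(path)


def read_network(path: str | Path, subject_id: str | None = None) -> IndividualNetwork:
    df = pd.read_csv(path, index_col=0)
    sid = subject_id if subject_id is not None else Path(path).stem
    return IndividualNetwork(df.to_numpy(float), sid, list(df.columns))


def write_eeg(rec: EEGRecording, path: str | Path) -> None:
    np.savez(
        path, data=rec.data, fs=rec.fs,
        channel_labels=np.array(rec.channel_labels),
    )


def read_eeg(path: str | Path) -> EEGRecording:
    with np.load(path, allow_pickle=False) as z:
        return EEGRecording(
            z["data"], float(z["fs"]), [str(c) for c in z["channel_labels"]]
        )


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    df.rename_axis("subject_id").to_csv(path)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
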