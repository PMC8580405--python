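"""On-disk formats: recording matrix + JSON sidecar, coherence matrix CSV.

A recording is stored as a plain delimited numeric matrix (rows = regions,
columns = samples) next to a ``<stem>.json`` sidecar holding the sampling
rate, region labels, lesion side and any provenance metadata.  Coherence
matrices are square CSVs with region labels as header row and index column,
plus a sidecar recording the band and epoch count.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import RegionRecording


def write_recording(rec: RegionRecording, path: str | Path) -> Path:
    """Write ``rec`` to ``path`` (.csv) with a ``.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter=",")
    sidecar = {
        "fs": rec.fs,
        "labels": rec.labels,
        "lesion_side": rec.lesion_side,
        "meta": rec.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path) -> RegionRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    return RegionRecording(
        data=data,
        fs=sidecar["fs"],
        labels=list(sidecar["labels"]),
        lesion_side=sidecar["lesion_side"],
        meta=sidecar.get("meta", {}),
    )


def write_matrix(
    values: np.ndarray,
    labels: list[str],
    path: str | Path,
    band: str | None = None,
    n_epochs: int | None = None,
) -> Path:
    """Write a labelled square matrix as CSV with a JSON sidecar."""
    path = Path(path)
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path)
    meta = {"band": band, "n_epochs": n_epochs}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], dict]:
    """Read a labelled square matrix; returns (values, labels, meta)."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return df.to_numpy(dtype=float), list(df.columns), meta
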