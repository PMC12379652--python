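"""Native on-disk format: TSV sample matrix + JSON sidecar.

A recording ``<stem>.tsv`` holds the samples x channels matrix (header row
of channel IDs, 17-significant-digit floats so values round-trip
bit-exactly) and ``<stem>.json`` holds sampling rate, phase, grid geometry
and the channel mask.  Cohorts are a directory of such pairs plus a
``manifest.csv`` (subject, phase, file, label).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_core import MultiChannelRecording, Segmentation, SensorGrid

__all__ = ["write_recording", "read_recording", "write_manifest", "read_manifest"]


def write_recording(rec: MultiChannelRecording, stem: str | Path,
                    fiducials: Segmentation | None = None) -> tuple[Path, Path]:
    """Write ``<stem>.tsv`` + ``<stem>.json``; returns both paths."""
    stem = Path(stem)
    tsv = stem.with_suffix(".tsv")
    meta = stem.with_suffix(".json")
    cols = [f"ch{i:02d}" for i in range(rec.data.shape[1])]
    pd.DataFrame(rec.data, columns=cols).to_csv(
        tsv, sep="\t", index=False, float_format="%.17g"
    )
    sidecar = {
        "fs_hz": rec.fs,
        "phase": rec.phase,
        "grid": {
            "rows": rec.grid.layout[0],
            "cols": rec.grid.layout[1],
            "spacing_m": rec.grid.spacing,
            "positions": rec.grid.positions.tolist(),
        },
        "channel_mask": rec.channel_mask.astype(int).tolist(),
    }
    if fiducials is not None:
        sidecar["fiducials"] = {
            k: getattr(fiducials, k)
            for k in ("qrs_beg", "qrs_end", "t_beg", "t_max", "t_end")
        }
    meta.write_text(json.dumps(sidecar, indent=1))
    return tsv, meta


def read_recording(stem: str | Path):
    """Read a TSV+JSON pair; returns (recording, fiducials or None)."""
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = pd.read_csv(stem.with_suffix(".tsv"), sep="\t",
                       float_precision="round_trip").to_numpy(dtype=float)
    g = meta["grid"]
    grid = SensorGrid(np.asarray(g["positions"], dtype=float),
                      float(g["spacing_m"]), (int(g["rows"]), int(g["cols"])))
    rec = MultiChannelRecording(
        data=data, fs=float(meta["fs_hz"]), grid=grid, phase=meta["phase"],
        channel_mask=np.asarray(meta["channel_mask"], dtype=bool),
    )
    fid = None
    if "fiducials" in meta:
        fid = Segmentation(**{k: int(v) for k, v in meta["fiducials"].items()})
    return rec, fid


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(rows, columns=["subject", "phase", "file", "label"]).to_csv(
        path, index=False
    )
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject", "phase", "file", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return df
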