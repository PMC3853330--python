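"""File output: CSV time series, myelin matrices, snapshot images, reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .cohort import CohortResult
from .engine import INTACT, RECOVERABLE, Snapshot, TimeSeries, UNRECOVERABLE
from .params import Params

# 3-level damage palette (RGB): intact light, recoverable dark, permanent black
PALETTE = {
    INTACT: (200, 230, 200),
    RECOVERABLE: (80, 120, 80),
    UNRECOVERABLE: (0, 0, 0),
}


def write_timeseries_csv(ts: TimeSeries, path: str | Path) -> None:
    ts.to_dataframe().to_csv(path, index=False)


def write_myelin_csv(snap: Snapshot, path: str | Path) -> None:
    np.savetxt(path, snap.myelin, fmt="%.6g", delimiter=",")


def write_snapshot_image(snap: Snapshot, path: str | Path) -> None:
    """One pixel per patch, colored by damage category (lossless PNG)."""
    cats = snap.categories
    rgb = np.zeros((*cats.shape, 3), dtype=np.uint8)
    for code, color in PALETTE.items():
        rgb[cats == code] = color
    Image.fromarray(rgb, mode="RGB").save(path)


def write_cohort_csv(result: CohortResult, path: str | Path) -> None:
    lines = ["seed,final_recoverable,final_unrecoverable,final_total"]
    for seed, rec, unrec, total in zip(
        result.seeds,
        result.final_recoverable,
        result.final_unrecoverable,
        result.final_total,
    ):
        lines.append(f"{seed},{rec:.6g},{unrec:.6g},{total:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def provenance_record(params: Params, **run_info) -> dict:
    """Machine-readable record of a run: resolved config + run metadata."""
    from . import __version__

    return {
        "package": "msabm",
        "version": __version__,
        "params": params.to_dict(),
        **run_info,
    }
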