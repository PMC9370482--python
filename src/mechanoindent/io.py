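"""Readers and writers for the assay's file formats.

Traces and trajectories travel as plain CSV, phase maps as 32-bit float TIFF
(radians), ROI masks as 16-bit integer label TIFF, and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .holography_morphometry import PhaseMap
from .indentation_protocol import IndentationTrain, ProtocolConfig, build_train
from .trace_classification import CellClassification, DualChannelTrace

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_train_csv",
    "read_train_csv",
    "write_phase_tiff",
    "read_phase_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
    "write_classifications_csv",
]


def write_traces_csv(
    traces: Sequence[DualChannelTrace],
    path: str | Path,
    ground_truth_path: Optional[str | Path] = None,
) -> None:
    """Write traces as long-format CSV (time_s, f340, f380, cell_id, group),
    optionally with a ground-truth sidecar CSV."""
    frames = [
        pd.DataFrame(
            {
                "time_s": tr.time_s,
                "f340": tr.f340,
                "f380": tr.f380,
                "cell_id": tr.cell_id,
                "group": tr.group,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if ground_truth_path is not None:
        rows = []
        for tr in traces:
            m = tr.meta
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "responsive": m.get("responsive", False),
                    "activation_index": m.get("activation_index"),
                    "rupture_index": m.get("rupture_index"),
                }
            )
        pd.DataFrame(rows).to_csv(ground_truth_path, index=False)


def read_traces_csv(
    path: str | Path, ground_truth_path: Optional[str | Path] = None
) -> list[DualChannelTrace]:
    df = pd.read_csv(path)
    truth = None
    if ground_truth_path is not None:
        truth = pd.read_csv(ground_truth_path).set_index("cell_id")
    traces = []
    for (cell_id, group), sub in df.groupby(["cell_id", "group"], sort=False):
        meta = {}
        if truth is not None and cell_id in truth.index:
            row = truth.loc[cell_id]
            meta = {
                "responsive": bool(row["responsive"]),
                "activation_index": None
                if pd.isna(row["activation_index"])
                else int(row["activation_index"]),
                "rupture_index": None
                if pd.isna(row["rupture_index"])
                else int(row["rupture_index"]),
            }
        traces.append(
            DualChannelTrace(
                time_s=sub["time_s"].to_numpy(),
                f340=sub["f340"].to_numpy(),
                f380=sub["f380"].to_numpy(),
                cell_id=str(cell_id),
                group=str(group),
                meta=meta,
            )
        )
    return traces


def write_trajectory_csv(traj: pd.DataFrame, path: str | Path) -> None:
    traj.to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"direction": str})


def write_train_csv(
    train: IndentationTrain, path: str | Path, tmax_mean_um: Optional[float] = None
) -> None:
    train.to_frame(tmax_mean_um).to_csv(path, index=False)


def read_train_csv(path: str | Path, config: Optional[ProtocolConfig] = None) -> IndentationTrain:
    """Rebuild a train from its CSV export.

    The protocol config is reconstructed from the step geometry when not
    given explicitly.
    """
    df = pd.read_csv(path)
    d = df["D_um"].to_numpy(dtype=float)
    z = df["Z_um"].to_numpy(dtype=float)
    t0 = df["t_start_s"].to_numpy(dtype=float)
    if config is None:
        h0 = float(d[0] + z[0])
        d_step = float(d[1] - d[0]) if len(d) > 1 else 2.0
        # infer speed and dwell from the step spacing when possible
        if len(d) > 1:
            gap = t0[1] - t0[0]
            # gap = 2 * d[0] / v + dwell; assume the canonical v = 3 um/s
            speed = 3.0
            dwell = max(gap - 2.0 * d[0] / speed, 0.0)
        else:
            speed, dwell = 3.0, 40.0
        config = ProtocolConfig(
            h0_um=h0,
            d_start_um=float(d[0]),
            d_step_um=d_step,
            d_max_um=float(d[-1]),
            speed_um_s=speed,
            dwell_s=dwell,
        )
    train = build_train(config, start_time_s=float(t0[0]))
    if len(train.steps) != len(d) or not np.allclose(train.d_um, d):
        raise ValueError("train CSV is inconsistent with the inferred protocol config")
    return train


def write_phase_tiff(pmap: PhaseMap, path: str | Path) -> None:
    tifffile.imwrite(path, pmap.phase.astype(np.float32))


def read_phase_tiff(path: str | Path, wavelength_nm: float = 635.0) -> PhaseMap:
    return PhaseMap(phase=tifffile.imread(path).astype(float), wavelength_nm=wavelength_nm)


def write_mask_tiff(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))


def read_mask_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_classifications_csv(
    classifications: Sequence[CellClassification], path: str | Path
) -> None:
    rows = []
    for c in classifications:
        rows.append(
            {
                "cell_id": c.cell_id,
                "group": c.group,
                "responsive": c.responsive,
                "step_index": c.step_index,
                "activation_delta_um": c.delta_um,
                "rupture_time_s": c.rupture_time_s,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
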