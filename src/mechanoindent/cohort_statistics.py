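"""Activation-rate statistics and threshold selection for cell cohorts.

The mechanosensitivity of a group is summarised by its activation rate

    AR = 100 * (# responsive cells) / (# tested cells),

optionally resolved by indentation depth (``AR_delta``, the same fraction
binned by the depth that elicited the response).  Because the classification
depends on the ratio threshold ``R_T``, the full sweep of ``AR(R_T)`` over
[0, 4.5] is computed for every group; the working threshold is the median of
the stable interval bounded below by the point where the calcium-free
control's AR vanishes (the noise regime ends) and above by the last point at
which any group still responds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .indentation_protocol import DepthMap, IndentationTrain
from .trace_classification import (
    CellClassification,
    DualChannelTrace,
    classify_cell,
    detect_activation_peaks,
    detect_rupture,
    normalize_ratio,
)

__all__ = [
    "SweepCurve",
    "CohortReport",
    "activation_rate",
    "activation_rate_at_depth",
    "threshold_sweep",
    "select_threshold",
    "build_report",
    "default_sweep_grid",
]

UNASSIGNED = "unassigned"


def default_sweep_grid(lo: float = 0.0, hi: float = 4.5, step: float = 0.1) -> np.ndarray:
    return np.round(np.arange(lo, hi + step / 2, step), 10)


@dataclass(frozen=True)
class SweepCurve:
    """AR (percent) as a function of the classification threshold per group."""

    grid: np.ndarray
    ar_percent: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        if len(grid) < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("threshold grid must be strictly increasing")
        if grid[0] < 0 or grid[-1] > 4.5:
            raise ValueError("threshold grid must lie within [0, 4.5]")
        for g, ar in self.ar_percent.items():
            ar = np.asarray(ar, dtype=float)
            if len(ar) != len(grid):
                raise ValueError(f"AR curve for group {g!r} does not match the grid")


@dataclass
class CohortReport:
    """Aggregated activation statistics for all groups at the selected R_T."""

    selected_rt: float
    ar_percent: dict[str, float]
    ar_delta: dict[str, dict[str, float]]  #: per group: delta (um, as str key) -> AR_delta %
    n_per_group: dict[str, int]
    sweep: SweepCurve
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "selected_rt": self.selected_rt,
            "ar_percent": self.ar_percent,
            "ar_delta": self.ar_delta,
            "n_per_group": self.n_per_group,
            "sweep": {
                "grid": self.sweep.grid.tolist(),
                "ar_percent": {g: np.asarray(a).tolist() for g, a in self.sweep.ar_percent.items()},
            },
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "CohortReport":
        return cls(
            selected_rt=float(d["selected_rt"]),
            ar_percent={g: float(v) for g, v in d["ar_percent"].items()},
            ar_delta={g: {k: float(v) for k, v in h.items()} for g, h in d["ar_delta"].items()},
            n_per_group={g: int(v) for g, v in d["n_per_group"].items()},
            sweep=SweepCurve(
                grid=np.asarray(d["sweep"]["grid"], dtype=float),
                ar_percent={
                    g: np.asarray(a, dtype=float) for g, a in d["sweep"]["ar_percent"].items()
                },
            ),
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def activation_rate(classifications: Sequence[CellClassification]) -> float:
    """AR in percent: responsive cells over tested cells for one group."""
    if len(classifications) == 0:
        raise ValueError("activation rate of an empty group is undefined")
    n_resp = sum(1 for c in classifications if c.responsive)
    return 100.0 * n_resp / len(classifications)


def activation_rate_at_depth(
    classifications: Sequence[CellClassification], depths: DepthMap
) -> dict[str, float]:
    """AR_delta histogram: percentage of cells activated at each depth.

    Keys are the positive depths of the train formatted to two decimals
    (negative-depth, i.e. no-contact, steps are excluded) plus an
    ``"unassigned"`` bin collecting responsive cells whose event could not be
    attributed to a contact indentation.  The bins sum to the group AR.
    """
    if len(classifications) == 0:
        raise ValueError("AR_delta of an empty group is undefined")
    n = len(classifications)
    bins = {f"{d:.2f}": 0 for d in depths.delta_um if d > 0}
    unassigned = 0
    for c in classifications:
        if not c.responsive:
            continue
        if c.delta_um is None or c.delta_um <= 0:
            if c.delta_um is None:
                warnings.warn(
                    f"cell {c.cell_id}: responsive without an assigned depth; "
                    "counted in the 'unassigned' bin",
                    stacklevel=2,
                )
            unassigned += 1
        else:
            bins[f"{c.delta_um:.2f}"] += 1
    out = {k: 100.0 * v / n for k, v in bins.items()}
    out[UNASSIGNED] = 100.0 * unassigned / n
    return out


def threshold_sweep(
    traces: Sequence[DualChannelTrace],
    train: IndentationTrain,
    depths: DepthMap,
    grid: Optional[np.ndarray] = None,
    baseline_window_s: Optional[tuple[float, float]] = None,
    **detector_kwargs,
) -> SweepCurve:
    """Rerun the classification over a grid of thresholds, per group.

    The ratio normalisation, rupture detection and channel-coincidence peak
    search do not depend on ``R_T``; only the threshold test is repeated, so
    the sweep reuses one pass of event detection per trace.  By construction
    the resulting AR curves are non-increasing in ``R_T``.
    """
    grid = default_sweep_grid() if grid is None else np.asarray(grid, dtype=float)
    if baseline_window_s is None:
        baseline_window_s = (0.0, float(train.steps[0].t_start_s))
    rupture_keys = {"drop_fraction", "drop_window_s", "flat_window_s", "flat_sd_max"}
    rupture_kwargs = {k: v for k, v in detector_kwargs.items() if k in rupture_keys}
    peak_kwargs = {k: v for k, v in detector_kwargs.items() if k not in rupture_keys}

    groups: dict[str, list[float]] = {}
    peak_r_by_trace: list[tuple[str, list[float]]] = []
    for tr in traces:
        r = normalize_ratio(tr, baseline_window_s)
        rupture_t = detect_rupture(tr, r, **rupture_kwargs)
        events = detect_activation_peaks(
            r, tr, r_threshold=0.0, rupture_time_s=rupture_t, **peak_kwargs
        )
        peak_r_by_trace.append((tr.group, [e.peak_r for e in events]))
        groups.setdefault(tr.group, [])

    ar_percent: dict[str, np.ndarray] = {}
    for g in groups:
        peaks = [ps for grp, ps in peak_r_by_trace if grp == g]
        n = len(peaks)
        curve = np.array(
            [100.0 * sum(any(p > rt for p in ps) for ps in peaks) / n for rt in grid]
        )
        ar_percent[g] = curve
    return SweepCurve(grid=grid, ar_percent=ar_percent)


def select_threshold(sweep: SweepCurve, control_group: str = "CaFree") -> float:
    """Median of the stable threshold interval.

    The lower bound is the smallest grid threshold at which the calcium-free
    control's AR reaches zero and stays zero (above the noise regime); the
    upper bound is the largest grid threshold at which any group still shows
    a response.  Returns the midpoint.
    """
    if control_group not in sweep.ar_percent:
        raise ValueError(f"control group {control_group!r} not present in the sweep")
    control = np.asarray(sweep.ar_percent[control_group], dtype=float)
    zero_after = np.array([np.all(control[i:] == 0.0) for i in range(len(control))])
    if not zero_after.any():
        raise ValueError(
            "the control group's AR never settles to zero within the sweep; "
            f"control AR at the top of the grid is {control[-1]:.1f}%"
        )
    lower = float(sweep.grid[int(np.argmax(zero_after))])
    any_pos = np.zeros(len(sweep.grid), dtype=bool)
    for curve in sweep.ar_percent.values():
        any_pos |= np.asarray(curve) > 0.0
    if any_pos.any():
        upper = float(sweep.grid[int(np.flatnonzero(any_pos)[-1])])
    else:
        upper = lower
    upper = max(upper, lower)
    return (lower + upper) / 2.0


def build_report(
    classifications: Sequence[CellClassification],
    sweep: SweepCurve,
    selected_rt: float,
    depths: DepthMap,
    provenance: Optional[dict] = None,
) -> CohortReport:
    """Assemble per-group AR and AR_delta at the selected threshold.

    ``classifications`` must have been produced at ``selected_rt``.
    """
    by_group: dict[str, list[CellClassification]] = {}
    for c in classifications:
        by_group.setdefault(c.group, []).append(c)
    return CohortReport(
        selected_rt=float(selected_rt),
        ar_percent={g: activation_rate(cls) for g, cls in by_group.items()},
        ar_delta={g: activation_rate_at_depth(cls, depths) for g, cls in by_group.items()},
        n_per_group={g: len(cls) for g, cls in by_group.items()},
        sweep=sweep,
        provenance=provenance or {},
    )
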