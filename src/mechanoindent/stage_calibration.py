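"""Positioning metrology for a screw-driven stage with backlash.

The stage is calibrated by commanding a saw-tooth trajectory (repeated sweeps
of equal steps forward and backward) while an external interferometer records
the actual position.  From the deviations of measured from target positions
this module computes the ISO-style bidirectional statistics:

* ``E`` -- bidirectional systematic positioning deviation, the span of the
  per-position, per-direction mean deviations;
* ``B+-``, ``B-+`` -- backlash estimates, the offsets between positionings of
  the same target approached from opposite directions;
* ``A`` -- bidirectional positioning accuracy, the span of the mean
  deviations widened by ``k`` standard uncertainties (coverage factor
  ``k = 2`` by default);
* ``E_R`` -- random positioning error after correction;
* ``delta_z = E + E_R`` -- total positioning uncertainty.

Backlash is corrected open-loop by *overshooting*: after every direction
reversal the first commanded move is extended by a rounded integer number of
motor steps so the screw slack is taken up before the carriage reaches the
target.

A trajectory is a :class:`pandas.DataFrame` with columns ``repeat``,
``position_index``, ``direction`` (``'+'``/``'-'``), ``target_um`` and
``measured_um`` (optionally ``commanded_um``), ordered in acquisition time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAJECTORY_COLUMNS",
    "CalibrationReport",
    "OvershootPlan",
    "validate_trajectory",
    "deviations",
    "bidirectional_systematic_error",
    "estimate_backlash",
    "plan_overshoot",
    "apply_overshoot",
    "positioning_accuracy",
    "random_error",
    "total_uncertainty",
    "calibrate",
]

TRAJECTORY_COLUMNS = ("repeat", "position_index", "direction", "target_um", "measured_um")


def validate_trajectory(traj: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRAJECTORY_COLUMNS if c not in traj.columns]
    if missing:
        raise ValueError(f"trajectory is missing columns {missing}")
    if len(traj) < 2:
        raise ValueError("trajectory must contain at least two records")
    bad = set(traj["direction"].unique()) - {"+", "-"}
    if bad:
        raise ValueError(f"direction labels must be '+' or '-', got {sorted(bad)}")
    return traj


@dataclass(frozen=True)
class OvershootPlan:
    """Integer motor-step overshoots applied after each direction reversal."""

    steps_pos_to_neg: int
    steps_neg_to_pos: int
    step_pos_to_neg_nm: float = 21.1  #: actual motor step size moving in '-'
    step_neg_to_pos_nm: float = 18.9  #: actual motor step size moving in '+'

    def __post_init__(self) -> None:
        if self.steps_pos_to_neg < 0 or self.steps_neg_to_pos < 0:
            raise ValueError("overshoot step counts must be >= 0")
        if self.step_pos_to_neg_nm <= 0 or self.step_neg_to_pos_nm <= 0:
            raise ValueError("nominal step sizes must be positive")


@dataclass(frozen=True)
class CalibrationReport:
    """Summary of a stage-calibration run."""

    e_um: float  #: bidirectional systematic positioning deviation
    b_pos_neg_um: float  #: backlash estimate for + -> - reversals
    b_neg_pos_um: float  #: backlash estimate for - -> + reversals
    a_um: float  #: bidirectional positioning accuracy (coverage factor k)
    e_r_um: float  #: random error
    delta_z_um: float  #: total positioning uncertainty E + E_R
    k: float = 2.0
    n_positions: int = 0
    n_repeats: int = 0

    def to_dict(self) -> dict:
        return {
            "E_um": self.e_um,
            "B_pos_neg_um": self.b_pos_neg_um,
            "B_neg_pos_um": self.b_neg_pos_um,
            "A_um": self.a_um,
            "E_R_um": self.e_r_um,
            "delta_z_um": self.delta_z_um,
            "k": self.k,
            "n_positions": self.n_positions,
            "n_repeats": self.n_repeats,
        }


def deviations(traj: pd.DataFrame) -> pd.DataFrame:
    """Per-position, per-direction mean deviation and standard uncertainty.

    Returns a DataFrame indexed by ``(position_index, direction)`` with
    columns ``mean_dev_um`` (mean of measured - target over repeats),
    ``std_dev_um`` (sample standard deviation, 0 for a single repeat) and
    ``n`` (number of repeats).
    """
    validate_trajectory(traj)
    dev = traj["measured_um"] - traj["target_um"]
    g = dev.groupby([traj["position_index"], traj["direction"]])
    out = pd.DataFrame(
        {
            "mean_dev_um": g.mean(),
            "std_dev_um": g.std(ddof=1).fillna(0.0),
            "n": g.size(),
        }
    )
    out.index.names = ["position_index", "direction"]
    return out


def _require_both_directions(dev_table: pd.DataFrame) -> None:
    dirs = set(dev_table.index.get_level_values("direction"))
    if not {"+", "-"} <= dirs:
        raise ValueError("both approach directions are required; trajectory has only "
                         f"{sorted(dirs)}")


def bidirectional_systematic_error(traj: pd.DataFrame) -> float:
    """Span (max - min) of the mean deviations over all positions and both
    approach directions."""
    table = deviations(traj)
    _require_both_directions(table)
    means = table["mean_dev_um"]
    return float(means.max() - means.min())


def _direction_runs(traj: pd.DataFrame) -> list[pd.DataFrame]:
    """Split the temporally ordered trajectory into runs of constant direction."""
    d = traj["direction"].to_numpy()
    breaks = np.flatnonzero(d[1:] != d[:-1]) + 1
    bounds = np.concatenate(([0], breaks, [len(d)]))
    return [traj.iloc[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def estimate_backlash(traj: pd.DataFrame) -> tuple[float, float]:
    """Estimate the direction-reversal backlash (B+-, B-+) in um.

    Adjacent opposite-direction sweeps are paired in acquisition order and
    matched position by position; the backlash for a reversal is the median
    over common positions of the difference in positioning deviation, which
    is insensitive to the few positions recorded while the slack is still
    being traversed.  Each estimate is the mean magnitude over all reversals
    of the corresponding sense.
    """
    validate_trajectory(traj)
    traj = traj.assign(_dev=traj["measured_um"] - traj["target_um"])
    runs = _direction_runs(traj)
    pos_neg: list[float] = []
    neg_pos: list[float] = []
    for first, second in zip(runs[:-1], runs[1:]):
        d1 = first["direction"].iloc[0]
        d2 = second["direction"].iloc[0]
        if d1 == d2:  # pragma: no cover - runs are maximal by construction
            continue
        merged = pd.merge(
            first[["position_index", "_dev"]],
            second[["position_index", "_dev"]],
            on="position_index",
            suffixes=("_a", "_b"),
        )
        if merged.empty:
            continue
        offset = float(np.median(merged["_dev_a"] - merged["_dev_b"]))
        if d1 == "+":
            pos_neg.append(abs(offset))
        else:
            neg_pos.append(abs(offset))
    if not pos_neg or not neg_pos:
        raise ValueError(
            "backlash estimation needs opposite-direction sweeps visiting common positions"
        )
    return float(np.mean(pos_neg)), float(np.mean(neg_pos))


def plan_overshoot(
    b_pos_neg_um: float,
    b_neg_pos_um: float,
    step_pos_to_neg_nm: float = 21.1,
    step_neg_to_pos_nm: float = 18.9,
) -> OvershootPlan:
    """Round the backlash estimates to integer motor steps per reversal sense."""
    if step_pos_to_neg_nm <= 0 or step_neg_to_pos_nm <= 0:
        raise ValueError("nominal step sizes must be positive")
    if b_pos_neg_um < 0 or b_neg_pos_um < 0:
        raise ValueError("backlash magnitudes must be >= 0")
    return OvershootPlan(
        steps_pos_to_neg=int(round(b_pos_neg_um * 1000.0 / step_pos_to_neg_nm)),
        steps_neg_to_pos=int(round(b_neg_pos_um * 1000.0 / step_neg_to_pos_nm)),
        step_pos_to_neg_nm=step_pos_to_neg_nm,
        step_neg_to_pos_nm=step_neg_to_pos_nm,
    )


def apply_overshoot(targets_um: Sequence[float], plan: OvershootPlan,
                    start_um: float = 0.0) -> np.ndarray:
    """Return the commanded positions implementing overshoot correction.

    After every direction reversal the command stream is shifted further in
    the new direction by the planned number of motor steps, so the screw
    slack is consumed by the extra travel and the carriage lands on the
    original targets.  Monotone segments keep their commanded increments.
    """
    targets = np.asarray(targets_um, dtype=float)
    commanded = targets.copy()
    shift = 0.0
    last_dir = 0
    prev = start_um
    for i, t in enumerate(targets):
        step = t - prev
        d = int(np.sign(step))
        if d != 0 and last_dir != 0 and d != last_dir:
            if d < 0:
                shift -= plan.steps_pos_to_neg * plan.step_pos_to_neg_nm * 1e-3
            else:
                shift += plan.steps_neg_to_pos * plan.step_neg_to_pos_nm * 1e-3
        if d != 0:
            last_dir = d
        commanded[i] = t + shift
        prev = t
    return commanded


def positioning_accuracy(traj: pd.DataFrame, k: float = 2.0) -> float:
    """Bidirectional positioning accuracy: the span of the mean deviations
    widened by ``k`` standard uncertainties on each side."""
    table = deviations(traj)
    _require_both_directions(table)
    hi = table["mean_dev_um"] + k * table["std_dev_um"]
    lo = table["mean_dev_um"] - k * table["std_dev_um"]
    return float(hi.max() - lo.min())


def random_error(traj: pd.DataFrame) -> float:
    """Random positioning error: mean absolute deviation of measured from
    target across all positions and repeats (applied to corrected runs)."""
    validate_trajectory(traj)
    return float((traj["measured_um"] - traj["target_um"]).abs().mean())


def total_uncertainty(e_residual_um: float, e_r_um: float) -> float:
    """Total positioning uncertainty ``delta_z = E + E_R``."""
    if e_residual_um < 0 or e_r_um < 0:
        raise ValueError("uncertainty components must be >= 0")
    return e_residual_um + e_r_um


def calibrate(
    traj: pd.DataFrame,
    corrected_traj: pd.DataFrame | None = None,
    k: float = 2.0,
) -> CalibrationReport:
    """Full calibration summary from an uncorrected (and optionally a
    backlash-corrected) trajectory.

    ``E``, ``A`` and ``E_R`` are evaluated on the corrected trajectory when
    one is given (residual errors after overshoot correction), while the
    backlash estimates always come from the uncorrected data.
    """
    b_pn, b_np = estimate_backlash(traj)
    eval_traj = corrected_traj if corrected_traj is not None else traj
    e = bidirectional_systematic_error(eval_traj)
    a = positioning_accuracy(eval_traj, k=k)
    e_r = random_error(eval_traj)
    return CalibrationReport(
        e_um=e,
        b_pos_neg_um=b_pn,
        b_neg_pos_um=b_np,
        a_um=a,
        e_r_um=e_r,
        delta_z_um=total_uncertainty(e, e_r),
        k=k,
        n_positions=int(eval_traj["position_index"].nunique()),
        n_repeats=int(eval_traj["repeat"].nunique()),
    )
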