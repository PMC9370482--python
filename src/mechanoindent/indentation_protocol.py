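"""Progressive microindentation protocol: geometry, timing and motion program.

A glass microprobe rests at a height ``h0`` above the coverslip and performs a
train of progressively deeper excursions.  Each indentation moves the tip down
by a travelled distance ``D`` at constant speed ``v`` and immediately retracts
to the rest position; the tip height at the bottom of the excursion is
``Z = h0 - D``.  The indentation depth into the cell is ``delta = <T_max> - Z``
where ``<T_max>`` is the average maximal cell thickness of the group measured
by holographic morphometry.  A dwell separates successive indentations so that
late calcium-activation events can still be attributed to the stimulus that
caused them.

The motion program is emitted as plain G-code (relative moves, millimetre
units) suitable for any stepper-based stage driven through a standard G-code
sender.  No hardware communication is performed here.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .stage_calibration import OvershootPlan

__all__ = [
    "ProtocolConfig",
    "IndentationStep",
    "IndentationTrain",
    "DepthMap",
    "build_train",
    "travel_time",
    "indentation_depth",
    "depth_map",
    "emit_gcode",
    "parse_gcode",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Geometry and timing of the indentation train.

    Parameters
    ----------
    h0_um
        Rest height of the probe tip above the coverslip (um).
    d_start_um, d_step_um, d_max_um
        First travelled distance, increment and maximum (um).  The defaults
        produce the six-step train {8, 10, 12, 14, 16, 18} um.
    speed_um_s
        Stage speed during down- and up-travel (um/s).
    dwell_s
        Pause between successive indentations (s), long enough to observe
        late activation transients.
    """

    h0_um: float = 20.0
    d_start_um: float = 8.0
    d_step_um: float = 2.0
    d_max_um: float = 18.0
    speed_um_s: float = 3.0
    dwell_s: float = 40.0

    def __post_init__(self) -> None:
        if not (0.0 < self.d_start_um <= self.d_max_um <= self.h0_um):
            raise ValueError(
                "require 0 < d_start <= d_max <= h0; got "
                f"d_start={self.d_start_um}, d_max={self.d_max_um}, h0={self.h0_um}"
            )
        if self.d_step_um <= 0:
            raise ValueError(f"d_step_um must be positive, got {self.d_step_um}")
        if self.speed_um_s <= 0:
            raise ValueError(f"speed_um_s must be positive, got {self.speed_um_s}")
        if self.dwell_s < 0:
            raise ValueError(f"dwell_s must be >= 0, got {self.dwell_s}")


@dataclass(frozen=True)
class IndentationStep:
    """One indentation of the train."""

    index: int
    d_um: float  #: travelled distance of the excursion
    z_um: float  #: tip height at the bottom of the excursion, ``h0 - D``
    travel_s: float  #: one-way travel time ``D / v``
    t_start_s: float  #: protocol time at which the down-travel begins


@dataclass(frozen=True)
class IndentationTrain:
    """Ordered sequence of progressive indentations."""

    steps: tuple[IndentationStep, ...]
    config: ProtocolConfig

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def d_um(self) -> np.ndarray:
        return np.array([s.d_um for s in self.steps])

    @property
    def z_um(self) -> np.ndarray:
        return np.array([s.z_um for s in self.steps])

    @property
    def t_start_s(self) -> np.ndarray:
        return np.array([s.t_start_s for s in self.steps])

    @property
    def end_s(self) -> float:
        """Protocol time at which the last retraction completes."""
        last = self.steps[-1]
        return last.t_start_s + 2.0 * last.travel_s

    @property
    def duration_s(self) -> float:
        """Total span of the train including the trailing dwell."""
        return self.end_s + self.config.dwell_s - self.steps[0].t_start_s

    def to_frame(self, tmax_mean_um: Optional[float] = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "index": [s.index for s in self.steps],
                "D_um": [s.d_um for s in self.steps],
                "Z_um": [s.z_um for s in self.steps],
                "t_start_s": [s.t_start_s for s in self.steps],
            }
        )
        if tmax_mean_um is not None:
            df["delta_um"] = tmax_mean_um - df["Z_um"]
        return df


@dataclass(frozen=True)
class DepthMap:
    """Per-step indentation depth ``delta = <T_max> - Z``.

    Negative values indicate the tip does not reach the cell surface
    (no contact).
    """

    delta_um: tuple[float, ...]
    tmax_mean_um: float

    @property
    def contact(self) -> tuple[bool, ...]:
        return tuple(d > 0 for d in self.delta_um)

    def __getitem__(self, index: int) -> float:
        return self.delta_um[index]


def travel_time(d_um: float, speed_um_s: float) -> float:
    """One-way travel time of an excursion of length ``d_um`` at speed ``v``."""
    if speed_um_s <= 0:
        raise ValueError(f"speed must be positive, got {speed_um_s}")
    return d_um / speed_um_s


def build_train(config: ProtocolConfig, start_time_s: float = 10.0) -> IndentationTrain:
    """Enumerate the indentation train D = d_start, d_start+d_step, ..., d_max.

    ``start_time_s`` sets the protocol time of the first down-travel; the
    interval before it is the resting-baseline window used to normalise the
    fluorescence ratio.  Each subsequent step starts after the previous
    down-travel, up-travel and dwell.
    """
    n = int(math.floor((config.d_max_um - config.d_start_um) / config.d_step_um + 1e-9)) + 1
    steps = []
    t = float(start_time_s)
    for i in range(n):
        d = config.d_start_um + i * config.d_step_um
        dt = travel_time(d, config.speed_um_s)
        steps.append(
            IndentationStep(index=i, d_um=d, z_um=config.h0_um - d, travel_s=dt, t_start_s=t)
        )
        t += 2.0 * dt + config.dwell_s
    return IndentationTrain(steps=tuple(steps), config=config)


def indentation_depth(z_um: float, tmax_mean_um: float) -> float:
    """Indentation depth ``delta = <T_max> - Z``; negative means no contact."""
    return tmax_mean_um - z_um


def depth_map(train: IndentationTrain, tmax_mean_um: float) -> DepthMap:
    """Map every step of the train to its indentation depth."""
    return DepthMap(
        delta_um=tuple(indentation_depth(s.z_um, tmax_mean_um) for s in train.steps),
        tmax_mean_um=tmax_mean_um,
    )


_GCODE_HEADER = ["G21 ; millimetre units", "G91 ; relative positioning"]
_GCODE_FOOTER = ["M2 ; end of program"]
_TAKEUP_TAG = "backlash takeup"


def emit_gcode(
    train: IndentationTrain,
    config: Optional[ProtocolConfig] = None,
    overshoot_plan: Optional["OvershootPlan"] = None,
) -> str:
    """Emit the indentation train as a relative-move G-code program.

    Speeds are converted to feed rates in mm/min; distances to mm.  When an
    :class:`~mechanoindent.stage_calibration.OvershootPlan` is supplied, a
    slack-takeup move (an integer number of motor steps) is inserted before
    every direction reversal so the carriage lands on target despite screw
    backlash.  Takeup moves are tagged and ignored by :func:`parse_gcode`.
    """
    config = config or train.config
    feed_mm_min = config.speed_um_s * 60.0 / 1000.0
    lines = list(_GCODE_HEADER)
    for step in train.steps:
        d_mm = step.d_um / 1000.0
        lines.append(f"; step {step.index} D={step.d_um:.3f} um Z={step.z_um:.3f} um")
        if overshoot_plan is not None and overshoot_plan.steps_pos_to_neg > 0:
            extra_mm = overshoot_plan.steps_pos_to_neg * overshoot_plan.step_pos_to_neg_nm * 1e-6
            lines.append(f"G1 Z{-extra_mm:.6f} F{feed_mm_min:g} ; {_TAKEUP_TAG}")
        lines.append(f"G1 Z{-d_mm:.6f} F{feed_mm_min:g}")
        if overshoot_plan is not None and overshoot_plan.steps_neg_to_pos > 0:
            extra_mm = overshoot_plan.steps_neg_to_pos * overshoot_plan.step_neg_to_pos_nm * 1e-6
            lines.append(f"G1 Z{extra_mm:.6f} F{feed_mm_min:g} ; {_TAKEUP_TAG}")
        lines.append(f"G1 Z{d_mm:.6f} F{feed_mm_min:g}")
        if config.dwell_s > 0:
            lines.append(f"G4 P{config.dwell_s:g}")
    lines.extend(_GCODE_FOOTER)
    return "\n".join(lines) + "\n"


_G1_RE = re.compile(r"^G1\s+Z(?P<z>-?\d+(?:\.\d+)?)\s+F(?P<f>\d+(?:\.\d+)?)")


def parse_gcode(text: str) -> np.ndarray:
    """Recover the travelled-distance sequence D (um) from an emitted program.

    Slack-takeup moves are skipped; each remaining down/up move pair yields
    one D value.  Raises if moves do not pair up.
    """
    moves_um = []
    for line in text.splitlines():
        line = line.strip()
        if _TAKEUP_TAG in line:
            continue
        m = _G1_RE.match(line)
        if m:
            moves_um.append(float(m.group("z")) * 1000.0)
    if len(moves_um) % 2 != 0:
        raise ValueError("unpaired G1 move in program")
    d_seq = []
    for down, up in zip(moves_um[::2], moves_um[1::2]):
        if down >= 0 or up <= 0 or not math.isclose(-down, up, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(f"down/up moves do not pair: {down} / {up}")
        d_seq.append(-down)
    return np.asarray(d_seq)
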