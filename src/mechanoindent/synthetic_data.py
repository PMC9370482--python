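"""Seeded synthetic inputs with the statistical structure the assay assumes.

Three generators emulate the measurements consumed downstream:

* dual-channel fura-2 traces with Gaussian calcium transients (anti-correlated
  F340/F380, ~40 s FWHM), sub-threshold spontaneous excursions, and a terminal
  membrane-rupture decay shared by both channels;
* interferometric stage trajectories from a dead-band hysteresis model of a
  screw-driven stage, with direction-dependent backlash and step/readout noise;
* holographic phase maps of dome-shaped cells with known maximal thickness,
  plus matching integer ROI label masks and a ground-truth table.

All outputs are deterministic functions of their configuration seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .holography_morphometry import OpticalConstants, PhaseMap, thickness_to_phase
from .indentation_protocol import IndentationTrain
from .trace_classification import DualChannelTrace

__all__ = [
    "TraceGenConfig",
    "CohortSpec",
    "StageSimConfig",
    "PhaseMapSpec",
    "KNOWN_GROUPS",
    "DEFAULT_RESPONSIVE_FRACTIONS",
    "gen_trace",
    "gen_cohort",
    "make_sawtooth",
    "gen_stage_trajectory",
    "gen_phase_map",
]

#: Cell groups of the validation experiment: wild type, Piezo1-overexpressing,
#: calcium-free buffer control, and GsMTx4 (mechanosensitive-channel blocker).
KNOWN_GROUPS = ("WT", "Piezo1", "CaFree", "GsMTx4")

#: Responsive fractions used to parameterise cohorts by default.
DEFAULT_RESPONSIVE_FRACTIONS = {"WT": 0.18, "Piezo1": 0.32, "CaFree": 0.0, "GsMTx4": 0.07}

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))
#: multiples of sigma between the Gaussian centre and its 10 %-of-amplitude
#: edge, which is where the peak detector places the event onset
_ONSET_LEAD_SIGMA = math.sqrt(2.0 * math.log(10.0))


@dataclass(frozen=True)
class TraceGenConfig:
    """Parameters of the dual-channel trace generator.

    ``peak_ratio_amplitude`` is the target maximum of the normalised ratio R
    during an activation transient.  Spontaneous sub-threshold excursions
    (drawn between ``spontaneous_amplitude_range`` with probability
    ``spontaneous_prob`` per cell) emulate the low-amplitude calcium activity
    that makes very permissive thresholds unusable.
    """

    sampling_interval_s: float = 0.44
    baseline_f340: float = 500.0
    baseline_f380: float = 1000.0
    noise_cv: float = 0.02
    peak_fwhm_s: float = 40.0
    peak_ratio_amplitude: float = 3.0
    rupture_decay_tau_s: float = 3.0
    rupture_floor: float = 0.1
    activation_latency_max_s: float = 10.0
    spontaneous_prob: float = 0.5
    #: sub-threshold excursion amplitudes; the upper end keeps the detected
    #: noise-regime edge just below R = 1.5 once smoothing/noise are added
    spontaneous_amplitude_range: tuple[float, float] = (1.25, 1.45)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.peak_fwhm_s <= 0:
            raise ValueError("peak_fwhm_s must be positive")
        if self.baseline_f340 <= 0 or self.baseline_f380 <= 0:
            raise ValueError("baseline intensities must be positive")
        if not 0.0 <= self.spontaneous_prob <= 1.0:
            raise ValueError("spontaneous_prob must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """One experimental group of cells."""

    group_name: str
    n_cells: int
    responsive_fraction: float
    responsive_depth_index: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise ValueError("responsive_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class StageSimConfig:
    """Dead-band hysteresis model of the screw-driven stage.

    On every direction reversal the first ``true_backlash_*`` micrometres of
    commanded travel are consumed by the screw slack before the carriage
    moves.  ``step_noise_sd_nm`` is the actuation noise per commanded
    displacement, scaled with the square root of the travel (in units of
    1 um moves); ``position_noise_sd_um`` is independent readout noise.
    """

    true_backlash_pos_neg_um: float = 3.7
    true_backlash_neg_pos_um: float = 3.1
    nominal_step_pos_nm: float = 21.1  #: actual per-step displacement moving '+'
    nominal_step_neg_nm: float = 18.9  #: actual per-step displacement moving '-'
    step_noise_sd_nm: float = 0.0
    position_noise_sd_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_backlash_pos_neg_um < 0 or self.true_backlash_neg_pos_um < 0:
            raise ValueError("backlash values must be >= 0")
        if self.step_noise_sd_nm < 0 or self.position_noise_sd_um < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.nominal_step_pos_nm <= 0 or self.nominal_step_neg_nm <= 0:
            raise ValueError("nominal step sizes must be positive")


@dataclass(frozen=True)
class PhaseMapSpec:
    """Synthetic holographic field of dome-shaped cells."""

    image_shape: tuple[int, int] = (256, 256)
    n_cells: int = 5
    tmax_mean_um: float = 9.4
    tmax_sd_um: float = 1.5
    cell_radius_px: int = 18
    wavelength_nm: float = 635.0
    n_cell: float = 1.38
    n_medium: float = 1.34
    phase_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell <= self.n_medium:
            raise ValueError("require n_cell > n_medium")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.tmax_mean_um < 0 or self.tmax_sd_um < 0:
            raise ValueError("thickness parameters must be >= 0")
        if self.n_cells < 1 or self.cell_radius_px < 1:
            raise ValueError("n_cells and cell_radius_px must be >= 1")

    @property
    def constants(self) -> OpticalConstants:
        return OpticalConstants(n_cell=self.n_cell, n_medium=self.n_medium)


def _gaussian_bump(t: np.ndarray, amplitude: float, onset_s: float, fwhm_s: float) -> np.ndarray:
    """Transient R excursion whose 10 %-of-amplitude edge sits at ``onset_s``
    and whose maximum reaches ``amplitude`` (in units of normalised R)."""
    sigma = fwhm_s / _FWHM_TO_SIGMA
    center = onset_s + _ONSET_LEAD_SIGMA * sigma
    return (amplitude - 1.0) * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _peak_span_s(fwhm_s: float) -> float:
    """Full duration of a transient between its 10 %-of-amplitude edges."""
    return 2.0 * _ONSET_LEAD_SIGMA * fwhm_s / _FWHM_TO_SIGMA


def eligible_activation_indices(
    train: IndentationTrain, config: TraceGenConfig, rupture_index: Optional[int]
) -> list[int]:
    """Step indices at which a full transient fits before the rupture."""
    if rupture_index is None:
        horizon = train.end_s + train.config.dwell_s
    else:
        rs = train.steps[rupture_index]
        horizon = rs.t_start_s + rs.travel_s
    span = _peak_span_s(config.peak_fwhm_s) + config.activation_latency_max_s
    out = []
    for s in train.steps:
        if rupture_index is not None and s.index >= rupture_index:
            continue
        if s.t_start_s + 2.0 * s.travel_s + span <= horizon:
            out.append(s.index)
    return out


def gen_trace(
    config: TraceGenConfig,
    train: IndentationTrain,
    responsive: bool = False,
    activation_index: Optional[int] = None,
    rupture_index: Optional[int] = None,
    *,
    cell_id: str = "cell-0",
    group: str = "WT",
    peak_amplitude: Optional[float] = None,
    spontaneous_amplitude: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> DualChannelTrace:
    """Generate one dual-channel trace over the span of an indentation train.

    A responsive cell carries a single Gaussian R transient whose onset falls
    within ``activation_latency_max_s`` after the activating indentation
    (down- and up-travel) completes.  A rupture index triggers a simultaneous
    exponential decay of both channels to ``rupture_floor`` of baseline at
    the deepest point of that indentation, after which R is flat.  Ground
    truth is attached to ``trace.meta``.
    """
    if responsive:
        if activation_index is None:
            raise ValueError("responsive traces need an activation_index")
        if rupture_index is not None and activation_index >= rupture_index:
            raise ValueError(
                f"activation_index ({activation_index}) must precede "
                f"rupture_index ({rupture_index})"
            )
    rng = np.random.default_rng(config.seed) if rng is None else rng
    t_end = train.end_s + train.config.dwell_s
    t = np.arange(0.0, t_end, config.sampling_interval_s)

    rupture_time: Optional[float] = None
    if rupture_index is not None:
        rs = train.steps[rupture_index]
        rupture_time = rs.t_start_s + rs.travel_s  # deepest point of the excursion

    r_clean = np.ones_like(t)
    onset: Optional[float] = None
    if responsive:
        step = train.steps[activation_index]
        stim_end = step.t_start_s + 2.0 * step.travel_s
        onset = stim_end + float(rng.uniform(0.0, config.activation_latency_max_s))
        amp = config.peak_ratio_amplitude if peak_amplitude is None else peak_amplitude
        r_clean = r_clean + _gaussian_bump(t, amp, onset, config.peak_fwhm_s)

    spont_onset: Optional[float] = None
    if spontaneous_amplitude is not None and spontaneous_amplitude > 1.0:
        span = _peak_span_s(config.peak_fwhm_s)
        lo = train.steps[0].t_start_s + 20.0
        horizon = rupture_time if rupture_time is not None else t_end
        hi = horizon - span - 20.0
        if hi > lo:
            # keep the excursion clear of the activation transient so peak
            # amplitudes superpose neither in R nor in the channels
            for _ in range(20):
                candidate = float(rng.uniform(lo, hi))
                if onset is None or abs(candidate - onset) >= span:
                    spont_onset = candidate
                    break
            if spont_onset is not None:
                r_clean = r_clean + _gaussian_bump(
                    t, spontaneous_amplitude, spont_onset, config.peak_fwhm_s
                )

    if rupture_time is not None:
        # the dye reports nothing once the membrane is breached
        r_clean = np.where(t < rupture_time, r_clean, 1.0)
        envelope = np.where(
            t < rupture_time,
            1.0,
            config.rupture_floor
            + (1.0 - config.rupture_floor) * np.exp(-(t - rupture_time) / config.rupture_decay_tau_s),
        )
    else:
        envelope = np.ones_like(t)

    f340 = config.baseline_f340 * np.sqrt(r_clean) * envelope
    f380 = config.baseline_f380 / np.sqrt(r_clean) * envelope
    if config.noise_cv > 0:
        f340 = f340 * (1.0 + config.noise_cv * rng.standard_normal(len(t)))
        f380 = f380 * (1.0 + config.noise_cv * rng.standard_normal(len(t)))
        tiny = 1e-6 * min(config.baseline_f340, config.baseline_f380)
        f340 = np.maximum(f340, tiny)
        f380 = np.maximum(f380, tiny)

    meta = {
        "responsive": bool(responsive),
        "activation_index": activation_index if responsive else None,
        "rupture_index": rupture_index,
        "onset_s": onset,
        "rupture_time_s": rupture_time,
        "spontaneous_amplitude": spontaneous_amplitude,
        "spontaneous_onset_s": spont_onset,
    }
    return DualChannelTrace(time_s=t, f340=f340, f380=f380, cell_id=cell_id, group=group, meta=meta)


def gen_cohort(
    spec: CohortSpec,
    config: TraceGenConfig,
    train: IndentationTrain,
    peak_amplitude: Optional[float] = None,
) -> list[DualChannelTrace]:
    """Generate a group of traces with an exact number of responsive cells.

    Exactly ``round(n_cells * responsive_fraction)`` traces are responsive
    (the calcium-free control is always fully unresponsive).  Every cell
    ruptures at the last indentation.  Activation steps follow
    ``responsive_depth_index`` when given, otherwise they are drawn from the
    two deepest steps at which a full transient still fits before rupture.
    """
    if spec.group_name not in KNOWN_GROUPS:
        raise ValueError(f"unknown group {spec.group_name!r}; known: {KNOWN_GROUPS}")
    fraction = 0.0 if spec.group_name == "CaFree" else spec.responsive_fraction
    n_resp = int(math.floor(spec.n_cells * fraction + 0.5))
    rupture_index = len(train.steps) - 1
    eligible = eligible_activation_indices(train, config, rupture_index)
    if n_resp > 0 and not eligible:
        raise ValueError("no indentation step leaves room for a full transient before rupture")
    default_choices = eligible[-2:] if len(eligible) >= 2 else eligible

    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_cells + 1)
    order_rng = np.random.default_rng(children[-1])
    flags = np.zeros(spec.n_cells, dtype=bool)
    flags[:n_resp] = True
    flags = flags[order_rng.permutation(spec.n_cells)]

    traces = []
    for i in range(spec.n_cells):
        rng = np.random.default_rng(children[i])
        responsive = bool(flags[i])
        if responsive:
            ai = (
                spec.responsive_depth_index
                if spec.responsive_depth_index is not None
                else int(rng.choice(default_choices))
            )
        else:
            ai = None
        spont = None
        if rng.random() < config.spontaneous_prob:
            spont = float(rng.uniform(*config.spontaneous_amplitude_range))
        traces.append(
            gen_trace(
                config,
                train,
                responsive=responsive,
                activation_index=ai,
                rupture_index=rupture_index,
                cell_id=f"{spec.group_name}-{i:03d}",
                group=spec.group_name,
                peak_amplitude=peak_amplitude,
                spontaneous_amplitude=spont,
                rng=rng,
            )
        )
    return traces


def make_sawtooth(
    n_positions: int = 20,
    step_um: float = 1.0,
    n_repeats: int = 3,
    start_um: float = 0.0,
) -> pd.DataFrame:
    """Command table for a saw-tooth calibration trajectory.

    Each repeat ascends through positions ``1..n_positions`` (direction '+')
    and descends through ``n_positions-1..0`` (direction '-'); the start
    position itself is not a record.  Position indices label targets, so the
    same index is visited by both directions.
    """
    if n_positions < 2 or n_repeats < 1:
        raise ValueError("need n_positions >= 2 and n_repeats >= 1")
    rows = []
    for rep in range(1, n_repeats + 1):
        for i in range(1, n_positions + 1):
            rows.append((rep, i, "+", start_um + i * step_um))
        for i in range(n_positions - 1, -1, -1):
            rows.append((rep, i, "-", start_um + i * step_um))
    return pd.DataFrame(rows, columns=["repeat", "position_index", "direction", "target_um"])


def gen_stage_trajectory(
    config: StageSimConfig,
    commands: pd.DataFrame | Sequence[float],
    start_um: float = 0.0,
) -> pd.DataFrame:
    """Simulate the measured positions of a commanded trajectory.

    ``commands`` is either a table from :func:`make_sawtooth` (optionally
    with a ``commanded_um`` column holding overshoot-corrected commands) or a
    plain sequence of target positions.  The carriage follows the commanded
    stream through a dead-band: on each direction reversal the configured
    backlash of commanded travel is absorbed before motion resumes.  The
    stage starts at ``start_um``, pre-engaged in the direction of its first
    move.
    """
    if not isinstance(commands, pd.DataFrame):
        targets = np.asarray(list(commands), dtype=float)
        if len(targets) == 0:
            raise ValueError("command sequence must be non-empty")
        dirs = np.sign(np.diff(np.concatenate(([start_um], targets))))
        dir_labels = np.where(dirs >= 0, "+", "-")
        commands = pd.DataFrame(
            {
                "repeat": 1,
                "position_index": np.arange(1, len(targets) + 1),
                "direction": dir_labels,
                "target_um": targets,
            }
        )
    df = commands.copy().reset_index(drop=True)
    if "commanded_um" not in df.columns:
        df["commanded_um"] = df["target_um"]
    if len(df) == 0:
        raise ValueError("command sequence must be non-empty")

    rng = np.random.default_rng(config.seed)
    cmd = df["commanded_um"].to_numpy(dtype=float)
    carriage = float(start_um)
    prev = float(start_um)
    first_move = next((c - prev for c in cmd if c != prev), 1.0)
    state_dir = 1 if first_move >= 0 else -1
    gap_left = 0.0
    measured = np.empty(len(cmd))
    for i, c in enumerate(cmd):
        delta = c - prev
        d = int(np.sign(delta))
        if d != 0 and d != state_dir:
            state_dir = d
            gap_left = (
                config.true_backlash_neg_pos_um if d > 0 else config.true_backlash_pos_neg_um
            )
        travel = abs(delta)
        consumed = min(travel, gap_left)
        gap_left -= consumed
        carriage += d * (travel - consumed)
        noise = 0.0
        if config.step_noise_sd_nm > 0 and travel > 0:
            noise += rng.normal(0.0, config.step_noise_sd_nm * 1e-3 * math.sqrt(travel))
        if config.position_noise_sd_um > 0:
            noise += rng.normal(0.0, config.position_noise_sd_um)
        measured[i] = carriage + noise
        prev = c
    df["measured_um"] = measured
    return df


def gen_phase_map(spec: PhaseMapSpec) -> tuple[PhaseMap, np.ndarray, pd.DataFrame]:
    """Synthesise a phase map of dome-shaped cells with known thickness.

    Cells are smooth raised-cosine domes centred on a regular grid (never
    overlapping); each dome's centre-pixel phase encodes exactly its drawn
    maximal thickness.  Returns the phase map, a uint16 ROI label mask, and
    a ground-truth table (``label``, ``tmax_um``).
    """
    h, w = spec.image_shape
    r = spec.cell_radius_px
    margin = 4
    pitch = 2 * r + margin
    n_rows = max((h - margin) // pitch, 0)
    n_cols = max((w - margin) // pitch, 0)
    if spec.n_cells > n_rows * n_cols:
        raise ValueError(
            f"cannot place {spec.n_cells} non-overlapping cells of radius {r} px "
            f"in a {h}x{w} image (capacity {n_rows * n_cols})"
        )
    rng = np.random.default_rng(spec.seed)
    tmax = np.maximum(rng.normal(spec.tmax_mean_um, spec.tmax_sd_um, spec.n_cells), 0.0)

    thickness = np.zeros((h, w))
    mask = np.zeros((h, w), dtype=np.uint16)
    yy, xx = np.mgrid[0:h, 0:w]
    labels = []
    for k in range(spec.n_cells):
        row, col = divmod(k, n_cols)
        cy = margin + r + row * pitch
        cx = margin + r + col * pitch
        dist = np.hypot(yy - cy, xx - cx)
        inside = dist < r
        dome = tmax[k] * np.cos(np.pi * dist / (2.0 * r)) ** 2
        thickness[inside] = dome[inside]
        mask[inside] = k + 1
        labels.append(k + 1)

    phase = np.asarray(
        thickness_to_phase(thickness, spec.wavelength_nm, spec.constants), dtype=float
    )
    if spec.phase_noise_sd > 0:
        phase = phase + rng.normal(0.0, spec.phase_noise_sd, phase.shape)
    truth = pd.DataFrame({"label": labels, "tmax_um": tmax})
    return PhaseMap(phase=phase, wavelength_nm=spec.wavelength_nm), mask, truth
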