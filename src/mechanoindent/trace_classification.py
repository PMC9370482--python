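"""Ratiometric calcium-trace classification for the microindentation assay.

Each cell is recorded as a pair of fura-2 fluorescence channels: emission at
510 nm under 340 nm excitation (``F340``, rising with cytosolic calcium) and
under 380 nm excitation (``F380``, falling with calcium).  The dye-independent
readout is the fluorescence ratio ``FR = F340/F380`` normalised to its
resting baseline, ``R = FR / FR0``.

A qualifying *activation* event is a transient peak of ``R`` that

* exceeds the activation threshold ``R_T``,
* has a width at (near-)baseline of at least ``w`` seconds, and
* coincides with a peak in ``F340`` and a dip in ``F380`` (anti-correlated
  channels distinguish calcium influx from artefacts).

Membrane *rupture* is the point where both channels drop rapidly together
(the dye diffuses away) while ``R`` flattens.  A cell is responsive when a
qualifying event occurs before rupture; the first event is attributed to the
most recent indentation and inherits its depth ``delta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .indentation_protocol import DepthMap, IndentationTrain

__all__ = [
    "DualChannelTrace",
    "RatiometricTrace",
    "ActivationEvent",
    "CellClassification",
    "normalize_ratio",
    "detect_activation_peaks",
    "detect_rupture",
    "classify_cell",
    "classify_cohort",
]


@dataclass(frozen=True)
class DualChannelTrace:
    """Time-stamped F340/F380 intensities for one cell."""

    time_s: np.ndarray
    f340: np.ndarray
    f380: np.ndarray
    cell_id: str = "cell-0"
    group: str = "WT"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        a = np.asarray(self.f340, dtype=float)
        b = np.asarray(self.f380, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "f340", a)
        object.__setattr__(self, "f380", b)
        if not (len(t) == len(a) == len(b)):
            raise ValueError("time and channel arrays must have equal length")
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing with >= 2 samples")

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))


@dataclass(frozen=True)
class RatiometricTrace:
    """Normalised fluorescence ratio ``R = (F340/F380) / FR0``."""

    time_s: np.ndarray
    r: np.ndarray
    fr0: float
    baseline_window_s: tuple[float, float]


@dataclass(frozen=True)
class ActivationEvent:
    """One qualifying calcium transient."""

    peak_time_s: float
    peak_r: float
    onset_s: float  #: left crossing of the near-baseline level
    width_s: float  #: width at the near-baseline level
    half_rise_s: float  #: left crossing of the half-maximum level, used for
    #: attributing the event to an indentation (robust to overlap with
    #: sub-threshold excursions)
    f340_peak_time_s: float
    f380_dip_time_s: float


@dataclass(frozen=True)
class CellClassification:
    cell_id: str
    group: str
    responsive: bool
    event: Optional[ActivationEvent] = None
    step_index: Optional[int] = None
    delta_um: Optional[float] = None
    rupture_time_s: Optional[float] = None


def normalize_ratio(
    trace: DualChannelTrace, baseline_window_s: tuple[float, float] = (0.0, 10.0)
) -> RatiometricTrace:
    """Compute ``R`` with ``FR0`` averaged over the resting-baseline window.

    The window must precede the first indentation and contain at least five
    samples.  ``R`` is invariant under any joint positive rescaling of the
    two channels (dye-concentration independence).
    """
    if np.any(trace.f380 <= 0) or np.any(trace.f340 <= 0):
        raise ValueError("channel intensities must be positive")
    fr = trace.f340 / trace.f380
    lo, hi = baseline_window_s
    sel = (trace.time_s >= lo) & (trace.time_s < hi)
    if sel.sum() < 5:
        raise ValueError(
            f"baseline window {baseline_window_s} contains {int(sel.sum())} samples; need >= 5"
        )
    fr0 = float(fr[sel].mean())
    return RatiometricTrace(
        time_s=trace.time_s, r=fr / fr0, fr0=fr0, baseline_window_s=(float(lo), float(hi))
    )


def _baseline_crossings(
    t: np.ndarray, y: np.ndarray, peak_idx: int, level: float
) -> tuple[float, float]:
    """Interpolated times where ``y`` crosses ``level`` on either side of a peak."""
    j = peak_idx
    while j > 0 and y[j - 1] > level:
        j -= 1
    if j == 0:
        left = t[0]
    else:
        frac = (y[j] - level) / (y[j] - y[j - 1])
        left = t[j] - frac * (t[j] - t[j - 1])
    k = peak_idx
    n = len(y)
    while k < n - 1 and y[k + 1] > level:
        k += 1
    if k == n - 1:
        right = t[-1]
    else:
        frac = (y[k] - level) / (y[k] - y[k + 1])
        right = t[k] + frac * (t[k + 1] - t[k])
    return float(left), float(right)


def _smooth(y: np.ndarray, dt: float, smoothing_s: float) -> np.ndarray:
    if smoothing_s <= 0:
        return y
    return gaussian_filter1d(y, sigma=smoothing_s / dt, mode="nearest")


def _channel_extrema(
    trace: DualChannelTrace, baseline_sel: np.ndarray, smoothing_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate F340 peak times and F380 dip times.

    Extrema are located on lightly smoothed channels -- the transients are
    tens of seconds wide while frame noise would otherwise split each broad
    peak into several jittering local maxima -- and thresholded well above
    the (smoothed) baseline channel noise.
    """
    dt = trace.dt_s
    f340 = _smooth(trace.f340, dt, smoothing_s)
    f380 = _smooth(trace.f380, dt, smoothing_s)
    s340 = float(f340[baseline_sel].std())
    s380 = float(f380[baseline_sel].std())
    floor340 = max(5.0 * s340, 1e-6 * float(np.median(f340[baseline_sel])))
    floor380 = max(5.0 * s380, 1e-6 * float(np.median(f380[baseline_sel])))
    p340, _ = find_peaks(f340, prominence=floor340)
    p380, _ = find_peaks(-f380, prominence=floor380)
    return trace.time_s[p340], trace.time_s[p380]


def detect_activation_peaks(
    r: RatiometricTrace,
    trace: DualChannelTrace,
    r_threshold: float,
    min_width_s: float = 30.0,
    coincidence_tol_s: float = 10.0,
    min_prominence: float = 0.2,
    baseline_guard: float = 0.1,
    smoothing_s: float = 2.0,
    rupture_time_s: Optional[float] = None,
) -> list[ActivationEvent]:
    """Qualifying activation transients in ascending onset order.

    Signals are lightly smoothed (Gaussian kernel of ``smoothing_s``) before
    peak analysis; with transients tens of seconds wide this suppresses
    frame-noise maxima without measurably attenuating the peaks.  Local
    maxima of ``R`` above ``r_threshold`` (with prominence at least
    ``min_prominence`` to ignore noise maxima) are kept when their width at
    the near-baseline level ``1 + baseline_guard*(peak - 1)`` reaches
    ``min_width_s`` and a F340 peak and F380 dip occur within
    ``coincidence_tol_s`` of the ratio peak.  Events at or after a detected
    rupture are discarded.
    """
    if r_threshold < 0:
        raise ValueError("r_threshold must be >= 0")
    height = max(r_threshold, 1.0 + min_prominence)
    r_s = _smooth(r.r, trace.dt_s, smoothing_s)
    idx, _ = find_peaks(r_s, height=height, prominence=min_prominence)
    lo, hi = r.baseline_window_s
    baseline_sel = (trace.time_s >= lo) & (trace.time_s < hi)
    t340, t380 = _channel_extrema(trace, baseline_sel, smoothing_s)
    events: list[ActivationEvent] = []
    for i in idx:
        tp = float(r.time_s[i])
        if rupture_time_s is not None and tp >= rupture_time_s:
            continue
        level = 1.0 + baseline_guard * (r_s[i] - 1.0)
        left, right = _baseline_crossings(r.time_s, r_s, int(i), level)
        width = right - left
        if width < min_width_s:
            continue
        near340 = t340[np.abs(t340 - tp) <= coincidence_tol_s]
        near380 = t380[np.abs(t380 - tp) <= coincidence_tol_s]
        if len(near340) == 0 or len(near380) == 0:
            continue
        half_level = 1.0 + 0.5 * (r_s[i] - 1.0)
        half_rise, _ = _baseline_crossings(r.time_s, r_s, int(i), half_level)
        events.append(
            ActivationEvent(
                peak_time_s=tp,
                peak_r=float(r_s[i]),
                onset_s=left,
                width_s=float(width),
                half_rise_s=float(half_rise),
                f340_peak_time_s=float(near340[np.argmin(np.abs(near340 - tp))]),
                f380_dip_time_s=float(near380[np.argmin(np.abs(near380 - tp))]),
            )
        )
    events.sort(key=lambda e: e.onset_s)
    return events


def detect_rupture(
    trace: DualChannelTrace,
    r: Optional[RatiometricTrace] = None,
    drop_fraction: float = 0.5,
    drop_window_s: float = 5.0,
    flat_window_s: float = 20.0,
    flat_sd_max: float = 0.05,
) -> Optional[float]:
    """Earliest time at which the membrane rupture signature appears.

    Rupture requires *both* channels to fall by at least ``drop_fraction`` of
    their level ``drop_window_s`` earlier, with ``R`` flat (sd below
    ``flat_sd_max``) over the following ``flat_window_s``.  A dip in a single
    channel -- the F380 drop during an activation transient -- never
    qualifies.  Returns ``None`` when no rupture is found.
    """
    if r is None:
        r = normalize_ratio(trace)
    dt = trace.dt_s
    w = max(1, int(round(drop_window_s / dt)))
    fw = max(5, int(round(flat_window_s / dt)))
    n = len(trace.time_s)
    for i in range(w, n):
        f340_drop = 1.0 - trace.f340[i] / trace.f340[i - w]
        f380_drop = 1.0 - trace.f380[i] / trace.f380[i - w]
        if f340_drop < drop_fraction or f380_drop < drop_fraction:
            continue
        tail = r.r[i : i + fw]
        if len(tail) >= 5 and float(tail.std()) < flat_sd_max:
            return float(trace.time_s[i])
    return None


def classify_cell(
    trace: DualChannelTrace,
    train: IndentationTrain,
    depths: DepthMap,
    r_threshold: float,
    baseline_window_s: Optional[tuple[float, float]] = None,
    **detector_kwargs,
) -> CellClassification:
    """Classify one cell as responsive or unresponsive at threshold ``R_T``.

    The baseline window defaults to the interval before the first
    indentation.  A responsive cell's first event (by onset) is attributed
    to the indentation in whose observation window -- down-travel, up-travel
    and the following dwell, i.e. until the next step starts -- its
    half-maximum rise falls, and inherits that step's depth; events not
    attributable to any indentation leave the depth unassigned with a
    warning.
    """
    if baseline_window_s is None:
        baseline_window_s = (0.0, float(train.steps[0].t_start_s))
    r = normalize_ratio(trace, baseline_window_s)
    rupture_keys = {"drop_fraction", "drop_window_s", "flat_window_s", "flat_sd_max"}
    rupture_kwargs = {k: v for k, v in detector_kwargs.items() if k in rupture_keys}
    peak_kwargs = {k: v for k, v in detector_kwargs.items() if k not in rupture_keys}
    rupture_t = detect_rupture(trace, r, **rupture_kwargs)
    events = detect_activation_peaks(
        r, trace, r_threshold, rupture_time_s=rupture_t, **peak_kwargs
    )
    if not events:
        return CellClassification(
            cell_id=trace.cell_id,
            group=trace.group,
            responsive=False,
            rupture_time_s=rupture_t,
        )
    ev = events[0]
    step_index: Optional[int] = None
    delta: Optional[float] = None
    candidates = [s for s in train.steps if s.t_start_s <= ev.half_rise_s]
    if candidates:
        step = candidates[-1]
        window_s = 2.0 * step.travel_s + train.config.dwell_s
        if ev.half_rise_s - step.t_start_s <= window_s:
            step_index = step.index
            delta = float(depths[step.index])
    if step_index is None:
        warnings.warn(
            f"cell {trace.cell_id}: activation at t={ev.half_rise_s:.1f} s is not "
            "attributable to any indentation window; depth left unassigned",
            stacklevel=2,
        )
    return CellClassification(
        cell_id=trace.cell_id,
        group=trace.group,
        responsive=True,
        event=ev,
        step_index=step_index,
        delta_um=delta,
        rupture_time_s=rupture_t,
    )


def classify_cohort(
    traces: Sequence[DualChannelTrace],
    train: IndentationTrain,
    depths: DepthMap,
    r_threshold: float,
    **kwargs,
) -> list[CellClassification]:
    """Classify every trace of a cohort at a single threshold."""
    return [classify_cell(tr, train, depths, r_threshold, **kwargs) for tr in traces]
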