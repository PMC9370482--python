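"""Phase-to-thickness morphometry for digital holographic microscopy.

A transmission phase map records, pixel by pixel, the optical path delay of
light traversing a cell relative to the surrounding medium.  For a cell of
thickness ``T`` and mean integral refractive index ``n_c`` in a medium of
index ``n_m`` the measured phase shift at wavelength ``lambda`` is

    phi = (2 pi / lambda) (n_c - n_m) T,

so thickness follows by inversion and the maximal cell thickness is obtained
from the maximum phase shift within the cell's region of interest:

    T_max = (lambda / 2 pi) max(phi) / (n_c - n_m).

Reference indices of n_c = 1.38 and n_m = 1.34 are typical for adherent
mammalian cells in physiological buffer.  Phase maps are assumed unwrapped;
values beyond 2 pi (thickness beyond ~16 um at these constants and 635 nm)
trigger a wrap warning.  Segmentation is out of scope: regions of interest
arrive as integer label masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OpticalConstants",
    "PhaseMap",
    "MorphometryResult",
    "calibrate_background",
    "phase_to_thickness",
    "thickness_to_phase",
    "cell_tmax",
    "cohort_thickness_summary",
]


@dataclass(frozen=True)
class OpticalConstants:
    """Mean integral refractive indices of cell and medium."""

    n_cell: float = 1.38
    n_medium: float = 1.34

    def __post_init__(self) -> None:
        if not (self.n_cell > self.n_medium > 1.0):
            raise ValueError(
                f"require n_cell > n_medium > 1, got {self.n_cell}, {self.n_medium}"
            )

    @property
    def delta_n(self) -> float:
        return self.n_cell - self.n_medium


@dataclass(frozen=True)
class PhaseMap:
    """Unwrapped phase image (radians) with its acquisition wavelength."""

    phase: np.ndarray
    wavelength_nm: float = 635.0

    def __post_init__(self) -> None:
        phase = np.asarray(self.phase, dtype=float)
        object.__setattr__(self, "phase", phase)
        if phase.ndim != 2:
            raise ValueError(f"phase map must be 2-D, got shape {phase.shape}")
        if not np.all(np.isfinite(phase)):
            raise ValueError("phase map contains non-finite values")
        if self.wavelength_nm <= 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength_nm}")


@dataclass(frozen=True)
class MorphometryResult:
    """Per-cell maximal thickness and its cohort summary."""

    tmax_um: pd.Series  #: T_max keyed by ROI label
    mean_um: float
    sem_um: float

    @property
    def n_cells(self) -> int:
        return len(self.tmax_um)


def calibrate_background(pmap: PhaseMap, background_mask: np.ndarray) -> PhaseMap:
    """Subtract the mean phase of the background region.

    The background mask selects pixels containing only medium; after
    subtraction their mean phase is zero, anchoring thickness to the medium
    optical path.  Idempotent on already-calibrated maps.
    """
    mask = np.asarray(background_mask, dtype=bool)
    if mask.shape != pmap.phase.shape:
        raise ValueError("background mask shape does not match the phase map")
    if not mask.any():
        raise ValueError("background mask selects no pixels")
    offset = float(pmap.phase[mask].mean())
    return replace(pmap, phase=pmap.phase - offset)


def phase_to_thickness(
    phi_rad: float | np.ndarray,
    wavelength_nm: float = 635.0,
    constants: OpticalConstants = OpticalConstants(),
) -> float | np.ndarray:
    """Thickness (um) from phase shift: ``T = (lambda/2pi) phi / (n_c - n_m)``."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    t_nm = wavelength_nm / (2.0 * np.pi) * np.asarray(phi_rad, dtype=float) / constants.delta_n
    t_um = t_nm * 1e-3
    return float(t_um) if np.isscalar(phi_rad) or np.ndim(phi_rad) == 0 else t_um


def thickness_to_phase(
    t_um: float | np.ndarray,
    wavelength_nm: float = 635.0,
    constants: OpticalConstants = OpticalConstants(),
) -> float | np.ndarray:
    """Forward model: phase shift (radians) of a cell of thickness ``t_um``."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    phi = 2.0 * np.pi / wavelength_nm * constants.delta_n * np.asarray(t_um, dtype=float) * 1e3
    return float(phi) if np.isscalar(t_um) or np.ndim(t_um) == 0 else phi


def cell_tmax(
    pmap: PhaseMap,
    mask: np.ndarray,
    constants: OpticalConstants = OpticalConstants(),
    percentile: float = 100.0,
) -> pd.Series:
    """Maximal thickness per ROI label.

    For each positive label in ``mask`` the maximum calibrated phase inside
    the label's footprint is converted to thickness.  ``percentile`` below
    100 substitutes a percentile of the in-ROI phase for the raw maximum as
    a noise-robust variant; the default is the plain maximum.  Labels with no
    pixels are skipped with a warning.
    """
    mask = np.asarray(mask)
    if mask.shape != pmap.phase.shape:
        raise ValueError("label mask shape does not match the phase map")
    if np.nanmax(pmap.phase, initial=0.0) > 2.0 * np.pi:
        warnings.warn(
            "phase values exceed 2 pi; the map may be wrapped and thicknesses "
            "underestimated",
            stacklevel=2,
        )
    labels = [int(l) for l in np.unique(mask) if l > 0]
    out: dict[int, float] = {}
    for label in labels:
        sel = pmap.phase[mask == label]
        if sel.size == 0:  # pragma: no cover - unique() only returns present labels
            warnings.warn(f"ROI label {label} has no pixels; skipped", stacklevel=2)
            continue
        phi = float(sel.max()) if percentile >= 100.0 else float(np.percentile(sel, percentile))
        out[label] = float(phase_to_thickness(phi, pmap.wavelength_nm, constants))
    return pd.Series(out, name="tmax_um", dtype=float).rename_axis("label")


def cohort_thickness_summary(tmax_um: Iterable[float] | pd.Series) -> MorphometryResult:
    """Mean maximal thickness and its standard error over a cohort of cells."""
    if isinstance(tmax_um, pd.Series):
        series = tmax_um.astype(float)
    else:
        series = pd.Series(np.asarray(list(tmax_um), dtype=float), name="tmax_um")
    if len(series) == 0:
        raise ValueError("cohort summary needs at least one cell")
    mean = float(series.mean())
    sem = float(series.std(ddof=1) / np.sqrt(len(series))) if len(series) > 1 else 0.0
    return MorphometryResult(tmax_um=series, mean_um=mean, sem_um=sem)
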