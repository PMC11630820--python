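"""Steady-state FRET from fluorescence intensity time courses.

A cysteine-containing (acceptor-labelable) sample and a no-cysteine control
are recorded as intensity time courses with annotated reagent additions
(acceptor, then cyclic nucleotide, optionally TCEP to reverse labeling).
After baseline normalization, the FRET efficiency in a plateau window is

    E = 1 - mean(F_cys / F_no_cys),

the no-cysteine control correcting for any nonspecific intensity change.
If a fraction f of the protein carries no acceptor, the observed efficiency
underestimates the true per-molecule efficiency and is corrected by
E_corr = E_obs / (1 - f).  Weighted-average distances follow from the
Förster equation; plateau windows are explicit inputs, not auto-detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import forster
from .energetics import HillFit, hill_fit

__all__ = [
    "IntensityTimeCourse",
    "EfficiencyEstimate",
    "normalize_course",
    "fret_efficiency",
    "correct_unlabeled",
    "weighted_avg_distance",
    "dose_response",
    "tcep_reversal_ok",
]


@dataclass
class IntensityTimeCourse:
    """Fluorescence intensity vs time (s) with (time, reagent) event annotations."""

    time: np.ndarray
    intensity: np.ndarray
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.size != self.intensity.size or self.time.size == 0:
            raise ValueError("time and intensity must be parallel and nonempty")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be positive")
        self.events = sorted(self.events, key=lambda e: e[0])

    def window_mean(self, window: tuple[float, float]) -> float:
        lo, hi = window
        mask = (self.time >= lo) & (self.time <= hi)
        if not mask.any():
            raise ValueError(f"no samples in window [{lo}, {hi}]")
        return float(self.intensity[mask].mean())


@dataclass(frozen=True)
class EfficiencyEstimate:
    """A FRET efficiency with the condition label and time window it came from."""

    E: float
    condition: str
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.E < 1.0:
            raise ValueError(f"efficiency must be in [0, 1), got {self.E}")


def normalize_course(
    course: IntensityTimeCourse, baseline_window: tuple[float, float]
) -> IntensityTimeCourse:
    """Divide intensities by the baseline-window mean (which must precede all events)."""
    if course.events and baseline_window[1] > course.events[0][0]:
        raise ValueError("baseline window must precede the first event")
    base = course.window_mean(baseline_window)
    return IntensityTimeCourse(course.time, course.intensity / base, list(course.events))


def _check_window_clear(course: IntensityTimeCourse, window: tuple[float, float]) -> None:
    lo, hi = window
    for t, label in course.events:
        if lo < t < hi:
            raise ValueError(f"window [{lo}, {hi}] overlaps event {label!r} at t={t}")


def fret_efficiency(
    cys_course: IntensityTimeCourse,
    nocys_course: IntensityTimeCourse,
    window: tuple[float, float],
    condition: str = "",
) -> EfficiencyEstimate:
    """E = 1 - mean(F_cys / F_no_cys) over a plateau window.

    Both courses must be baseline-normalized; the window must not straddle a
    reagent addition.  The control course is interpolated onto the sample's
    time base if the grids differ.
    """
    _check_window_clear(cys_course, window)
    _check_window_clear(nocys_course, window)
    lo, hi = window
    mask = (cys_course.time >= lo) & (cys_course.time <= hi)
    if not mask.any():
        raise ValueError(f"no samples in window [{lo}, {hi}]")
    t = cys_course.time[mask]
    f_cys = cys_course.intensity[mask]
    f_nocys = np.interp(t, nocys_course.time, nocys_course.intensity)
    e = 1.0 - float(np.mean(f_cys / f_nocys))
    return EfficiencyEstimate(E=e, condition=condition, window=window)


def correct_unlabeled(e_obs: float, f_unlabeled: float) -> float:
    """Correct an observed efficiency for a fraction of acceptor-free protein.

    The unlabeled fraction contributes E = 0, so E_obs = (1 - f) * E_true and
    E_corr = E_obs / (1 - f).  Raises if the corrected value reaches 1.
    """
    if not 0.0 <= f_unlabeled < 1.0:
        raise ValueError("f_unlabeled must be in [0, 1)")
    if e_obs < 0:
        raise ValueError("E_obs must be nonnegative")
    e_corr = e_obs / (1.0 - f_unlabeled)
    if e_corr >= 1.0:
        raise ValueError(
            f"corrected efficiency {e_corr:.3f} >= 1: E_obs inconsistent with f_unlabeled"
        )
    return e_corr


def weighted_avg_distance(e: float, pair: forster.ForsterPair) -> float:
    """Distance (Å) whose Förster efficiency equals the measured average E."""
    return forster.distance_from_efficiency(e, pair.r0)


def dose_response(
    conc,
    efficiencies,
    e_apo: float | None = None,
    fix_h: float | None = None,
) -> tuple[np.ndarray, HillFit]:
    """Assemble and fit a dose-response curve from per-concentration efficiencies.

    The response at each ligand concentration is the efficiency change
    relative to the apo efficiency (``e_apo``; defaults to the smallest
    observed E), normalized to the maximal change.  Returns the normalized
    responses and the Hill fit.
    """
    c = np.asarray(conc, dtype=float)
    e = np.asarray(efficiencies, dtype=float)
    if c.shape != e.shape:
        raise ValueError("conc and efficiencies must be parallel")
    if c.size < 3:
        raise ValueError("need at least 3 concentrations")
    base = float(e.min()) if e_apo is None else float(e_apo)
    delta = e - base
    dmax = delta.max()
    if dmax <= 0:
        raise ValueError("no dynamic range: efficiencies do not increase with ligand")
    norm = delta / dmax
    return norm, hill_fit(c, norm, fix_h=fix_h)


def tcep_reversal_ok(
    cys_course: IntensityTimeCourse,
    nocys_course: IntensityTimeCourse,
    window: tuple[float, float],
    tolerance: float = 0.05,
) -> bool:
    """QC flag: after TCEP removes the acceptor, F_cys should return to F_no_cys.

    The window should follow the TCEP event; returns True when the residual
    apparent efficiency is below ``tolerance``.  Computed directly from the
    intensity ratio so that small negative residuals (noise) are tolerated.
    """
    _check_window_clear(cys_course, window)
    lo, hi = window
    mask = (cys_course.time >= lo) & (cys_course.time <= hi)
    if not mask.any():
        raise ValueError(f"no samples in window [{lo}, {hi}]")
    t = cys_course.time[mask]
    ratio = cys_course.intensity[mask] / np.interp(
        t, nocys_course.time, nocys_course.intensity
    )
    return abs(1.0 - float(ratio.mean())) < tolerance
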