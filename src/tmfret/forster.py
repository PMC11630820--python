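"""Förster-equation conversions between distance, FRET efficiency and donor lifetime.

Conventions used throughout the package: distances in ångströms, lifetimes in
nanoseconds, frequencies in hertz.  The Förster radius ``R0`` of a
donor-acceptor pair is the separation at which transfer efficiency is 50%;
it is treated as a fixed, externally determined input and is never fitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ForsterPair",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "fret_lifetime",
    "get_pair",
    "register_pair",
    "load_registry",
    "DEFAULT_PAIRS",
]


@dataclass(frozen=True)
class ForsterPair:
    """A donor/acceptor labeling pair.

    Parameters
    ----------
    donor_name, acceptor_name:
        Free-text labels (e.g. ``"Acd"`` and ``"Fe(phenM)3"``).
    r0:
        Förster radius in Å.
    tau_donor:
        Donor-only fluorescence lifetime in ns (single exponential).
    """

    donor_name: str
    acceptor_name: str
    r0: float
    tau_donor: float

    def __post_init__(self) -> None:
        if not self.r0 > 0:
            raise ValueError(f"R0 must be positive, got {self.r0}")
        if not self.tau_donor > 0:
            raise ValueError(f"tau_donor must be positive, got {self.tau_donor}")


def efficiency_from_distance(r, r0):
    """FRET efficiency E = 1 / (1 + (r/R0)^6) for donor-acceptor distance ``r`` (Å).

    Strictly decreasing in ``r``; E(R0) = 0.5 by definition of the Förster
    radius.  Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    r0 = float(r0)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    if r0 <= 0:
        raise ValueError("R0 must be positive")
    out = 1.0 / (1.0 + (r / r0) ** 6)
    return float(out) if out.ndim == 0 else out


def distance_from_efficiency(efficiency, r0):
    """Invert the Förster equation: r = R0 * ((1-E)/E)^(1/6).

    Only defined for 0 < E < 1 (E=1 would require zero separation, E=0
    infinite separation).
    """
    e = np.asarray(efficiency, dtype=float)
    if np.any(e <= 0) or np.any(e >= 1):
        raise ValueError("efficiency must lie strictly between 0 and 1")
    if r0 <= 0:
        raise ValueError("R0 must be positive")
    out = float(r0) * ((1.0 - e) / e) ** (1.0 / 6.0)
    return float(out) if out.ndim == 0 else out


def fret_lifetime(r, pair: ForsterPair):
    """Donor lifetime in the presence of an acceptor at distance ``r`` (Å).

    tau_DA = tau_D * (1 - E(r)); FRET adds a nonradiative de-excitation path
    so the lifetime shortens in proportion to the transfer efficiency.
    """
    e = efficiency_from_distance(r, pair.r0)
    return pair.tau_donor * (1.0 - np.asarray(e)) if np.ndim(e) else pair.tau_donor * (1.0 - e)


# Registered pairs: Acd donor with the three transition-metal acceptor
# complexes.  R0 values from prior calibration; Cu(TETAC) is a short-range
# pair used only for steady-state work.
DEFAULT_PAIRS: dict[str, ForsterPair] = {
    "Fe(phenM)3": ForsterPair("Acd", "Fe(phenM)3", r0=41.8, tau_donor=17.2),
    "Ru(bpy)2phenM": ForsterPair("Acd", "Ru(bpy)2phenM", r0=43.5, tau_donor=17.2),
    "Cu(TETAC)": ForsterPair("Acd", "Cu(TETAC)", r0=15.6, tau_donor=17.2),
}

_registry: dict[str, ForsterPair] = dict(DEFAULT_PAIRS)


def register_pair(name: str, pair: ForsterPair) -> None:
    """Add or replace a named pair in the registry.

    Buffer-specific donor lifetimes can be registered under qualified names,
    e.g. ``"Fe(phenM)3@KBT"``.
    """
    _registry[name] = pair


def get_pair(name: str, buffer: str | None = None) -> ForsterPair:
    """Look up a registered pair, preferring a buffer-qualified entry."""
    if buffer is not None and f"{name}@{buffer}" in _registry:
        return _registry[f"{name}@{buffer}"]
    try:
        return _registry[name]
    except KeyError:
        known = ", ".join(sorted(_registry))
        raise KeyError(f"no Förster pair named {name!r}; known pairs: {known}") from None


def load_registry(path: str | Path) -> dict[str, ForsterPair]:
    """Load additional pairs from a JSON config section.

    The file maps names to ``{"donor": ..., "acceptor": ..., "r0": ..,
    "tau_donor": ..}``.  Entries are merged into the process registry and
    returned.
    """
    with open(path) as fh:
        raw = json.load(fh)
    loaded = {}
    for name, spec in raw.items():
        pair = ForsterPair(
            donor_name=spec.get("donor", "Acd"),
            acceptor_name=spec.get("acceptor", name),
            r0=float(spec["r0"]),
            tau_donor=float(spec["tau_donor"]),
        )
        register_pair(name, pair)
        loaded[name] = pair
    return loaded
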