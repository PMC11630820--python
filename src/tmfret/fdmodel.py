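"""Frequency-domain lifetime forward model.

In frequency-domain lifetime spectroscopy the excitation light is modulated
sinusoidally and the donor emission is characterized, at each modulation
frequency, by its phase delay and modulation ratio (a "Weber plot").  For a
mixture of exponentially decaying species with pre-exponential amplitudes
alpha_j and lifetimes tau_j, the standard relations are

    f_j  = alpha_j tau_j / sum_k alpha_k tau_k     (fractional intensities)
    N(w) = sum_j f_j * w tau_j / (1 + w^2 tau_j^2)
    D(w) = sum_j f_j / (1 + w^2 tau_j^2)
    phase = atan2(N, D) + w * t0,   modulation = sqrt(N^2 + D^2)

with w = 2*pi*frequency.  A per-experiment timing offset t0 shifts the phase
in proportion to frequency and leaves the modulation untouched.

Convention for amplitude vs intensity fractions: the donor-only and
background fractions in :class:`NuisanceParams` are molecule (amplitude)
fractions.  They are converted to intensity fractions by tau-weighting
inside :func:`fd_response` — except that a species with tau = 0 is treated
as scattered excitation light whose intensity fraction equals its amplitude
and which contributes at phasor position (g, s) = (1, 0) (zero phase, unit
modulation).  Without this special case a tau-weighted zero-lifetime species
would vanish from the signal.

Phases are degrees in all public interfaces and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import DistanceDistribution, discretize
from .forster import ForsterPair, efficiency_from_distance

__all__ = [
    "NuisanceParams",
    "SpeciesMixture",
    "FDDataset",
    "species_from_distribution",
    "fd_response",
    "predict_dataset",
    "phasor_coordinates",
    "DEFAULT_FREQUENCIES",
]

# 14 log-spaced modulation frequencies from the 10 MHz fundamental up to
# 200 MHz, the default grid for simulation; measured grids come from files.
DEFAULT_FREQUENCIES: np.ndarray = np.geomspace(10e6, 200e6, 14)


@dataclass(frozen=True)
class NuisanceParams:
    """Non-structural parameters of one FD experiment.

    f_donor_only : molecule fraction lacking a functional acceptor
        (decays at the unquenched donor lifetime).
    f_background : molecule-equivalent background fraction (default bound
        0.05); with tau_background = 0 it behaves as pure scatter.
    tau_background : background lifetime in ns (0 = scatter).
    t0 : per-experiment timing offset in ns.
    """

    f_donor_only: float = 0.0
    f_background: float = 0.0
    tau_background: float = 0.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_donor_only < 1.0:
            raise ValueError("f_donor_only must be in [0, 1)")
        if not 0.0 <= self.f_background <= 1.0:
            raise ValueError("f_background must be in [0, 1]")
        if self.f_donor_only + self.f_background >= 1.0:
            raise ValueError("f_donor_only + f_background must be < 1")
        if self.tau_background < 0:
            raise ValueError("tau_background must be >= 0")


@dataclass(frozen=True)
class SpeciesMixture:
    """Pre-exponential amplitudes and lifetimes (ns) of a decay mixture."""

    amplitudes: np.ndarray
    lifetimes: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        t = np.asarray(self.lifetimes, dtype=float)
        if a.size == 0:
            raise ValueError("mixture must contain at least one species")
        if a.shape != t.shape:
            raise ValueError("amplitudes and lifetimes must have equal length")
        if np.any(a < 0):
            raise ValueError("amplitudes must be nonnegative")
        if np.any(t < 0):
            raise ValueError("lifetimes must be nonnegative")
        s = a.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"amplitudes must sum to 1, got {s}")
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "lifetimes", t)


@dataclass
class FDDataset:
    """One experiment's Weber-plot data plus condition metadata."""

    frequencies: np.ndarray
    phase_deg: np.ndarray
    mod_ratio: np.ndarray
    condition: str = ""
    acceptor: str = ""
    ionic: str = ""
    replicate_id: str = ""
    sample_id: str = ""
    phase_sd: np.ndarray | None = None
    mod_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)
        self.mod_ratio = np.asarray(self.mod_ratio, dtype=float)
        n = self.frequencies.size
        if self.phase_deg.size != n or self.mod_ratio.size != n:
            raise ValueError("frequency, phase and modulation columns must be parallel")
        if n == 0:
            raise ValueError("dataset is empty")
        if np.any(np.diff(self.frequencies) <= 0):
            bad = int(np.argmax(np.diff(self.frequencies) <= 0)) + 1
            raise ValueError(f"frequencies must be strictly increasing (row {bad + 1})")
        if np.any(self.mod_ratio <= 0) or np.any(self.mod_ratio > 1):
            raise ValueError("modulation ratios must lie in (0, 1]")
        # a per-experiment timing offset t0 shifts phase by w*t0, so measured
        # phases can leave [0, 90); only clearly unphysical values are rejected
        if np.any(self.phase_deg <= -90) or np.any(self.phase_deg >= 180):
            raise ValueError("phase delays must lie in (-90, 180) degrees")
        if not self.sample_id:
            self.sample_id = self.replicate_id
        for name in ("phase_sd", "mod_sd"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != n:
                    raise ValueError(f"{name} must be parallel to frequencies")
                setattr(self, name, v)

    def __len__(self) -> int:
        return int(self.frequencies.size)


def species_from_distribution(
    dist: DistanceDistribution,
    pair: ForsterPair,
    nuisance: NuisanceParams | None = None,
    n_points: int = 501,
    span: float = 5.0,
    warn: bool = True,
) -> SpeciesMixture:
    """Expand a distance distribution into a decay-species mixture.

    Each quadrature node r_k becomes a species with lifetime
    tau_D * (1 - E(r_k)) and amplitude (1 - f_DO - f_B) * w_k; donor-only
    molecules contribute (f_DO, tau_D) and background (f_B, tau_background).
    """
    if nuisance is None:
        nuisance = NuisanceParams()
    r, w = discretize(dist, n_points=n_points, span=span, warn=warn)
    e = efficiency_from_distance(r, pair.r0)
    scale = 1.0 - nuisance.f_donor_only - nuisance.f_background
    amps = [scale * w]
    taus = [pair.tau_donor * (1.0 - e)]
    amps.append(np.array([nuisance.f_donor_only]))
    taus.append(np.array([pair.tau_donor]))
    if nuisance.f_background > 0:
        amps.append(np.array([nuisance.f_background]))
        taus.append(np.array([nuisance.tau_background]))
    a = np.concatenate(amps)
    t = np.concatenate(taus)
    return SpeciesMixture(a / a.sum(), t)


def fd_response(mix: SpeciesMixture, frequency, t0: float = 0.0):
    """Phase delay (degrees) and modulation ratio at the given frequencies (Hz).

    ``t0`` is the timing offset in ns; it adds w*t0 to the phase only.
    Species with tau = 0 are scatter: their intensity fraction equals their
    amplitude and they contribute (g, s) = (1, 0).  Returns a pair of arrays
    shaped like ``frequency`` (scalars for scalar input).
    """
    freq = np.asarray(frequency, dtype=float)
    if np.any(freq <= 0):
        raise ValueError("frequency must be positive")
    scalar = freq.ndim == 0
    w = 2.0 * np.pi * np.atleast_1d(freq)[:, None]  # rad/s
    tau = mix.lifetimes[None, :] * 1e-9  # s
    alpha = mix.amplitudes

    scatter = mix.lifetimes == 0.0
    f_scatter = alpha[scatter].sum()
    # tau-weighted intensity fractions of the fluorescent species, sharing
    # the (1 - f_scatter) of the signal not due to scatter
    at = alpha * mix.lifetimes
    at_sum = at.sum()
    if at_sum == 0 and f_scatter == 0:
        raise ValueError("mixture has no intensity")
    if at_sum > 0:
        fj = np.where(scatter, 0.0, at / at_sum) * (1.0 - f_scatter)
    else:
        fj = np.zeros_like(alpha)

    wt = w * tau
    denom = 1.0 + wt**2
    n_comp = (fj[None, :] * wt / denom).sum(axis=1)
    d_comp = (fj[None, :] / denom).sum(axis=1) + f_scatter

    phase = np.arctan2(n_comp, d_comp) + (w[:, 0] * t0 * 1e-9)
    mod = np.hypot(n_comp, d_comp)
    phase_deg = np.degrees(phase)
    if scalar:
        return float(phase_deg[0]), float(mod[0])
    return phase_deg, mod


def predict_dataset(
    dist: DistanceDistribution,
    pair: ForsterPair,
    nuisance: NuisanceParams | None = None,
    frequencies=DEFAULT_FREQUENCIES,
    n_points: int = 501,
    span: float = 5.0,
    **metadata,
) -> FDDataset:
    """Noise-free predicted Weber data for a distribution under one condition."""
    if nuisance is None:
        nuisance = NuisanceParams()
    mix = species_from_distribution(dist, pair, nuisance, n_points=n_points, span=span)
    phase, mod = fd_response(mix, frequencies, t0=nuisance.t0)
    return FDDataset(
        frequencies=np.asarray(frequencies, dtype=float),
        phase_deg=phase,
        mod_ratio=mod,
        acceptor=metadata.pop("acceptor", pair.acceptor_name),
        **metadata,
    )


def phasor_coordinates(phase_deg, mod_ratio):
    """Phasor-plot coordinates g = m cos(phi), s = m sin(phi).

    Single-exponential decays fall on the universal semicircle
    (g - 1/2)^2 + s^2 = 1/4; mixtures fall inside it, on the chord joining
    their components' phasors.
    """
    phi = np.radians(np.asarray(phase_deg, dtype=float))
    m = np.asarray(mod_ratio, dtype=float)
    g = m * np.cos(phi)
    s = m * np.sin(phi)
    if g.ndim == 0:
        return float(g), float(s)
    return g, s
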