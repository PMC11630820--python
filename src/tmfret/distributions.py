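"""Gaussian donor-acceptor distance distributions and their discretization.

Distance heterogeneity in a labeled protein has two sources: backbone and
rotamer motion within one conformational state (the width sigma of a
Gaussian component) and exchange between conformational states (the relative
weight of two components).  A two-component mixture therefore encodes a
resting/active conformational equilibrium, with the weight of the
short-distance component, A2, read as the probability of the active state.

Gaussians are truncated at r > 0 and renormalized: physical distances are
positive, and for all realistic parameter sets (rbar >> sigma) the removed
mass is negligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GaussianComponent",
    "DistanceDistribution",
    "DistributionTable",
    "make_single",
    "make_two_state",
    "discretize",
]

SIGMA_FIT_BOUNDS = (0.5, 10.0)  # Å; enforced at the fitting layer, not here


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian component: mean distance rbar (Å), width sigma (Å), weight."""

    rbar: float
    sigma: float
    weight: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight must be in [0, 1], got {self.weight}")


@dataclass(frozen=True)
class DistanceDistribution:
    """An ordered mixture of one or two Gaussian components.

    For a two-component distribution the second component is the active
    (short-distance) state and its weight is the active-state fraction A2.
    """

    components: tuple[GaussianComponent, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 2:
            raise ValueError("distribution must have 1 or 2 components")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"component weights must sum to 1, got {total}")

    @property
    def mean(self) -> float:
        """Mixture mean of the untruncated Gaussians (Å)."""
        return sum(c.weight * c.rbar for c in self.components)

    def pdf(self, r):
        """Probability density at r (Å), truncated to r > 0 and renormalized."""
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for c in self.components:
            if c.weight == 0.0:
                continue
            keep = 1.0 - stats.norm.cdf(0.0, loc=c.rbar, scale=c.sigma)
            out = out + c.weight * stats.norm.pdf(r, loc=c.rbar, scale=c.sigma) / keep
        return np.where(r > 0, out, 0.0)


def make_single(rbar: float, sigma: float) -> DistanceDistribution:
    """A single-Gaussian distribution with unit weight."""
    return DistanceDistribution((GaussianComponent(rbar, sigma, 1.0),))


def make_two_state(
    r1: float, s1: float, r2: float, s2: float, a2: float
) -> DistanceDistribution:
    """Sum of two Gaussians with weights (1 - A2, A2).

    Component 1 is the resting (long-distance) state, component 2 the active
    (short-distance) state; ``a2`` is the fraction of molecules in the active
    state.
    """
    if not 0.0 <= a2 <= 1.0:
        raise ValueError(f"A2 must be in [0, 1], got {a2}")
    return DistanceDistribution(
        (
            GaussianComponent(r1, s1, 1.0 - a2),
            GaussianComponent(r2, s2, a2),
        )
    )


def discretize(
    dist: DistanceDistribution, n_points: int = 501, span: float = 5.0, warn: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature grid (r_k, w_k) over the distribution.

    Each component gets its own ``n_points`` trapezoid grid over
    rbar ± span*sigma, clipped to r > 0; the grids are concatenated and the
    weights renormalized so each component carries exactly its mixture
    weight (hence sum(w) == 1).  The defaults resolve fitted means to well
    under 0.01 Å.

    A warning is emitted if clipping at r <= 0 removes more than 1e-6 of a
    component's mass (only possible for unphysically wide components).
    """
    if n_points < 25:
        raise ValueError("n_points must be >= 25")
    rs, ws = [], []
    for c in dist.components:
        lo = c.rbar - span * c.sigma
        hi = c.rbar + span * c.sigma
        clipped_mass = stats.norm.cdf(0.0, loc=c.rbar, scale=c.sigma)
        if warn and clipped_mass > 1e-6:
            warnings.warn(
                f"truncation at r<=0 removes {clipped_mass:.2e} of the mass of the "
                f"component at rbar={c.rbar}, sigma={c.sigma}",
                stacklevel=2,
            )
        lo = max(lo, 1e-9)
        if hi <= lo:
            raise ValueError("component support lies entirely at r <= 0")
        r = np.linspace(lo, hi, n_points)
        pdf = stats.norm.pdf(r, loc=c.rbar, scale=c.sigma)
        # composite trapezoid weights
        w = np.empty_like(r)
        dr = r[1] - r[0]
        w[:] = dr
        w[0] = w[-1] = dr / 2.0
        w = w * pdf
        total = w.sum()
        if total <= 0:
            raise ValueError("degenerate component grid")
        w = w * (c.weight / total)
        rs.append(r)
        ws.append(w)
    return np.concatenate(rs), np.concatenate(ws)


@dataclass(frozen=True)
class DistributionTable:
    """A tabulated distance distribution (e.g. a rotamer-library export).

    Used only for overlay and comparison; never as a fit model.  Density is
    renormalized to unit area on construction.
    """

    r: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if r.size == 0 or r.size != d.size:
            raise ValueError("table must be two equal-length nonempty columns")
        if np.any(np.diff(r) <= 0):
            raise ValueError("distances must be strictly increasing")
        if np.any(d < 0):
            raise ValueError("densities must be nonnegative")
        area = np.trapezoid(d, r)
        if area <= 0:
            raise ValueError("table has zero total density")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "density", d / area)

    @property
    def mean(self) -> float:
        return float(np.trapezoid(self.r * self.density, self.r))
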