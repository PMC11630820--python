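"""Four-state conformational energetics and Hill dose-response fitting.

A ligand-binding domain is modeled as occupying a resting or an active
conformation, each with or without bound ligand.  The measured active-state
probability P_active under one ligand condition gives the free energy of the
resting-to-active transition,

    dG = -R T ln(P_active / P_resting),        P_resting = 1 - P_active,

the ligand's energetic contribution is the difference to the apo condition,

    ddG_ligand = dG_ligand - dG_apo,

and the effect of a solution condition (here ionic strength) on that
contribution is the second difference,

    dddG = ddG(150 mM KCl) - ddG(500 mM KCl).

When a fit pins P_active at 1 the transition energy is unbounded; a maximum
resting-state contribution (default 0.01) is assumed instead and the result
is flagged as an upper bound ("more favorable than").  The flag propagates
through all differences.

Dose-response curves are fitted with the Hill equation

    response = 1 / (1 + (K_half / c)^h),

where K_half is the half-maximal ligand concentration and h the Hill
coefficient (optionally fixed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "R_KCAL",
    "DEFAULT_TEMPERATURE",
    "FreeEnergy",
    "HillFit",
    "delta_G",
    "delta_delta_G",
    "delta3_G",
    "p_active_from_delta_G",
    "hill_eval",
    "hill_fit",
    "aggregate_energetics",
]

R_KCAL = 1.98722e-3  # molar gas constant, kcal/(mol*K)
DEFAULT_TEMPERATURE = 298.0  # K


@dataclass(frozen=True)
class FreeEnergy:
    """A free energy in kcal/mol, optionally an upper bound.

    ``is_bound`` means the underlying occupancy hit the resting-state floor,
    so the true value is *more favorable than* (at most) ``value``.
    """

    value: float
    is_bound: bool = False

    def __float__(self) -> float:
        return self.value

    def __sub__(self, other: "FreeEnergy") -> "FreeEnergy":
        return FreeEnergy(self.value - other.value, self.is_bound or other.is_bound)

    def __str__(self) -> str:
        return f"<{self.value:.3g}" if self.is_bound else f"{self.value:.3g}"


def delta_G(
    p_active: float,
    temperature: float = DEFAULT_TEMPERATURE,
    resting_floor: float = 0.01,
) -> FreeEnergy:
    """Free energy of the resting-to-active transition from its occupancy.

    If ``p_active >= 1 - resting_floor`` (including exactly 1), the value is
    evaluated at the floor and flagged as an upper bound.  ``p_active == 0``
    returns +inf with the bound flag.
    """
    if not 0.0 <= p_active <= 1.0:
        raise ValueError("P_active must be in [0, 1]")
    rt = R_KCAL * temperature
    if p_active == 0.0:
        return FreeEnergy(math.inf, True)
    if p_active >= 1.0 - resting_floor:
        p = 1.0 - resting_floor
        return FreeEnergy(-rt * math.log(p / (1.0 - p)), True)
    return FreeEnergy(-rt * math.log(p_active / (1.0 - p_active)), False)


def p_active_from_delta_G(dg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Logistic inverse of :func:`delta_G` (ignores any bound flag)."""
    return 1.0 / (1.0 + math.exp(float(dg) / (R_KCAL * temperature)))


def delta_delta_G(dg_ligand: FreeEnergy, dg_apo: FreeEnergy) -> FreeEnergy:
    """Ligand-induced change in transition free energy; bound flags propagate."""
    return dg_ligand - dg_apo


def delta3_G(ddg_low_salt: FreeEnergy, ddg_high_salt: FreeEnergy) -> FreeEnergy:
    """Ionic-strength effect on the ligand contribution (low minus high salt)."""
    return ddg_low_salt - ddg_high_salt


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters: K_half (µM), coefficient h, and whether h was fixed."""

    k_half: float
    h: float
    h_fixed: bool

    def __post_init__(self) -> None:
        if not self.k_half > 0 or not self.h > 0:
            raise ValueError("K_half and h must be positive")


def hill_eval(conc, k_half: float, h: float = 1.0):
    """Normalized Hill response 1 / (1 + (K_half / c)^h); 0.5 at c = K_half."""
    c = np.asarray(conc, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    out = 1.0 / (1.0 + (k_half / c) ** h)
    return float(out) if out.ndim == 0 else out


def hill_fit(conc, response, fix_h: float | None = None) -> HillFit:
    """Least-squares Hill fit of normalized responses against concentration (µM)."""
    c = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if c.shape != y.shape:
        raise ValueError("conc and response must be parallel")
    n_free = 1 if fix_h is not None else 2
    if c.size < n_free + 1:
        raise ValueError(f"need at least {n_free + 1} points for {n_free} free parameters")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    k0 = float(np.exp(np.interp(0.5, np.clip(y, 1e-6, 1 - 1e-6), np.log(c))))

    if fix_h is not None:
        res = optimize.least_squares(
            lambda p: hill_eval(c, np.exp(p[0]), fix_h) - y, x0=[np.log(k0)]
        )
        return HillFit(k_half=float(np.exp(res.x[0])), h=float(fix_h), h_fixed=True)
    res = optimize.least_squares(
        lambda p: hill_eval(c, np.exp(p[0]), np.exp(p[1])) - y,
        x0=[np.log(k0), 0.0],
    )
    return HillFit(k_half=float(np.exp(res.x[0])), h=float(np.exp(res.x[1])), h_fixed=False)


def aggregate_energetics(
    groups: dict[str, list[float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean ± SEM per group and pairwise two-tailed t-tests.

    Returns ``(summary, comparisons)``: ``summary`` has one row per group
    (n, mean, sem; sem is NaN for n < 2); ``comparisons`` one row per group
    pair with Student's t statistic and two-tailed p-value.
    """
    rows = []
    for label, values in groups.items():
        v = np.asarray(list(values), dtype=float)
        rows.append(
            {
                "group": label,
                "n": v.size,
                "mean": float(v.mean()) if v.size else math.nan,
                "sem": float(stats.sem(v)) if v.size >= 2 else math.nan,
            }
        )
    summary = pd.DataFrame(rows)
    comps = []
    labels = list(groups)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            va, vb = np.asarray(groups[a], float), np.asarray(groups[b], float)
            if va.size >= 2 and vb.size >= 2:
                t, p = stats.ttest_ind(va, vb)
                comps.append({"group_a": a, "group_b": b, "t": float(t), "p": float(p)})
            else:
                comps.append({"group_a": a, "group_b": b, "t": math.nan, "p": math.nan})
    return summary, pd.DataFrame(comps)
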