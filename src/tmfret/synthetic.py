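"""Synthetic study generator.

Emulates the study design the analysis assumes: two long-range metal-ion
acceptors (Fe(phenM)3, R0 = 41.8 Å; Ru(bpy)2phenM, R0 = 43.5 Å) measured in
three ligand conditions (apo, cAMP, cGMP), a 17.2 ns single-exponential
donor, a 10 MHz fundamental modulation frequency with harmonics up to
200 MHz, and additive Gaussian measurement noise on phase (degrees) and
modulation (independent, the way frequency-domain instruments report
precision).

Default truth values are the study's fitted two-Gaussian model — resting
state at 40.9 ± 4.3 Å, active state at 29.5 ± 0.84 Å, active-state fractions
A2 = 0.12 (apo), 1.0 (cAMP), 0.34 (cGMP) — so parameter-recovery tests
double as plausibility checks.  Per-experiment nuisance parameters are drawn
from documented ranges: donor-only fraction 0.05-0.15 (shared within a
labeled sample), background fraction 0-0.05, timing offset ±0.5 ns.

Every generator is a deterministic function of its design and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .distributions import make_two_state
from .fdmodel import (
    DEFAULT_FREQUENCIES,
    FDDataset,
    NuisanceParams,
    SpeciesMixture,
    fd_response,
    predict_dataset,
)
from .forster import DEFAULT_PAIRS, ForsterPair
from .steady_state import IntensityTimeCourse

__all__ = [
    "TwoGaussianTruth",
    "StudyDesign",
    "generate_fd_study",
    "generate_donor_only",
    "generate_timecourses",
    "generate_dose_response",
]


@dataclass(frozen=True)
class TwoGaussianTruth:
    """Generating parameters of the two-state distance model."""

    rbar1: float = 40.9
    sigma1: float = 4.3
    rbar2: float = 29.5
    sigma2: float = 0.84
    a2: Mapping[str, float] = field(
        default_factory=lambda: {"apo": 0.12, "cAMP": 1.0, "cGMP": 0.34}
    )

    def a2_for(self, condition: str, ionic) -> float:
        """A2 for a condition, preferring an ionic-specific key ``(cond, ionic)``."""
        key = (condition, ionic)
        if key in self.a2:
            return self.a2[key]
        return self.a2[condition]


@dataclass(frozen=True)
class StudyDesign:
    """Full factorial design of a synthetic frequency-domain study."""

    acceptors: Sequence[str] = ("Fe(phenM)3", "Ru(bpy)2phenM")
    conditions: Sequence[str] = ("apo", "cAMP", "cGMP")
    ionic: Sequence[int] = (500,)
    replicates: int = 1
    frequencies: np.ndarray = field(default_factory=lambda: DEFAULT_FREQUENCIES.copy())
    noise_phase: float = 0.2  # degrees
    noise_mod: float = 0.004
    truth: TwoGaussianTruth = field(default_factory=TwoGaussianTruth)
    f_donor_only_range: tuple[float, float] = (0.05, 0.15)
    f_background_range: tuple[float, float] = (0.0, 0.05)
    t0_range: tuple[float, float] = (-0.5, 0.5)  # ns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_phase < 0 or self.noise_mod < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def _pairs_for(design: StudyDesign) -> dict[str, ForsterPair]:
    return {name: DEFAULT_PAIRS[name] for name in design.acceptors}


def generate_fd_study(design: StudyDesign) -> tuple[list[FDDataset], dict]:
    """Generate one noisy Weber dataset per (acceptor, ionic, condition, replicate).

    The donor-only fraction is drawn once per labeled protein sample
    (acceptor x ionic x replicate) and shared across that sample's ligand
    conditions; background fraction and t0 are drawn per experiment.
    Returns the datasets and a truth record (generating parameters and all
    drawn nuisance values) suitable for recovery studies.
    """
    rng = np.random.default_rng(design.seed)
    pairs = _pairs_for(design)
    truth = design.truth
    datasets: list[FDDataset] = []
    record: dict = {
        "rbar1": truth.rbar1,
        "sigma1": truth.sigma1,
        "rbar2": truth.rbar2,
        "sigma2": truth.sigma2,
        "a2": {},
        "nuisance": {},
        "seed": design.seed,
    }
    for acceptor in design.acceptors:
        for ionic in design.ionic:
            for rep in range(design.replicates):
                sample_id = f"{acceptor}_{ionic}mM_rep{rep}"
                f_do = rng.uniform(*design.f_donor_only_range)
                for condition in design.conditions:
                    a2 = truth.a2_for(condition, ionic)
                    record["a2"][f"{condition}@{ionic}"] = a2
                    f_bg = rng.uniform(*design.f_background_range)
                    t0 = rng.uniform(*design.t0_range)
                    nuis = NuisanceParams(
                        f_donor_only=f_do, f_background=f_bg, tau_background=0.0, t0=t0
                    )
                    dist = make_two_state(
                        truth.rbar1, truth.sigma1, truth.rbar2, truth.sigma2, a2
                    )
                    ds = predict_dataset(
                        dist,
                        pairs[acceptor],
                        nuis,
                        frequencies=design.frequencies,
                        condition=condition,
                        acceptor=acceptor,
                        ionic=str(ionic),
                        replicate_id=f"{sample_id}_{condition}",
                        sample_id=sample_id,
                    )
                    if design.noise_phase > 0:
                        ds.phase_deg = ds.phase_deg + rng.normal(
                            0.0, design.noise_phase, len(ds)
                        )
                    else:
                        rng.normal(0.0, 0.0, len(ds))
                    if design.noise_mod > 0:
                        ds.mod_ratio = np.clip(
                            ds.mod_ratio + rng.normal(0.0, design.noise_mod, len(ds)),
                            1e-9,
                            1.0,
                        )
                    else:
                        rng.normal(0.0, 0.0, len(ds))
                    ds.phase_sd = np.full(len(ds), design.noise_phase or np.nan)
                    ds.mod_sd = np.full(len(ds), design.noise_mod or np.nan)
                    if design.noise_phase == 0:
                        ds.phase_sd = None
                    if design.noise_mod == 0:
                        ds.mod_sd = None
                    record["nuisance"][ds.replicate_id] = {
                        "f_donor_only": f_do,
                        "f_background": f_bg,
                        "t0": t0,
                    }
                    datasets.append(ds)
    return datasets, record


def generate_donor_only(
    tau_d: float = 17.2,
    frequencies=None,
    noise_phase: float = 0.2,
    noise_mod: float = 0.004,
    seed: int = 0,
    t0: float = 0.0,
) -> FDDataset:
    """Noisy single-exponential (acceptor-free) Weber dataset."""
    if frequencies is None:
        frequencies = DEFAULT_FREQUENCIES
    freqs = np.asarray(frequencies, dtype=float)
    mix = SpeciesMixture(np.array([1.0]), np.array([tau_d]))
    phase, mod = fd_response(mix, freqs, t0=t0)
    rng = np.random.default_rng(seed)
    phase = phase + rng.normal(0.0, noise_phase, freqs.size)
    mod = np.clip(mod + rng.normal(0.0, noise_mod, freqs.size), 1e-9, 1.0)
    return FDDataset(
        frequencies=freqs,
        phase_deg=phase,
        mod_ratio=mod,
        condition="donor-only",
        replicate_id="donor_only",
        phase_sd=np.full(freqs.size, noise_phase) if noise_phase > 0 else None,
        mod_sd=np.full(freqs.size, noise_mod) if noise_mod > 0 else None,
    )


def _relax(t, t_event, start, target, tau):
    """Exponential relaxation from ``start`` to ``target`` after ``t_event``."""
    out = np.full_like(t, start, dtype=float)
    after = t >= t_event
    out[after] = target + (start - target) * np.exp(-(t[after] - t_event) / tau)
    return out


def generate_timecourses(
    e_acceptor: float = 0.45,
    e_ligand: float = 0.60,
    ligand: str = "cAMP",
    tau_relax: float = 20.0,
    dt: float = 10.0,
    duration: float = 900.0,
    t_acceptor: float = 100.0,
    t_ligand: float = 400.0,
    t_tcep: float = 650.0,
    include_tcep: bool = True,
    nonspecific_quench: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[IntensityTimeCourse, IntensityTimeCourse]:
    """Paired cysteine / no-cysteine intensity time courses.

    The cysteine course quenches to 1 - E after acceptor addition, further
    after ligand addition, and recovers after TCEP strips the acceptor; the
    control course is flat apart from an optional nonspecific quench applied
    to both.  Intensities are baseline-normalized by construction (baseline
    mean 1) with multiplicative Gaussian noise.
    """
    if not 0.0 <= e_acceptor < 1.0 or not 0.0 <= e_ligand < 1.0:
        raise ValueError("efficiencies must be in [0, 1)")
    t = np.arange(0.0, duration, dt)
    rng = np.random.default_rng(seed)

    e_t = _relax(t, t_acceptor, 0.0, e_acceptor, tau_relax)
    e_after_ligand = _relax(t, t_ligand, e_acceptor, e_ligand, tau_relax)
    e_t = np.where(t >= t_ligand, e_after_ligand, e_t)
    events = [(t_acceptor, "acceptor"), (t_ligand, ligand)]
    if include_tcep:
        e_tcep = _relax(t, t_tcep, e_ligand, 0.0, tau_relax)
        e_t = np.where(t >= t_tcep, e_tcep, e_t)
        events.append((t_tcep, "TCEP"))

    quench = _relax(t, t_acceptor, 1.0, 1.0 - nonspecific_quench, tau_relax)
    cys = (1.0 - e_t) * quench
    nocys = quench.copy()
    if noise > 0:
        cys = cys * (1.0 + rng.normal(0.0, noise, t.size))
        nocys = nocys * (1.0 + rng.normal(0.0, noise, t.size))
    return (
        IntensityTimeCourse(t, np.clip(cys, 1e-9, None), list(events)),
        IntensityTimeCourse(t, np.clip(nocys, 1e-9, None), list(events)),
    )


def generate_dose_response(
    k_half: float = 0.14,
    h: float = 1.0,
    conc=None,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized Hill responses on a concentration grid (µM) with Gaussian noise."""
    from .energetics import hill_eval

    if conc is None:
        conc = np.geomspace(0.01, 30.0, 9)
    c = np.asarray(conc, dtype=float)
    rng = np.random.default_rng(seed)
    y = hill_eval(c, k_half, h)
    if noise > 0:
        y = y + rng.normal(0.0, noise, c.size)
    return c, y
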