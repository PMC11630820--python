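"""Chi-squared fitting of frequency-domain lifetime data.

Three layers of analysis:

* per-dataset single-Gaussian fits (one conformational state per ligand
  condition, each experiment fitted on its own);
* a global two-Gaussian fit across datasets, in which the four Gaussian
  parameters (rbar1, sigma1, rbar2, sigma2) are shared by every condition
  and acceptor, the active-state fraction A2 varies per condition, the
  donor-only fraction is shared within a labeled protein sample, and the
  background fraction and timing offset vary per experiment;
* chi-squared profile scans for parameter identifiability.

The objective is the weighted sum of squared residuals over both observables,

    chi2 = sum_ds sum_f [ (phi_obs - phi_pred)^2 / s_phi^2
                          + (m_obs - m_pred)^2 / s_m^2 ],

with per-point uncertainties taken from the data when present and otherwise
from configurable defaults (0.2 degrees, 0.004) typical of frequency-domain
instrument precision.

Distance lifetimes are multi-exponential mixtures with local minima, so fits
use bounded trust-region least squares (via lmfit) from several starting
points spanning plausible distances, with a fixed seed for start generation.
Component labels are normalized after the fit so that component 1 is always
the long-distance (resting) state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .distributions import SIGMA_FIT_BOUNDS, make_single, make_two_state
from .fdmodel import FDDataset, NuisanceParams, fd_response, species_from_distribution
from .forster import ForsterPair, efficiency_from_distance

__all__ = [
    "FitResult",
    "ProfileScan",
    "chi_squared",
    "fit_donor_only",
    "fit_single_gaussian",
    "fit_global_two_gaussian",
    "profile_parameter",
]

DEFAULT_SIGMA_PHASE = 0.2  # degrees
DEFAULT_SIGMA_MOD = 0.004
RBAR_BOUNDS = (5.0, 80.0)  # Å; wide, effectively unconstrained
F_BACKGROUND_MAX = 0.05
MAX_NFEV_PER_START = 5000
CHI2_FTOL = 1e-10


@dataclass
class FitResult:
    """Fitted parameter values plus goodness-of-fit bookkeeping."""

    parameters: dict[str, float]
    chi2: float
    n_obs: int
    converged: bool
    bound_hits: list[str] = field(default_factory=list)
    message: str = ""
    weights: dict[str, float] = field(default_factory=dict)
    per_dataset_chi2: list[float] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "chi2": self.chi2,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "bound_hits": self.bound_hits,
            "message": self.message,
            "weights": self.weights,
            "per_dataset_chi2": self.per_dataset_chi2,
            "flags": self.flags,
        }


@dataclass
class ProfileScan:
    """Chi-squared profile of one parameter: re-minimized chi2 on a fixed grid."""

    parameter: str
    values: np.ndarray
    chi2: np.ndarray
    ok: np.ndarray  # per-point convergence flags


def _weights_for(ds: FDDataset, sigma_phase: float, sigma_mod: float):
    sp = ds.phase_sd if ds.phase_sd is not None else np.full(len(ds), sigma_phase)
    sm = ds.mod_sd if ds.mod_sd is not None else np.full(len(ds), sigma_mod)
    return sp, sm


def chi_squared(
    datasets: list[FDDataset],
    predictions: list[tuple[np.ndarray, np.ndarray]],
    sigma_phase: float = DEFAULT_SIGMA_PHASE,
    sigma_mod: float = DEFAULT_SIGMA_MOD,
) -> float:
    """Weighted chi-squared of predictions against observed Weber data.

    ``predictions`` holds one (phase_deg, mod_ratio) pair of arrays per
    dataset, aligned with that dataset's frequencies.
    """
    if len(datasets) != len(predictions):
        raise ValueError("one prediction per dataset required")
    total = 0.0
    for ds, (phase, mod) in zip(datasets, predictions):
        phase = np.asarray(phase, dtype=float)
        mod = np.asarray(mod, dtype=float)
        if phase.shape != ds.phase_deg.shape or mod.shape != ds.mod_ratio.shape:
            raise ValueError("prediction shape does not match dataset")
        sp, sm = _weights_for(ds, sigma_phase, sigma_mod)
        total += float(
            np.sum(((ds.phase_deg - phase) / sp) ** 2)
            + np.sum(((ds.mod_ratio - mod) / sm) ** 2)
        )
    return total


def _sanitize(label: str) -> str:
    s = re.sub(r"\W", "_", str(label))
    return s if s and not s[0].isdigit() else f"x{s}"


def _residual_vector(datasets, predict, sigma_phase, sigma_mod):
    """Concatenate weighted residuals; ``predict(ds)`` -> (phase, mod)."""
    parts = []
    for ds in datasets:
        phase, mod = predict(ds)
        sp, sm = _weights_for(ds, sigma_phase, sigma_mod)
        parts.append((ds.phase_deg - phase) / sp)
        parts.append((ds.mod_ratio - mod) / sm)
    return np.concatenate(parts)


def _minimize(params, resid_fn, args=()):
    return lmfit.minimize(
        resid_fn,
        params,
        args=args,
        method="least_squares",
        max_nfev=MAX_NFEV_PER_START,
        ftol=CHI2_FTOL,
        xtol=1e-12,
        gtol=1e-12,
    )


def _bound_hits(params: lmfit.Parameters, rel: float = 1e-4) -> list[str]:
    hits = []
    for name, p in params.items():
        if not p.vary:
            continue
        span = (p.max - p.min) if np.isfinite(p.max - p.min) else 1.0
        if np.isfinite(p.min) and abs(p.value - p.min) < rel * span:
            hits.append(name)
        elif np.isfinite(p.max) and abs(p.value - p.max) < rel * span:
            hits.append(name)
    return hits


def fit_donor_only(
    dataset: FDDataset,
    tau_init: float = 15.0,
    fit_t0: bool = False,
    sigma_phase: float = DEFAULT_SIGMA_PHASE,
    sigma_mod: float = DEFAULT_SIGMA_MOD,
) -> FitResult:
    """Fit a single-exponential lifetime to donor-only Weber data."""
    params = lmfit.Parameters()
    params.add("tau", value=tau_init, min=0.1, max=100.0)
    params.add("t0", value=0.0, min=-2.0, max=2.0, vary=fit_t0)

    def predict_factory(p):
        from .fdmodel import SpeciesMixture

        mix = SpeciesMixture(np.array([1.0]), np.array([p["tau"].value]))

        def predict(ds):
            return fd_response(mix, ds.frequencies, t0=p["t0"].value)

        return predict

    def resid(p):
        return _residual_vector([dataset], predict_factory(p), sigma_phase, sigma_mod)

    out = _minimize(params, resid)
    chi2 = float(np.sum(out.residual**2))
    return FitResult(
        parameters={k: float(v.value) for k, v in out.params.items()},
        chi2=chi2,
        n_obs=2 * len(dataset),
        converged=bool(out.success),
        bound_hits=_bound_hits(out.params),
        message=str(out.message),
        weights={"sigma_phase": sigma_phase, "sigma_mod": sigma_mod},
    )


def _multistart_rbars(n_starts: int, seed: int) -> np.ndarray:
    """Deterministic extra starting means spanning 20-50 Å."""
    if n_starts <= 1:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    return rng.uniform(20.0, 50.0, size=n_starts - 1)


def fit_single_gaussian(
    dataset: FDDataset,
    pair: ForsterPair,
    init: dict[str, float] | None = None,
    fixed_nuisance: NuisanceParams | None = None,
    sigma_phase: float = DEFAULT_SIGMA_PHASE,
    sigma_mod: float = DEFAULT_SIGMA_MOD,
    n_starts: int = 5,
    seed: int = 0,
    n_points: int = 501,
) -> FitResult:
    """Fit one dataset with a single-Gaussian distance distribution.

    Fits (rbar, sigma); nuisance parameters (f_donor_only, f_background, t0)
    are fitted too unless ``fixed_nuisance`` pins them.  R0 and tau_D come
    from ``pair`` and are never fitted.  Multi-start over rbar guards
    against local minima; results are deterministic given data, init and
    seed.
    """
    init = dict(init or {})
    params = lmfit.Parameters()
    params.add("rbar", value=init.get("rbar", 35.0), min=RBAR_BOUNDS[0], max=RBAR_BOUNDS[1])
    params.add(
        "sigma",
        value=init.get("sigma", 4.0),
        min=SIGMA_FIT_BOUNDS[0],
        max=SIGMA_FIT_BOUNDS[1],
    )
    if fixed_nuisance is not None:
        params.add("f_do", value=fixed_nuisance.f_donor_only, vary=False)
        params.add("f_bg", value=fixed_nuisance.f_background, vary=False)
        params.add("t0", value=fixed_nuisance.t0, vary=False)
        tau_bg = fixed_nuisance.tau_background
    else:
        params.add("f_do", value=init.get("f_do", 0.1), min=0.0, max=0.5)
        params.add("f_bg", value=init.get("f_bg", 0.01), min=0.0, max=F_BACKGROUND_MAX)
        params.add("t0", value=init.get("t0", 0.0), min=-2.0, max=2.0)
        tau_bg = 0.0

    def resid(p):
        dist = make_single(p["rbar"].value, p["sigma"].value)
        nuis = NuisanceParams(
            f_donor_only=p["f_do"].value,
            f_background=p["f_bg"].value,
            tau_background=tau_bg,
            t0=0.0,
        )
        mix = species_from_distribution(dist, pair, nuis, n_points=n_points, warn=False)

        def predict(ds):
            return fd_response(mix, ds.frequencies, t0=p["t0"].value)

        return _residual_vector([dataset], predict, sigma_phase, sigma_mod)

    best = None
    for extra_rbar in np.concatenate([[params["rbar"].value], _multistart_rbars(n_starts, seed)]):
        p = params.copy()
        p["rbar"].value = float(np.clip(extra_rbar, *RBAR_BOUNDS))
        out = _minimize(p, resid)
        chi2 = float(np.sum(out.residual**2))
        if best is None or chi2 < best[0]:
            best = (chi2, out)
    chi2, out = best

    # identifiability check: if the FRET species carries almost no intensity
    # (E near 0 or near 1, or the donor-only fraction soaks up the signal)
    # the distance is not constrained by the data
    p = out.params
    dist = make_single(p["rbar"].value, p["sigma"].value)
    nuis = NuisanceParams(
        f_donor_only=p["f_do"].value, f_background=p["f_bg"].value, tau_background=tau_bg
    )
    mix = species_from_distribution(dist, pair, nuis, n_points=n_points, warn=False)
    intensity = mix.amplitudes * mix.lifetimes
    n_aux = 2 if nuis.f_background > 0 else 1  # donor-only (+ background) appended last
    fret_fraction = float(intensity[:-n_aux].sum() / intensity.sum())
    mean_e = efficiency_from_distance(p["rbar"].value, pair.r0)
    flags = []
    bound_hits = _bound_hits(out.params)
    if fret_fraction < 0.05 or mean_e < 0.02 or "rbar" in bound_hits:
        flags.append("distance_unidentifiable")

    return FitResult(
        parameters={k: float(v.value) for k, v in out.params.items()},
        chi2=chi2,
        n_obs=2 * len(dataset),
        converged=bool(out.success),
        bound_hits=bound_hits,
        message=str(out.message),
        weights={"sigma_phase": sigma_phase, "sigma_mod": sigma_mod},
        flags=flags,
    )


def experiment_key(ds: FDDataset) -> str:
    """Stable per-experiment parameter suffix built from dataset identity."""
    return _sanitize(f"{ds.acceptor}_{ds.ionic}_{ds.condition}_{ds.replicate_id}")


def _canonical_order(datasets: list[FDDataset]) -> tuple[list[FDDataset], list[str], list[int]]:
    """Sort datasets by identity so the fit is exactly order-invariant.

    Returns the sorted datasets, a unique parameter key per dataset, and the
    position of each *input* dataset in the sorted list.
    """
    order = sorted(range(len(datasets)), key=lambda i: (experiment_key(datasets[i]), i))
    ds_sorted = [datasets[i] for i in order]
    keys, seen = [], {}
    for ds in ds_sorted:
        k = experiment_key(ds)
        if k in seen:
            seen[k] += 1
            k = f"{k}_dup{seen[k]}"
        else:
            seen[k] = 0
        keys.append(k)
    position = [0] * len(datasets)
    for pos, i in enumerate(order):
        position[i] = pos
    return ds_sorted, keys, position


def _global_parameters(
    datasets: list[FDDataset],
    keys: list[str],
    init: dict[str, float] | None = None,
) -> tuple[lmfit.Parameters, dict[str, str], dict[str, str]]:
    """Build the shared/per-condition/per-experiment parameter table."""
    init = dict(init or {})
    params = lmfit.Parameters()
    params.add("rbar1", value=init.get("rbar1", 42.0), min=RBAR_BOUNDS[0], max=RBAR_BOUNDS[1])
    params.add(
        "sigma1", value=init.get("sigma1", 4.0), min=SIGMA_FIT_BOUNDS[0], max=SIGMA_FIT_BOUNDS[1]
    )
    params.add("rbar2", value=init.get("rbar2", 28.0), min=RBAR_BOUNDS[0], max=RBAR_BOUNDS[1])
    params.add(
        "sigma2", value=init.get("sigma2", 1.0), min=SIGMA_FIT_BOUNDS[0], max=SIGMA_FIT_BOUNDS[1]
    )
    cond_key: dict[str, str] = {}
    samp_key: dict[str, str] = {}
    for ds, key in zip(datasets, keys):
        c = f"A2_{_sanitize(ds.condition)}"
        cond_key[ds.condition] = c
        if c not in params:
            params.add(c, value=init.get(c, 0.5), min=0.0, max=1.0)
        s = f"f_do_{_sanitize(ds.sample_id)}"
        samp_key[ds.sample_id] = s
        if s not in params:
            params.add(s, value=init.get(s, 0.1), min=0.0, max=0.5)
        params.add(
            f"f_bg_{key}", value=init.get(f"f_bg_{key}", 0.01), min=0.0, max=F_BACKGROUND_MAX
        )
        params.add(f"t0_{key}", value=init.get(f"t0_{key}", 0.0), min=-2.0, max=2.0)
    return params, cond_key, samp_key


def _global_predictor(datasets, keys, pairs, cond_key, samp_key, n_points):
    def predict_all(p):
        preds = []
        for ds, key in zip(datasets, keys):
            dist = make_two_state(
                p["rbar1"].value,
                p["sigma1"].value,
                p["rbar2"].value,
                p["sigma2"].value,
                p[cond_key[ds.condition]].value,
            )
            nuis = NuisanceParams(
                f_donor_only=p[samp_key[ds.sample_id]].value,
                f_background=p[f"f_bg_{key}"].value,
                tau_background=0.0,
                t0=0.0,
            )
            mix = species_from_distribution(
                dist, pairs[ds.acceptor], nuis, n_points=n_points, warn=False
            )
            preds.append(fd_response(mix, ds.frequencies, t0=p[f"t0_{key}"].value))
        return preds

    return predict_all


def fit_global_two_gaussian(
    datasets: list[FDDataset],
    pairs: dict[str, ForsterPair],
    init: dict[str, float] | None = None,
    sigma_phase: float = DEFAULT_SIGMA_PHASE,
    sigma_mod: float = DEFAULT_SIGMA_MOD,
    n_starts: int = 5,
    seed: int = 0,
    n_points: int = 501,
    _extra_fixed: dict[str, float] | None = None,
) -> FitResult:
    """Global two-Gaussian fit across conditions and acceptors.

    Shares (rbar1, sigma1, rbar2, sigma2) across all datasets; A2 varies per
    condition (bounded [0, 1]); f_donor_only is shared within each labeled
    sample (``sample_id``); f_background (bounded <= 0.05) and t0 vary per
    experiment.  tau_D and R0 are fixed by the registered pairs.  After
    fitting, components are reordered so component 1 is the long-distance
    state (A2 flipped accordingly).

    ``_extra_fixed`` pins named parameters at given values (used by profile
    scans).
    """
    if len(datasets) < 2:
        raise ValueError("global fitting requires at least 2 datasets")
    for ds in datasets:
        if ds.acceptor not in pairs:
            raise KeyError(f"no registered Förster pair for acceptor {ds.acceptor!r}")
    conditions = {ds.condition for ds in datasets}
    if len(conditions) < 2:
        import warnings

        warnings.warn("fewer than 2 conditions: two-state model weakly identified", stacklevel=2)

    ds_sorted, keys, position = _canonical_order(datasets)
    params, cond_key, samp_key = _global_parameters(ds_sorted, keys, init)
    for name, value in (_extra_fixed or {}).items():
        if name not in params:
            raise KeyError(f"unknown parameter {name!r}")
        params[name].set(value=value, vary=False)
    predict_all = _global_predictor(ds_sorted, keys, pairs, cond_key, samp_key, n_points)

    def resid(p):
        preds = predict_all(p)
        parts = []
        for ds, (phase, mod) in zip(ds_sorted, preds):
            sp, sm = _weights_for(ds, sigma_phase, sigma_mod)
            parts.append((ds.phase_deg - phase) / sp)
            parts.append((ds.mod_ratio - mod) / sm)
        return np.concatenate(parts)

    starts = [(params["rbar1"].value, params["rbar2"].value)]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - 1)):
        a, b = sorted(rng.uniform(20.0, 50.0, size=2))
        starts.append((b, a))  # rbar1 = long distance

    best = None
    for r1, r2 in starts:
        p = params.copy()
        if p["rbar1"].vary:
            p["rbar1"].value = float(np.clip(r1, *RBAR_BOUNDS))
        if p["rbar2"].vary:
            p["rbar2"].value = float(np.clip(r2, *RBAR_BOUNDS))
        out = _minimize(p, resid)
        chi2 = float(np.sum(out.residual**2))
        if best is None or chi2 < best[0]:
            best = (chi2, out)
    chi2, out = best

    values = {k: float(v.value) for k, v in out.params.items()}
    swapped = values["rbar1"] < values["rbar2"]
    if swapped:
        values["rbar1"], values["rbar2"] = values["rbar2"], values["rbar1"]
        values["sigma1"], values["sigma2"] = values["sigma2"], values["sigma1"]
        for c in cond_key.values():
            values[c] = 1.0 - values[c]

    preds = predict_all(out.params)
    per_ds_sorted = [
        chi_squared([ds], [pred], sigma_phase, sigma_mod) for ds, pred in zip(ds_sorted, preds)
    ]
    per_ds = [per_ds_sorted[position[i]] for i in range(len(datasets))]
    return FitResult(
        parameters=values,
        chi2=chi2,
        n_obs=sum(2 * len(ds) for ds in datasets),
        converged=bool(out.success),
        bound_hits=_bound_hits(out.params),
        message=str(out.message) + (" (components reordered)" if swapped else ""),
        weights={"sigma_phase": sigma_phase, "sigma_mod": sigma_mod},
        per_dataset_chi2=per_ds,
    )


def profile_parameter(
    datasets: list[FDDataset],
    pairs: dict[str, ForsterPair],
    parameter: str,
    grid,
    init: dict[str, float] | None = None,
    **fit_kwargs,
) -> ProfileScan:
    """Chi-squared profile: fix ``parameter`` at each grid value, re-minimize the rest.

    Per-point fit failures are recorded in ``ok`` rather than raised, so a
    partially failed scan is still plottable.  Profiling a parameter that is
    already fixed is an error.
    """
    ds_sorted, keys, _ = _canonical_order(datasets)
    probe, _, _ = _global_parameters(ds_sorted, keys, init)
    if parameter not in probe:
        raise KeyError(f"unknown parameter {parameter!r}")
    fixed0 = dict(fit_kwargs.pop("_extra_fixed", None) or {})
    if parameter in fixed0:
        raise ValueError(f"parameter {parameter!r} is fixed; its profile is not defined")
    grid = np.asarray(grid, dtype=float)
    chi2s = np.full(grid.shape, np.nan)
    ok = np.zeros(grid.shape, dtype=bool)
    fit_kwargs.setdefault("n_starts", 1)
    warm = dict(init or {})
    for i, v in enumerate(grid):
        try:
            res = fit_global_two_gaussian(
                datasets,
                pairs,
                init=warm,
                _extra_fixed={**fixed0, parameter: float(v)},
                **fit_kwargs,
            )
            chi2s[i] = res.chi2
            ok[i] = res.converged
            warm = dict(res.parameters)  # warm-start the next grid point
            warm.pop(parameter, None)
        except Exception:
            ok[i] = False
    return ProfileScan(parameter=parameter, values=grid, chi2=chi2s, ok=ok)
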