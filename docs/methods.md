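# Methods

This note documents the models implemented in `tmfret`, the conventions and
defaults chosen where several were defensible, and what the synthetic-data
tests do and do not demonstrate about real measurements.

## Distance model

Donor–acceptor distances within a labeled protein are modeled as a mixture
of one or two Gaussian components. One component describes rotamer and
backbone heterogeneity *within* a conformational state (mean r̄, width σ);
two components describe exchange *between* a resting (long-distance,
component 1) and an active (short-distance, component 2) state, with the
weight A₂ of the short component read as the probability of the active
state. Components are ordered by convention — after every fit the package
reorders so that r̄₁ > r̄₂ and flips A₂ accordingly, which removes
label-switching ambiguity from mixture fits.

Gaussians are truncated at r > 0 and renormalized per component. Whether
published fits of this kind truncate at zero is generally unstated; for all
physically sensible parameter sets (r̄ ≫ σ) the clipped mass is far below
1e−6 and the choice is immaterial. `discretize` warns whenever clipping
removes more than 1e−6 of a component's mass.

Numerical quadrature uses, per component, a 501-point trapezoid grid over
r̄ ± 5σ (the grids of the two components are concatenated; weights sum to
exactly 1). Against an adaptive-quadrature oracle the grid average of E(r)
is accurate to better than 1e−6, and refining from 501 to 2001 points moves
predicted efficiencies by less than 1e−6 — comfortably below the ~0.01 Å
resolution relevant to fitted means.

## Frequency-domain forward model

A distance distribution maps to a decay-species mixture: each quadrature
node r_k becomes a species with lifetime τ_D·(1 − E(r_k)) and amplitude
proportional to its quadrature weight. Phase delay and modulation ratio at
each modulation frequency follow the standard multi-exponential relations
(see README). Two conventions deserve emphasis:

* **Amplitude vs intensity fractions.** The donor-only fraction f_DO
  (molecules lacking a functional acceptor) and background fraction f_B are
  *molecule* (pre-exponential amplitude) fractions. They are converted to
  intensity fractions by lifetime weighting inside `fd_response`. The one
  exception is a species with τ = 0, which is treated as scattered
  excitation light: its intensity fraction equals its amplitude and it
  contributes at phasor position (g, s) = (1, 0). A τ-weighted zero-lifetime
  species would otherwise vanish from the signal, which is not how scatter
  behaves. Background defaults to τ = 0 (pure scatter) and is bounded at 5%
  of the signal.
* **Timing offset.** A per-experiment offset t₀ (ns) adds ω·t₀ to the phase
  and leaves the modulation untouched, as a pure time shift must. Because of
  t₀, measured phases can legitimately leave [0°, 90°] (±0.5 ns is ±36° at
  200 MHz); dataset validation therefore only rejects clearly unphysical
  values outside (−90°, 180°). Phases are degrees in every public interface
  and file format, radians internally.

The default simulation grid is 14 log-spaced frequencies from the 10 MHz
fundamental to 200 MHz; fits always use whatever frequencies the data files
contain. The forward model is verified in the test suite against an
independent oracle — numerical sine/cosine Fourier transforms of the
corresponding time-domain decays on a fine grid — to 1e−4 in phase (rad) and
modulation.

## Fitting

The objective is weighted least squares over both observables at every
frequency of every dataset, χ² = Σ[(Δφ/σ_φ)² + (Δm/σ_m)²]. Per-point
uncertainties are taken from the data when present; otherwise the defaults
are σ_φ = 0.2° and σ_m = 0.004, typical of frequency-domain instrument
precision. The weights are configurable and recorded in every result.

Optimization is bounded trust-region least squares (lmfit/scipy `trf`) with
ftol 1e−10 and at most 5000 evaluations per start. Mixtures of lifetimes
have local minima, so fits run from multiple starting points (default 5)
whose distance initializations span 20–50 Å, drawn deterministically from a
fixed seed; the best χ² wins. Parameter bounds: σ ∈ [0.5, 10] Å and
A₂ ∈ [0, 1] (enforced at the fitting layer, so forward simulation can
explore outside them); r̄ ∈ [5, 80] Å, wide enough to be effectively
unconstrained; f_DO ∈ [0, 0.5]; f_B ∈ [0, 0.05]; t₀ ∈ [−2, 2] ns. R₀ and
τ_D are fixed registry inputs, never fitted.

The global two-Gaussian fit shares (r̄₁, σ₁, r̄₂, σ₂) across all datasets,
frees A₂ per ligand condition, shares f_DO within each labeled protein
sample, and frees f_B and t₀ per experiment. Datasets are sorted internally
by (acceptor, ionic strength, condition, replicate), and per-experiment
parameters are keyed by that identity, so results are exactly invariant to
input order. When A₂ converges onto a bound (e.g. 1 under saturating
agonist) the result flags it as a bound hit rather than an interior
estimate. Single-dataset fits additionally flag `distance_unidentifiable`
when the fitted FRET species carries under 5% of the signal intensity or
transfer is negligible — the situation for acceptor-free data, where no
distance information exists.

Identifiability is assessed by χ² profiles: fix one parameter on a grid,
re-minimize all others (warm-started from the previous grid point), and
inspect whether the profile has an interior minimum. Bootstrap or posterior
uncertainty quantification is deliberately out of scope.

## Energetics

ΔG = −RT·ln(P_active/P_resting) with R = 1.98722×10⁻³ kcal/(mol·K) and
T = 298 K by default (configurable). When a fit drives P_active to 1 the
transition energy is unbounded; the package instead assumes a maximum
resting-state contribution of 0.01 (configurable) and flags the value as an
upper bound. The flag propagates through every difference (ΔΔG, ΔΔΔG) and
into reports, where bounded values print as "more favorable than".
Aggregation across experiments reports mean ± SEM and two-tailed Student's
t-tests; SEM is flagged undefined for n < 2.

Dose–response curves use the Hill form 1/(1 + (K½/c)^h) on responses
normalized to the maximal observed efficiency change, with h optionally
fixed at 1. Note the normalization is exact only when the top concentration
saturates the response; a non-saturating top dose biases K½ low by the
unsaturated fraction.

## Steady-state analysis

Efficiencies come from plateau windows of baseline-normalized intensity
time courses, E = 1 − mean(F_cys/F_noCys), with the no-cysteine control
correcting nonspecific intensity changes. Windows are explicit user inputs
(plateaus are read by eye from time courses in practice, and window-means
are the documented convention here — endpoint sampling would be the main
alternative). TCEP-reversal segments are parsed for a QC check (intensity
returns to the control level after the acceptor is stripped) and never used
for E. An unlabeled fraction f is corrected by E/(1 − f), the exact inverse
of mixing in a zero-efficiency subpopulation.

## Synthetic data

The generator emulates the study design the analysis assumes: two long-range
acceptors (R₀ 41.8 and 43.5 Å), three ligand conditions, a 17.2 ns
single-exponential donor, the 14-frequency grid above, and additive,
independent Gaussian noise on phase (0.2°) and modulation (0.004). Truth
defaults are the fitted two-state model (r̄₁ = 40.9 Å, σ₁ = 4.3 Å,
r̄₂ = 29.5 Å, σ₂ = 0.84 Å; A₂ = 0.12 apo, 1.0 cAMP, 0.34 cGMP), so recovery
tests double as plausibility checks. Per-experiment nuisance draws —
f_DO ∈ [0.05, 0.15] shared within a labeled sample, f_B ∈ [0, 0.05],
t₀ ∈ [−0.5, 0.5] ns — are documented assumptions; real replicate-to-replicate
variability is unknown. Every generator is a deterministic function of its
design and seed.

What passing recovery tests show: the estimator is consistent and
well-calibrated *under the model's own assumptions* (Gaussian mixtures,
additive independent noise, exact R₀ and τ_D). What they do not show:
robustness to correlated or frequency-dependent instrument noise,
calibration drift, R₀ misspecification (orientation factor, index of
refraction), non-Gaussian rotamer distributions, or inter-subunit FRET in
oligomers — none of which the generator emulates.

Recovery at the default noise level (20-seed medians, six-dataset studies,
2 starts per fit): means within 0.1 Å, A₂ within 0.01, σ₁ within 0.1 Å. The
narrow active-state width σ₂ is the exception: it is weakly informative at
these frequencies and noise levels, and its median recovery lands ~0.1 Å
below the generating 0.84 Å (noise-free fits recover it exactly). The study
sizes used throughout (six datasets per study, 20 seeds, 14 frequencies)
match the design being emulated and keep the full pipeline fast on one CPU.

## File formats

Weber CSV: `frequency_hz`, `phase_deg`, `mod_ratio`, optional
`phase_sd_deg`, `mod_sd`; one file per experiment; strictly increasing
frequencies; angles in degrees. A manifest JSON maps files to condition /
acceptor / ionic strength / replicate / sample ids and carries global
settings (temperature, resting floor, default weights). Spreadsheet source
data is converted to Weber CSV (`tmfret.io.convert_spreadsheet`, fuzzy
column matching) rather than parsed directly by the numeric core. Tabulated
distance distributions (e.g. rotamer-library exports) are imported as
two-column tables, renormalized to unit area, and used for overlay
comparison only — never as fit models.
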