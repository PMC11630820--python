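# tmfret

Analysis of **time-resolved transition-metal-ion FRET (tmFRET)** measurements:
frequency-domain fluorescence-lifetime forward modeling over Gaussian
donor–acceptor distance distributions, single and global χ² fitting, phasor
diagnostics, steady-state FRET efficiency analysis, and four-state
conformational energetics — plus a synthetic-data generator so the whole
pipeline is testable without instrument data.

## The scientific problem

tmFRET pairs a long-lifetime fluorescent amino acid donor (Acd, τ_D ≈ 17.2 ns,
single exponential) with a cysteine-reacted transition-metal acceptor
complex. Because the Förster radii are short (R₀ = 41.8 Å for
[Fe(phenM)₃]²⁺, 43.5 Å for [Ru(bpy)₂phenM]²⁺, 15.6 Å for [Cu(TETAC)]²⁺),
transfer efficiency

  E(r) = 1 / (1 + (r/R₀)⁶)

is steeply sensitive to donor–acceptor distances of 10–50 Å — the scale of
conformational changes in a ligand-binding domain. A protein exchanging
between a **resting** (long-distance) and an **active** (short-distance)
conformation produces a *distribution* of distances: a sum of two Gaussians
with means r̄₁, r̄₂, widths σ₁, σ₂ and active-state fraction A₂.

Fluorescence lifetimes measured in the frequency domain resolve that
distribution. For a decay mixture with amplitudes α_j and lifetimes
τ_j = τ_D·(1 − E(r_j)), the phase delay φ and modulation ratio m at angular
modulation frequency ω follow from

  N(ω) = Σ f_j ωτ_j/(1+ω²τ_j²),  D(ω) = Σ f_j/(1+ω²τ_j²),
  φ = atan2(N, D) + ω·t₀,   m = √(N² + D²),

with τ-weighted fractional intensities f_j. Fitting Weber plots (φ and m vs
ω) across ligand conditions (apo, cAMP, cGMP) and acceptors, with the
Gaussian parameters shared globally and A₂ free per condition, yields the
occupancy of the active state in each condition. The four-state
(apo/holo × resting/active) energetics follow directly:

  ΔG = −RT·ln(P_active/P_resting),  ΔΔG_ligand = ΔG_ligand − ΔG_apo,
  ΔΔΔG = ΔΔG(150 mM KCl) − ΔΔG(500 mM KCl),

and phasor plots (g = m·cosφ, s = m·sinφ) provide a model-free cross-check:
single exponentials sit on the universal semicircle, and a condition whose
data fall on the chord between two others is a mixture of those two states.

See `docs/methods.md` for model conventions, defaults and limitations.

## Worked example

```python
import tmfret as tm

# Distance -> efficiency -> lifetime for the Fe acceptor pair
pair = tm.get_pair("Fe(phenM)3")            # R0 = 41.8 Å, tau_D = 17.2 ns
print(tm.efficiency_from_distance(29.5, pair.r0))   # 0.8900289...
print(tm.fret_lifetime(29.5, pair))                 # 1.892 ns

# Simulate the six-dataset study (2 acceptors x 3 ligand conditions) at the
# two-state truth (r1=40.9, s1=4.3, r2=29.5, s2=0.84; A2=0.12/1.0/0.34)
# and refit it globally
design = tm.StudyDesign(seed=1)
datasets, truth = tm.generate_fd_study(design)
pairs = {a: tm.get_pair(a) for a in design.acceptors}
res = tm.fit_global_two_gaussian(datasets, pairs, n_starts=2, seed=0)
print({k: round(res.parameters[k], 3)
       for k in ("rbar1", "rbar2", "A2_apo", "A2_cAMP", "A2_cGMP")})
# {'rbar1': 40.813, 'rbar2': 29.505, 'A2_apo': 0.101, 'A2_cAMP': 1.0, 'A2_cGMP': 0.33}

# Four-state energetics from the fitted occupancies (T = 298 K)
dg_apo = tm.delta_G(res.parameters["A2_apo"])
dg_camp = tm.delta_G(res.parameters["A2_cAMP"])     # floored at P_resting = 0.01
print(dg_apo, dg_camp, tm.delta_delta_G(dg_camp, dg_apo))
# 1.3 <-2.72 <-4.02
```

The recovered means land within ~0.1 Å of the generating values; a single
seed's occupancies scatter by ~0.02 around truth (medians over 20 seeds are
within 0.01 — see the acceptance script). The cAMP condition pins A₂ at its
upper bound, so its energies are reported as upper bounds (printed with a
leading `<`, "more favorable than").

The same workflow is available from the shell:

```bash
tmfret simulate --out sim --seed 1
tmfret fit-global --manifest sim/manifest.json --out global.json
tmfret energetics --fit-results global.json --out energetics.csv
tmfret report --manifest sim/manifest.json --fit-results global.json --out report/
```

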