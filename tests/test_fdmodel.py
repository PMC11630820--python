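"""Frequency-domain forward model: closed forms, time-domain oracle, phasors."""

import numpy as np
import pytest

import tmfret as tm
from tmfret.fdmodel import DEFAULT_FREQUENCIES


def single_exp_expected(tau_ns, freq_hz):
    """Closed-form phase/modulation of a single exponential."""
    wt = 2 * np.pi * freq_hz * tau_ns * 1e-9
    return np.degrees(np.arctan(wt)), 1.0 / np.sqrt(1.0 + wt**2)


def td_fourier_oracle(amplitudes, lifetimes_ns, freq_hz):
    """Independent oracle: simulate I(t) = sum a_j exp(-t/tau_j) on a fine grid
    and take sine/cosine Fourier transforms numerically."""
    tau = np.asarray(lifetimes_ns, dtype=float) * 1e-9
    a = np.asarray(amplitudes, dtype=float)
    t_max = 40.0 * tau.max()
    dt = min(1.0 / (400.0 * freq_hz), tau.min() / 100.0)
    t = np.arange(0.0, t_max, dt)
    intensity = (a[None, :] * np.exp(-t[:, None] / tau[None, :])).sum(axis=1)
    w = 2 * np.pi * freq_hz
    total = np.trapezoid(intensity, t)
    n = np.trapezoid(intensity * np.sin(w * t), t) / total
    d = np.trapezoid(intensity * np.cos(w * t), t) / total
    return np.arctan2(n, d), np.hypot(n, d)  # phase in rad


def test_single_exponential_closed_form():
    mix = tm.SpeciesMixture(np.array([1.0]), np.array([17.2]))
    phase, mod = tm.fd_response(mix, 10e6)
    exp_phase, exp_mod = single_exp_expected(17.2, 10e6)
    assert phase == pytest.approx(exp_phase, abs=1e-9)
    assert phase == pytest.approx(47.2, abs=0.05)
    assert mod == pytest.approx(exp_mod, abs=1e-12)
    assert mod == pytest.approx(0.679, abs=5e-4)


def test_t0_shifts_phase_only():
    mix = tm.SpeciesMixture(np.array([0.4, 0.6]), np.array([17.2, 2.0]))
    p0, m0 = tm.fd_response(mix, 10e6, t0=0.0)
    p1, m1 = tm.fd_response(mix, 10e6, t0=1.0)
    assert p1 - p0 == pytest.approx(np.degrees(2 * np.pi * 10e6 * 1e-9), abs=1e-9)  # 3.6 deg
    assert m1 == m0


def test_low_frequency_limit():
    mix = tm.SpeciesMixture(np.array([1.0]), np.array([17.2]))
    phase, mod = tm.fd_response(mix, 1.0)  # 1 Hz
    assert phase == pytest.approx(0.0, abs=1e-4)
    assert mod == pytest.approx(1.0, abs=1e-10)


def test_fd_response_matches_time_domain_oracle():
    """Model predictions agree with numerical Fourier transforms of synthetic
    time-domain decays within 1e-4 (phase in rad, modulation) on >= 5 random
    mixtures."""
    rng = np.random.default_rng(42)
    for _ in range(6):
        k = rng.integers(1, 5)
        a = rng.dirichlet(np.ones(k))
        tau = rng.uniform(0.5, 20.0, size=k)
        mix = tm.SpeciesMixture(a, tau)
        for freq in (10e6, 47e6, 143e6):
            phase_deg, mod = tm.fd_response(mix, freq)
            oracle_phase, oracle_mod = td_fourier_oracle(a, tau, freq)
            assert np.radians(phase_deg) == pytest.approx(oracle_phase, abs=1e-4)
            assert mod == pytest.approx(oracle_mod, abs=1e-4)


def test_species_from_distribution_bookkeeping(fe_pair):
    dist = tm.make_two_state(40.9, 4.3, 29.5, 0.84, 0.34)
    nuis = tm.NuisanceParams(f_donor_only=0.1, f_background=0.02)
    mix = tm.species_from_distribution(dist, fe_pair, nuis)
    assert mix.amplitudes.sum() == pytest.approx(1.0)
    # donor-only species carries exactly f_donor_only at tau_D
    donor_idx = np.flatnonzero(mix.lifetimes == fe_pair.tau_donor)
    assert mix.amplitudes[donor_idx].sum() == pytest.approx(0.1)
    # background species carries f_background at tau 0
    assert mix.amplitudes[mix.lifetimes == 0.0].sum() == pytest.approx(0.02)


def test_pure_donor_limits(fe_pair):
    dist = tm.make_single(40.0, 4.0)
    mix = tm.species_from_distribution(dist, fe_pair, tm.NuisanceParams())
    assert mix.amplitudes.sum() == pytest.approx(1.0)
    # distribution far beyond R0 is indistinguishable from donor-only
    far = tm.make_single(400.0, 4.0)
    ds = tm.predict_dataset(far, fe_pair)
    donor = tm.SpeciesMixture(np.array([1.0]), np.array([fe_pair.tau_donor]))
    phase, mod = tm.fd_response(donor, ds.frequencies)
    np.testing.assert_allclose(ds.phase_deg, phase, atol=1e-4)
    np.testing.assert_allclose(ds.mod_ratio, mod, atol=1e-6)


def test_scatter_background_sits_at_phasor_origin_of_circle(fe_pair):
    """A tau=0 background fraction pulls the phasor toward (g, s) = (1, 0)."""
    pure = tm.SpeciesMixture(np.array([1.0]), np.array([0.0]))
    phase, mod = tm.fd_response(pure, 10e6)
    g, s = tm.phasor_coordinates(phase, mod)
    assert (g, s) == pytest.approx((1.0, 0.0), abs=1e-12)
    dist = tm.make_single(40.0, 4.0)
    m0 = tm.species_from_distribution(dist, fe_pair, tm.NuisanceParams())
    mbg = tm.species_from_distribution(
        dist, fe_pair, tm.NuisanceParams(f_background=0.05, tau_background=0.0)
    )
    p0, mod0 = tm.fd_response(m0, 10e6)
    p1, mod1 = tm.fd_response(mbg, 10e6)
    g0, s0 = tm.phasor_coordinates(p0, mod0)
    g1, s1 = tm.phasor_coordinates(p1, mod1)
    # the mixed phasor lies on the segment from the pure phasor to (1, 0)
    lam = (g1 - g0) / (1.0 - g0)
    assert 0 < lam < 0.06
    assert s1 == pytest.approx(s0 * (1 - lam), abs=1e-12)


def test_predict_dataset_qualitative_shape(fe_pair):
    dist = tm.make_single(40.9, 4.3)
    ds = tm.predict_dataset(dist, fe_pair, condition="apo")
    assert np.all(np.diff(ds.phase_deg) > 0), "phase rises with frequency"
    assert np.all(np.diff(ds.mod_ratio) < 0), "modulation falls with frequency"


def test_phasor_universal_circle():
    """Single exponentials lie on (g - 1/2)^2 + s^2 = 1/4 to 1e-12."""
    for tau in (0.5, 2.0, 17.2, 50.0):
        for freq in DEFAULT_FREQUENCIES:
            mix = tm.SpeciesMixture(np.array([1.0]), np.array([tau]))
            g, s = tm.phasor_coordinates(*tm.fd_response(mix, freq))
            assert (g - 0.5) ** 2 + s**2 == pytest.approx(0.25, abs=1e-12)


def test_phasor_known_point():
    mix = tm.SpeciesMixture(np.array([1.0]), np.array([17.2]))
    g, s = tm.phasor_coordinates(*tm.fd_response(mix, 10e6))
    wt = 2 * np.pi * 10e6 * 17.2e-9
    assert g == pytest.approx(1 / (1 + wt**2), abs=1e-12)
    assert s == pytest.approx(wt / (1 + wt**2), abs=1e-12)
    assert (g, s) == pytest.approx((0.4613, 0.4985), abs=5e-4)


def test_phasor_mixture_collinearity(fe_pair):
    """Phasors of amplitude mixtures of two distributions are collinear: the
    model-free signature that one condition is a mixture of two others."""
    apo = tm.species_from_distribution(tm.make_two_state(40.9, 4.3, 29.5, 0.84, 0.12), fe_pair)
    camp = tm.species_from_distribution(tm.make_two_state(40.9, 4.3, 29.5, 0.84, 1.0), fe_pair)
    pts = []
    for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
        a = np.concatenate([(1 - lam) * apo.amplitudes, lam * camp.amplitudes])
        t = np.concatenate([apo.lifetimes, camp.lifetimes])
        mix = tm.SpeciesMixture(a / a.sum(), t)
        pts.append(tm.phasor_coordinates(*tm.fd_response(mix, 10e6)))
    pts = np.asarray(pts)
    p0, p1 = pts[0], pts[-1]
    direction = p1 - p0
    direction /= np.linalg.norm(direction)
    normal = np.array([-direction[1], direction[0]])
    offsets = (pts - p0) @ normal
    assert np.max(np.abs(offsets)) < 1e-9


def test_dataset_validation():
    freqs = np.array([10e6, 20e6, 40e6])
    ok = dict(phase_deg=np.array([10.0, 20.0, 30.0]), mod_ratio=np.array([0.9, 0.8, 0.7]))
    tm.FDDataset(frequencies=freqs, **ok)
    with pytest.raises(ValueError, match="increasing"):
        tm.FDDataset(frequencies=freqs[::-1], **ok)
    with pytest.raises(ValueError, match="mod"):
        tm.FDDataset(frequencies=freqs, phase_deg=ok["phase_deg"], mod_ratio=np.array([0.9, 1.2, 0.7]))
    with pytest.raises(ValueError, match="parallel"):
        tm.FDDataset(frequencies=freqs, phase_deg=ok["phase_deg"][:2], mod_ratio=ok["mod_ratio"])


def test_nuisance_validation():
    with pytest.raises(ValueError):
        tm.NuisanceParams(f_donor_only=0.7, f_background=0.4)
    with pytest.raises(ValueError):
        tm.NuisanceParams(f_donor_only=-0.1)
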